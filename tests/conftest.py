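import numpy as np
import pytest

from pdzlinker.io import InteractionDataset, InteractionRecord
from pdzlinker.model import PDZProfile, PositionPairModel, SubscoreTable
from pdzlinker import simulate as sim


@pytest.fixture(scope="session")
def reference_pair_model() -> PositionPairModel:
    """The default 38-pair model derived from the synthetic reference complex."""
    return sim.reference_pair_model()


@pytest.fixture
def single_pair_model() -> PositionPairModel:
    """Smallest useful model: domain position 0 paired with peptide p0."""
    return PositionPairModel(pairs=((0, 0),))


@pytest.fixture
def toy_profiles() -> dict[str, PDZProfile]:
    return {
        "DOMA-1/1": PDZProfile("DOMA-1/1", "A"),
        "DOMC-1/1": PDZProfile("DOMC-1/1", "C"),
    }


def make_dataset(rows, label):
    return InteractionDataset(
        [
            InteractionRecord(pdz_id=p, binder_name=n, cterm_seq=s, label=label)
            for p, n, s in rows
        ]
    )


@pytest.fixture
def toy_training_sets():
    """2 domains x 2 peptides with a single modelled pair: sub-scores are
    hand-computable log-odds."""
    positives = make_dataset(
        [("DOMA-1/1", "b1", "GGGGV"), ("DOMA-1/1", "b2", "GGGGL")], "positive"
    )
    negatives = make_dataset(
        [("DOMC-1/1", "b1", "GGGGV"), ("DOMC-1/1", "b2", "GGGGL")], "negative_motif"
    )
    return positives, negatives


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20111101)


def random_table(pair_model, rng, density=0.5, scale=1.0) -> SubscoreTable:
    """A dense-ish random sub-score table for scoring tests."""
    from pdzlinker.io import AMINO_ACIDS

    entries = {}
    for i in range(len(pair_model)):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if rng.random() < density:
                    entries[(i, a, b)] = float(rng.normal(0, scale))
    return SubscoreTable(entries)
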