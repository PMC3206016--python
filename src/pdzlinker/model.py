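"""Additive pairwise position-based scoring of PDZ-peptide interactions.

The model scores a (PDZ domain, C-terminal peptide) pair as a sum of
sub-scores, one per modelled *position pair*.  A position pair couples one of
the domain positions of an alignment-derived profile (16 by default) with one
of the last five peptide positions (p0 .. p-4).  Each sub-score quantifies the
positive, neutral or negative contribution of the specific amino-acid pair
observed at that position pair; combinations never seen in training contribute
exactly 0.0.  A pair is classified as interacting when the summed score
reaches the decision cutoff (0.5 by default, inclusive).

Sub-scores are estimated from labelled interaction / non-interaction data as
pseudocounted log-odds of occurrence in positives versus negatives.  The
model / results split follows the usual statsmodels pattern:
:class:`PairwiseInteractionModel` holds the data, ``fit()`` returns a
:class:`PairwiseModelResults` carrying the trained sub-score table together
with prediction and summary methods.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import (
    AMINO_ACIDS,
    InteractionDataset,
    SequenceError,
    validate_peptide,
)

_AA_SET = frozenset(AMINO_ACIDS)
GAP = "-"

#: Residues observed at peptide position p0 in artificial or natural
#: PDZ-binding peptides; used to post-filter proteome-wide hits.
P0_ALLOWED = frozenset("CYFLIMVWA")

#: Inclusive decision cutoff on the summed score.
DEFAULT_CUTOFF = 0.5

#: Width of the modelled peptide window (positions p0 .. p-4).
PEPTIDE_WINDOW = 5


class TrainingError(ValueError):
    """Training inputs are unusable (e.g. an empty class)."""


@dataclass(frozen=True)
class AlignmentProfileSpec:
    """Selection of model columns from a master domain alignment.

    ``model_columns`` are one-based alignment column indices, strictly
    increasing; 16 columns by default define the domain positions used for
    prediction.
    """

    alignment_id: str
    model_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = tuple(self.model_columns)
        object.__setattr__(self, "model_columns", cols)
        if any(c < 1 for c in cols):
            raise ValueError("alignment columns are one-based (>= 1)")
        if list(cols) != sorted(set(cols)):
            raise ValueError("model columns must be strictly increasing")

    @property
    def n_positions(self) -> int:
        return len(self.model_columns)


@dataclass(frozen=True)
class PDZProfile:
    """Residues of one PDZ domain at the model's domain positions.

    ``residues`` may contain the gap character ``-`` where the domain has no
    residue in a model column; gapped positions contribute 0.0 to every score.
    """

    pdz_id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _AA_SET - {GAP}
        if bad:
            raise SequenceError(
                f"profile {self.pdz_id}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PositionPairModel:
    """The ordered (domain position, peptide position) pairs of the model.

    ``pairs`` holds ``(domain_position_index, peptide_offset)`` tuples where
    the domain index is 0-based into a :class:`PDZProfile` and the peptide
    offset is in {0, -1, -2, -3, -4} (0 = C-terminal residue p0).
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(d), int(p)) for d, p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("position pairs must be unique")
        for d, p in pairs:
            if d < 0:
                raise ValueError(f"domain position index {d} is negative")
            if not (-(PEPTIDE_WINDOW - 1) <= p <= 0):
                raise ValueError(
                    f"peptide offset {p} outside modelled window "
                    f"[{-(PEPTIDE_WINDOW - 1)}, 0]"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def n_parameters(self, alphabet_size: int = len(AMINO_ACIDS)) -> int:
        """Size of the trainable sub-score space: one parameter per
        (position pair, domain residue, peptide residue) combination."""
        return len(self.pairs) * alphabet_size * alphabet_size

    def n_domain_positions(self) -> int:
        return max((d for d, _ in self.pairs), default=-1) + 1


#: A sub-score key: (pair index into PositionPairModel.pairs, domain aa, peptide aa)
SubscoreKey = tuple[int, str, str]


@dataclass
class SubscoreTable:
    """Trained per-pair amino-acid-pair contributions.

    Lookup of any absent key returns exactly 0.0 — the neutral value given to
    combinations never seen in training.
    """

    entries: dict[SubscoreKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite sub-score for {key}")

    def lookup(self, pair_index: int, domain_aa: str, peptide_aa: str) -> float:
        return self.entries.get((pair_index, domain_aa, peptide_aa), 0.0)

    def __len__(self) -> int:
        return len(self.entries)

    # -- serialisation ------------------------------------------------------

    def to_tsv(self, path: str | Path, pair_model: PositionPairModel) -> None:
        with open(path, "w") as fh:
            fh.write("# pair_index\tdomain_pos\tpep_offset\tdomain_aa\tpep_aa\tsubscore\n")
            for (i, a, b), v in sorted(self.entries.items()):
                d, p = pair_model.pairs[i]
                fh.write(f"{i}\t{d}\t{p}\t{a}\t{b}\t{v:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubscoreTable":
        entries: dict[SubscoreKey, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i, _d, _p, a, b, v = line.split("\t")
                entries[(int(i), a, b)] = float(v)
        return cls(entries)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"pair_index": i, "domain_aa": a, "peptide_aa": b, "subscore": v}
            for (i, a, b), v in sorted(self.entries.items())
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubscoreTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                (e["pair_index"], e["domain_aa"], e["peptide_aa"]): e["subscore"]
                for e in payload
            }
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Estimator settings for sub-score training.

    pseudocount
        Laplace pseudocount added to positive and negative occurrence counts.
    log_base
        Base of the log-odds (2 by default, giving bit-scaled sub-scores).
    min_observations
        Minimum total occurrences (positives + negatives) for a combination
        to receive a trained entry; rarer combinations stay at neutral 0.0.
    """

    pseudocount: float = 1.0
    log_base: float = 2.0
    min_observations: int = 1

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")


@dataclass(frozen=True)
class ScoreResult:
    """Score of one (PDZ domain, peptide) pair and its classification."""

    pdz_id: str
    peptide: str
    score: float
    cutoff: float = DEFAULT_CUTOFF

    @property
    def is_hit(self) -> bool:
        return self.score >= self.cutoff


def build_profile(
    alignment: Mapping[str, str], spec: AlignmentProfileSpec, seq_id: str
) -> PDZProfile:
    """Project one aligned sequence onto the model columns of *spec*."""
    if seq_id not in alignment:
        raise KeyError(f"sequence {seq_id!r} not present in alignment")
    row = alignment[seq_id]
    width = len(row)
    for col in spec.model_columns:
        if col > width:
            raise ValueError(
                f"model column {col} beyond alignment width {width}"
            )
    residues = "".join(row[col - 1] for col in spec.model_columns)
    return PDZProfile(pdz_id=seq_id, residues=residues)


def _iter_pair_observations(
    record_peptide: str, profile: PDZProfile, pair_model: PositionPairModel
):
    """Yield (pair_index, domain_aa, peptide_aa) for one record, skipping
    gapped domain positions."""
    window = record_peptide[-PEPTIDE_WINDOW:]
    for i, (d, p) in enumerate(pair_model.pairs):
        domain_aa = profile.residues[d]
        if domain_aa == GAP:
            continue
        peptide_aa = window[len(window) - 1 + p]
        yield i, domain_aa, peptide_aa


def train_subscores(
    positives: InteractionDataset,
    negatives: InteractionDataset,
    profiles: Mapping[str, PDZProfile],
    pair_model: PositionPairModel,
    config: TrainingConfig = TrainingConfig(),
) -> SubscoreTable:
    """Estimate sub-scores as pseudocounted log-odds of occurrence in
    positives versus negatives.

    For each combination ``(pair, a, b)`` observed at least
    ``config.min_observations`` times across both classes::

        entry = log_base[ (c_pos + q) / (N_pos + 400 q)
                        / ((c_neg + q) / (N_neg + 400 q)) ]

    where ``q`` is the pseudocount, ``c_pos``/``c_neg`` the occurrence counts
    in each class and ``N_pos``/``N_neg`` the per-pair class totals.
    Combinations never observed stay absent (neutral, 0.0 on lookup).
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise TrainingError("both a positive and a negative set are required")
    n_aa_pairs = len(AMINO_ACIDS) ** 2
    pos_counts: Counter[SubscoreKey] = Counter()
    neg_counts: Counter[SubscoreKey] = Counter()
    pos_totals: Counter[int] = Counter()
    neg_totals: Counter[int] = Counter()

    for dataset, counts, totals in (
        (positives, pos_counts, pos_totals),
        (negatives, neg_counts, neg_totals),
    ):
        for rec in dataset:
            if rec.pdz_id not in profiles:
                raise TrainingError(f"no profile for {rec.pdz_id}")
            if len(rec.cterm_seq) < PEPTIDE_WINDOW:
                raise TrainingError(
                    f"{rec.pdz_id}/{rec.binder_name}: peptide shorter than "
                    f"{PEPTIDE_WINDOW} residues"
                )
            for obs in _iter_pair_observations(
                rec.cterm_seq, profiles[rec.pdz_id], pair_model
            ):
                counts[obs] += 1
                totals[obs[0]] += 1

    q = config.pseudocount
    log_b = math.log(config.log_base)
    entries: dict[SubscoreKey, float] = {}
    for key in set(pos_counts) | set(neg_counts):
        c_pos, c_neg = pos_counts[key], neg_counts[key]
        if c_pos + c_neg < config.min_observations:
            continue
        pair_index = key[0]
        p_pos = (c_pos + q) / (pos_totals[pair_index] + n_aa_pairs * q)
        p_neg = (c_neg + q) / (neg_totals[pair_index] + n_aa_pairs * q)
        entries[key] = math.log(p_pos / p_neg) / log_b
    return SubscoreTable(entries)


def score(
    profile: PDZProfile,
    peptide: str,
    table: SubscoreTable,
    pair_model: PositionPairModel,
    cutoff: float = DEFAULT_CUTOFF,
) -> ScoreResult:
    """Score one (profile, peptide) pair as the sum of sub-scores.

    Only the last five peptide residues are consulted; residues upstream of
    p-4 never influence the score.
    """
    validate_peptide(peptide, context=profile.pdz_id)
    if len(peptide) < PEPTIDE_WINDOW:
        raise SequenceError(
            f"peptide {peptide!r} shorter than the modelled window "
            f"({PEPTIDE_WINDOW} residues)"
        )
    total = 0.0
    for i, a, b in _iter_pair_observations(peptide, profile, pair_model):
        total += table.lookup(i, a, b)
    return ScoreResult(pdz_id=profile.pdz_id, peptide=peptide, score=total, cutoff=cutoff)


def classify(score_value: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True iff *score_value* >= *cutoff* (inclusive boundary)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return score_value >= cutoff


def p0_filter(peptide: str, allowed: frozenset[str] = P0_ALLOWED) -> bool:
    """True iff the C-terminal residue (p0) of *peptide* is in *allowed*."""
    if not peptide:
        raise SequenceError("empty peptide")
    return peptide[-1] in allowed


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------


class PairwiseInteractionModel:
    """Additive pairwise scoring model bound to labelled training data.

    Parameters
    ----------
    positives, negatives
        Labelled interaction / non-interaction datasets.
    profiles
        Mapping pdz_id -> :class:`PDZProfile` covering every domain in the
        datasets.
    pair_model
        The :class:`PositionPairModel` defining which (domain position,
        peptide position) pairs carry sub-scores.
    config
        Estimator settings; see :class:`TrainingConfig`.
    """

    def __init__(
        self,
        positives: InteractionDataset,
        negatives: InteractionDataset,
        profiles: Mapping[str, PDZProfile],
        pair_model: PositionPairModel,
        config: TrainingConfig = TrainingConfig(),
    ) -> None:
        self.positives = positives
        self.negatives = negatives
        self.profiles = dict(profiles)
        self.pair_model = pair_model
        self.config = config

    def fit(self) -> "PairwiseModelResults":
        table = train_subscores(
            self.positives, self.negatives, self.profiles, self.pair_model, self.config
        )
        return PairwiseModelResults(
            subscores=table,
            pair_model=self.pair_model,
            profiles=self.profiles,
            config=self.config,
            n_positives=len(self.positives),
            n_negatives=len(self.negatives),
        )


@dataclass
class PairwiseModelResults:
    """A fitted pairwise scoring model: the trained sub-score table plus
    scoring, prediction and summary methods.

    Can also be constructed directly from a pre-trained table via
    :meth:`from_table` (e.g. a distributed sub-score file), in which case the
    training metadata fields are zero.
    """

    subscores: SubscoreTable
    pair_model: PositionPairModel
    profiles: dict[str, PDZProfile]
    config: TrainingConfig = TrainingConfig()
    n_positives: int = 0
    n_negatives: int = 0
    cutoff: float = DEFAULT_CUTOFF

    @classmethod
    def from_table(
        cls,
        subscores: SubscoreTable,
        pair_model: PositionPairModel,
        profiles: Mapping[str, PDZProfile],
        cutoff: float = DEFAULT_CUTOFF,
    ) -> "PairwiseModelResults":
        return cls(
            subscores=subscores,
            pair_model=pair_model,
            profiles=dict(profiles),
            cutoff=cutoff,
        )

    def score(self, pdz_id: str, peptide: str) -> ScoreResult:
        if pdz_id not in self.profiles:
            raise KeyError(f"no profile for {pdz_id!r}")
        return score(
            self.profiles[pdz_id], peptide, self.subscores, self.pair_model, self.cutoff
        )

    def predict(
        self, dataset: InteractionDataset | Iterable[tuple[str, str]]
    ) -> dict[tuple[str, str], bool]:
        """Binary predictions for every (pdz_id, peptide) pair."""
        pairs = (
            dataset.pairs() if isinstance(dataset, InteractionDataset) else list(dataset)
        )
        return {
            (pdz, pep): self.score(pdz, pep).is_hit for pdz, pep in dict.fromkeys(pairs)
        }

    def coverage(self) -> float:
        """Fraction of the sub-score parameter space with a trained entry."""
        return len(self.subscores) / self.pair_model.n_parameters()

    def summary(self) -> str:
        lines = [
            "Pairwise PDZ-peptide interaction model",
            "=" * 42,
            f"position pairs:        {len(self.pair_model)}",
            f"parameter space:       {self.pair_model.n_parameters()}",
            f"trained sub-scores:    {len(self.subscores)}"
            f"  ({100 * self.coverage():.1f}% of space)",
            f"training positives:    {self.n_positives}",
            f"training negatives:    {self.n_negatives}",
            f"decision cutoff:       {self.cutoff} (inclusive)",
            f"pseudocount:           {self.config.pseudocount}",
            f"log base:              {self.config.log_base}",
        ]
        if self.subscores.entries:
            top = sorted(
                self.subscores.entries.items(), key=lambda kv: -abs(kv[1])
            )[:5]
            lines.append("largest |sub-scores|:")
            for (i, a, b), v in top:
                d, p = self.pair_model.pairs[i]
                lines.append(
                    f"  pair {i} (domain pos {d}, peptide p{p}): {a}/{b} = {v:+.3f}"
                )
        return "\n".join(lines)
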