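import math

import numpy as np
import pytest

from pdzlinker.io import AMINO_ACIDS, InteractionDataset, SequenceError
from pdzlinker.model import (
    AlignmentProfileSpec,
    PairwiseInteractionModel,
    PDZProfile,
    PositionPairModel,
    SubscoreTable,
    TrainingConfig,
    TrainingError,
    build_profile,
    classify,
    p0_filter,
    score,
    train_subscores,
)
from tests.conftest import make_dataset, random_table


class TestBuildProfile:
    def test_direct_projection(self):
        spec = AlignmentProfileSpec("toy", (1, 3, 4))
        profile = build_profile({"A": "R-KT"}, spec, "A")
        assert profile.residues == "RKT"

    def test_gap_passes_through(self):
        spec = AlignmentProfileSpec("toy", (1, 2))
        assert build_profile({"A": "R-KT"}, spec, "A").residues == "R-"

    def test_column_beyond_width(self):
        spec = AlignmentProfileSpec("toy", (1, 9))
        with pytest.raises(ValueError, match="beyond alignment width"):
            build_profile({"A": "R-KT"}, spec, "A")

    def test_missing_sequence(self):
        spec = AlignmentProfileSpec("toy", (1,))
        with pytest.raises(KeyError):
            build_profile({"A": "R-KT"}, spec, "B")

    def test_columns_must_increase(self):
        with pytest.raises(ValueError):
            AlignmentProfileSpec("toy", (3, 1))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected", [(0.64, True), (0.499, False), (0.50, True), (-1.0, False)]
    )
    def test_inclusive_cutoff(self, value, expected):
        assert classify(value) is expected

    def test_non_finite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify(1.0, cutoff=math.nan)


class TestP0Filter:
    @pytest.mark.parametrize("peptide", ["SETSV", "ETEV", "RETQV", "LQRRL"])
    def test_hydrophobic_termini_pass(self, peptide):
        assert p0_filter(peptide)

    @pytest.mark.parametrize("peptide", ["SETSE", "SETSD", "SETSK", "SETSG"])
    def test_other_termini_rejected(self, peptide):
        assert not p0_filter(peptide)

    def test_empty_peptide(self):
        with pytest.raises(SequenceError):
            p0_filter("")


class TestScore:
    def test_empty_table_scores_zero(self, single_pair_model):
        profile = PDZProfile("DOMA-1/1", "A")
        res = score(profile, "GGGGV", SubscoreTable(), single_pair_model)
        assert res.score == 0.0
        assert not res.is_hit

    def test_single_matching_entry(self, single_pair_model):
        profile = PDZProfile("DOMA-1/1", "A")
        table = SubscoreTable({(0, "A", "V"): 0.7})
        res = score(profile, "GGGGV", table, single_pair_model)
        assert res.score == 0.7
        assert res.is_hit

    def test_short_peptide_rejected(self, single_pair_model):
        with pytest.raises(SequenceError):
            score(PDZProfile("A-1/1", "A"), "GV", SubscoreTable(), single_pair_model)

    def test_gap_position_contributes_zero(self):
        pair_model = PositionPairModel(pairs=((0, 0), (1, 0)))
        profile = PDZProfile("A-1/1", "A-")
        table = SubscoreTable({(0, "A", "V"): 0.3, (1, "A", "V"): 9.9})
        assert score(profile, "GGGGV", table, pair_model).score == 0.3

    def test_additivity_matches_naive_oracle(self, reference_pair_model, rng):
        """The summed score equals an independent brute-force sum over all
        pairs on 1000 random (profile, peptide, table) triples."""
        pair_model = reference_pair_model
        n_pos = pair_model.n_domain_positions()
        aa = np.array(list(AMINO_ACIDS))
        table = random_table(pair_model, rng, density=0.4)
        for _ in range(1000):
            profile = PDZProfile("T-1/1", "".join(aa[rng.integers(0, 20, n_pos)]))
            peptide = "".join(aa[rng.integers(0, 20, 8)])
            expected = 0.0  # naive re-implementation, kept deliberately dumb
            for i, (d, o) in enumerate(pair_model.pairs):
                window = peptide[-5:]
                expected += table.entries.get(
                    (i, profile.residues[d], window[4 + o]), 0.0
                )
            assert score(profile, peptide, table, pair_model).score == expected

    def test_invariant_to_residues_upstream_of_p_minus_4(
        self, reference_pair_model, rng
    ):
        table = random_table(reference_pair_model, rng, density=0.6)
        profile = PDZProfile("T-1/1", "ACDEFGHIKLMNPQRS")
        base = score(profile, "WWWSETSV", table, reference_pair_model).score
        for prefix in ("AAA", "KRKRK", ""):
            assert (
                score(profile, prefix + "SETSV", table, reference_pair_model).score
                == base
            )

    def test_increasing_one_consulted_subscore_increases_score(
        self, single_pair_model
    ):
        profile = PDZProfile("A-1/1", "A")
        low = SubscoreTable({(0, "A", "V"): 0.1})
        high = SubscoreTable({(0, "A", "V"): 0.2})
        assert (
            score(profile, "GGGGV", high, single_pair_model).score
            > score(profile, "GGGGV", low, single_pair_model).score
        )


class TestTrainSubscores:
    def test_toy_set_matches_hand_computed_log_odds(
        self, toy_training_sets, toy_profiles, single_pair_model
    ):
        """2x2 toy data: entries equal log2 of the pseudocounted odds ratio
        computed by hand."""
        positives, negatives = toy_training_sets
        table = train_subscores(
            positives, negatives, toy_profiles, single_pair_model, TrainingConfig()
        )
        # (A,V): 1 of 2 positives, 0 of 2 negatives, pseudocount 1:
        # log2[ (1+1)/(2+400) / ((0+1)/(2+400)) ] = log2(2) = 1.0
        assert table.lookup(0, "A", "V") == pytest.approx(1.0)
        assert table.lookup(0, "A", "L") == pytest.approx(1.0)
        assert table.lookup(0, "C", "V") == pytest.approx(-1.0)
        assert table.lookup(0, "C", "L") == pytest.approx(-1.0)

    def test_unseen_combination_is_exactly_zero(
        self, toy_training_sets, toy_profiles, single_pair_model
    ):
        positives, negatives = toy_training_sets
        table = train_subscores(
            positives, negatives, toy_profiles, single_pair_model, TrainingConfig()
        )
        assert table.lookup(0, "W", "W") == 0.0
        assert (0, "W", "W") not in table.entries

    def test_empty_class_rejected(self, toy_profiles, single_pair_model):
        positives = make_dataset([("DOMA-1/1", "b", "GGGGV")], "positive")
        with pytest.raises(TrainingError):
            train_subscores(
                positives, InteractionDataset(), toy_profiles, single_pair_model
            )

    def test_min_observations_suppresses_rare_combinations(
        self, toy_training_sets, toy_profiles, single_pair_model
    ):
        positives, negatives = toy_training_sets
        table = train_subscores(
            positives,
            negatives,
            toy_profiles,
            single_pair_model,
            TrainingConfig(min_observations=2),
        )
        assert len(table) == 0  # every combination occurs exactly once

    def test_missing_profile_rejected(self, toy_training_sets, single_pair_model):
        positives, negatives = toy_training_sets
        with pytest.raises(TrainingError, match="no profile"):
            train_subscores(positives, negatives, {}, single_pair_model)

    def test_exhaustive_noise_free_training_recovers_sign_pattern(
        self, single_pair_model
    ):
        """With zero label noise and every amino-acid combination sampled,
        the trained table reproduces the planted sign for every observed
        combination."""
        rng = np.random.default_rng(5)
        planted = {
            (0, a, b): float(rng.normal(0, 0.5)) or 0.1
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        }
        pos_rows, neg_rows = [], []
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                row = (f"DOM{a}-1/1", f"pep{b}", "GGGG" + b)
                (pos_rows if planted[(0, a, b)] > 0 else neg_rows).append(row)
        profiles = {f"DOM{a}-1/1": PDZProfile(f"DOM{a}-1/1", a) for a in AMINO_ACIDS}
        table = train_subscores(
            make_dataset(pos_rows, "positive"),
            make_dataset(neg_rows, "negative_motif"),
            profiles,
            single_pair_model,
        )
        for key, value in planted.items():
            assert math.copysign(1, table.entries[key]) == math.copysign(1, value)


class TestPairModelAndTable:
    def test_parameter_space_size(self):
        pair_model = PositionPairModel(
            pairs=tuple((d, -(d % 5)) for d in range(38))
        )
        assert pair_model.n_parameters() == 15200

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            PositionPairModel(pairs=((0, 0), (0, 0)))

    def test_offset_outside_window_rejected(self):
        with pytest.raises(ValueError):
            PositionPairModel(pairs=((0, -5),))

    def test_table_serialisation_round_trips(self, tmp_path, rng, single_pair_model):
        table = random_table(single_pair_model, rng, density=0.2)
        tsv, js = tmp_path / "t.tsv", tmp_path / "t.json"
        table.to_tsv(tsv, single_pair_model)
        table.to_json(js)
        assert SubscoreTable.from_tsv(tsv).entries == pytest.approx(table.entries)
        assert SubscoreTable.from_json(js).entries == table.entries

    def test_non_finite_subscore_rejected(self):
        with pytest.raises(ValueError):
            SubscoreTable({(0, "A", "V"): math.inf})


class TestModelResults:
    def test_fit_predict_summary(
        self, toy_training_sets, toy_profiles, single_pair_model
    ):
        positives, negatives = toy_training_sets
        model = PairwiseInteractionModel(
            positives, negatives, toy_profiles, single_pair_model
        )
        results = model.fit()
        predictions = results.predict(positives)
        assert predictions[("DOMA-1/1", "GGGGV")] is True  # score 1.0 >= 0.5
        assert results.score("DOMC-1/1", "GGGGV").is_hit is False
        text = results.summary()
        assert "position pairs" in text and "400" in text

    def test_results_from_pretrained_table(self, toy_profiles, single_pair_model):
        from pdzlinker.model import PairwiseModelResults

        results = PairwiseModelResults.from_table(
            SubscoreTable({(0, "A", "V"): 0.64}), single_pair_model, toy_profiles
        )
        assert results.score("DOMA-1/1", "GGGGV").score == pytest.approx(0.64)
        assert results.score("DOMA-1/1", "GGGGV").is_hit
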