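import numpy as np
import pytest
import biotite.structure as struc

from pdzlinker import simulate as sim
from pdzlinker.contacts import (
    ContactConfig,
    MetricError,
    complex_contact_pairs,
    consensus_selection,
    derive_position_pair_model,
    jaccard,
    pair_mean_distances,
    residue_distance,
    sweep_thresholds,
)
from pdzlinker.io import ComplexStructure


def _residue(coords, names=None, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array([1] * n)
    arr.res_name = np.array(["ALA"] * n)
    arr.atom_name = np.array(names if names else ["CA"] + [f"C{i}" for i in range(1, n)])
    arr.element = np.array(elements if elements else ["C"] * n)
    return arr


class TestResidueDistance:
    def test_coincident_atoms(self):
        res = _residue([[1.0, 2.0, 3.0]])
        for metric in ("min_atom", "c_alpha", "center_of_mass"):
            assert residue_distance(res, res, metric) == 0.0

    def test_three_four_five_triangle(self):
        a = _residue([[0.0, 0.0, 0.0]])
        b = _residue([[3.0, 4.0, 0.0]])
        for metric in ("min_atom", "c_alpha", "center_of_mass"):
            assert residue_distance(a, b, metric) == pytest.approx(5.0)

    def test_missing_calpha_signalled(self):
        a = _residue([[0.0, 0.0, 0.0]], names=["CB"])
        b = _residue([[1.0, 0.0, 0.0]])
        with pytest.raises(MetricError):
            residue_distance(a, b, "c_alpha")
        assert residue_distance(a, b, "min_atom") == pytest.approx(1.0)

    def test_center_of_mass_is_mass_weighted(self):
        # C at origin, O at (0,0,2): centroid sits closer to the heavier O
        a = _residue([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]], names=["CA", "O"],
                     elements=["C", "O"])
        b = _residue([[0.0, 0.0, 10.0]])
        expected_z = (12.011 * 0 + 15.999 * 2) / (12.011 + 15.999)
        assert residue_distance(a, b, "center_of_mass") == pytest.approx(10 - expected_z)

    def test_min_atom_never_exceeds_c_alpha(self, rng):
        """Whenever both Cα atoms exist, the minimal atom distance cannot
        exceed the Cα-Cα distance."""
        for _ in range(50):
            a = _residue(rng.normal(0, 5, (6, 3)))
            b = _residue(rng.normal(10, 5, (6, 3)))
            assert residue_distance(a, b, "min_atom") <= residue_distance(
                a, b, "c_alpha"
            ) + 1e-12

    def test_min_atom_matches_exhaustive_enumeration(self, rng):
        """Oracle check: minimum over an explicit double loop on random
        10-atom residues."""
        for _ in range(25):
            a = _residue(rng.normal(0, 8, (10, 3)))
            b = _residue(rng.normal(4, 8, (10, 3)))
            brute = min(
                float(np.linalg.norm(x.astype(np.float64) - y.astype(np.float64)))
                for x in a.coord
                for y in b.coord
            )
            assert residue_distance(a, b, "min_atom") == pytest.approx(brute, abs=1e-12)

    def test_unknown_metric(self):
        res = _residue([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            residue_distance(res, res, "manhattan")


class TestComplexContacts:
    def test_planted_pair_at_4p9_selected_at_5_not_4p5(self):
        cpx = sim.simulate_complex([(7, 0, 4.9)], peptide_length=3)
        p0_res = cpx.peptide_residue_ids()[-1]
        assert (7, p0_res) in complex_contact_pairs(cpx, ContactConfig("min_atom", 5.0))
        assert (7, p0_res) not in complex_contact_pairs(
            cpx, ContactConfig("min_atom", 4.5)
        )

    def test_mean_over_models_decides(self):
        """Two models at 4 and 7 Å give a mean of 5.5 Å: excluded at 5 Å."""
        m1 = sim.simulate_complex([(1, 0, 4.0)], peptide_length=2).atoms[0]
        m2 = sim.simulate_complex([(1, 0, 7.0)], peptide_length=2).atoms[0]
        cpx = ComplexStructure(struc.stack([m1, m2]), "A", "B")
        means = pair_mean_distances(cpx, "min_atom")
        p0_res = cpx.peptide_residue_ids()[-1]
        assert means[(1, p0_res)] == pytest.approx(5.5)
        assert (1, p0_res) not in complex_contact_pairs(cpx, ContactConfig("min_atom", 5))
        assert (1, p0_res) in complex_contact_pairs(cpx, ContactConfig("min_atom", 5.5))

    def test_zero_threshold_selects_nothing(self):
        cpx = sim.simulate_complex([(1, 0, 3.0)], peptide_length=2)
        assert complex_contact_pairs(cpx, ContactConfig("min_atom", 0.0)) == set()

    def test_selection_grows_with_threshold(self, rng):
        """Monotonicity: raising the threshold can only add contacts."""
        geometry = [
            (int(d), -int(o), float(rng.uniform(2, 12)))
            for d, o in zip(rng.integers(1, 15, 8), rng.integers(0, 5, 8))
        ]
        geometry = list({(d, o): (d, o, dist) for d, o, dist in geometry}.values())
        cpx = sim.simulate_complex(geometry, peptide_length=5)
        for metric in ("min_atom", "c_alpha", "center_of_mass"):
            previous = set()
            for threshold in np.arange(0, 40.5, 2.5):
                current = complex_contact_pairs(cpx, ContactConfig(metric, threshold))
                assert previous <= current
                previous = current


class TestConsensus:
    def test_single_complex_equals_pairwise_selection(self):
        cpx = sim.simulate_complex([(3, 0, 4.0), (5, -2, 4.4)], peptide_length=5)
        sel = consensus_selection([cpx], ContactConfig("min_atom", 5.0))
        assert sel.selected == {(3, 0), (5, -2)}

    def test_pair_failing_in_one_complex_is_excluded(self):
        good = sim.simulate_complex([(3, 0, 4.0), (5, -2, 4.4)], peptide_length=5)
        partial = sim.simulate_complex([(3, 0, 4.0), (5, -2, 8.0)], peptide_length=5)
        sel = consensus_selection([good, partial], ContactConfig("min_atom", 5.0))
        assert sel.selected == {(3, 0)}

    def test_idempotent_over_identical_complexes(self):
        cpx = sim.simulate_complex([(3, 0, 4.0), (5, -2, 4.4)], peptide_length=5)
        single = consensus_selection([cpx], ContactConfig("min_atom", 5.0)).selected
        triple = consensus_selection(
            [cpx, cpx, cpx], ContactConfig("min_atom", 5.0)
        ).selected
        assert single == triple

    def test_pooled_reading_uses_grand_mean(self):
        near = sim.simulate_complex([(1, 0, 4.0)], peptide_length=2)
        far = sim.simulate_complex([(1, 0, 7.0)], peptide_length=2)
        strict = consensus_selection([near, far], ContactConfig("min_atom", 5.0))
        pooled = consensus_selection(
            [near, far], ContactConfig("min_atom", 5.0), pooled=True
        )
        assert strict.selected == set()
        assert pooled.selected == set()  # grand mean 5.5 > 5
        pooled6 = consensus_selection(
            [near, far], ContactConfig("min_atom", 6.0), pooled=True
        )
        assert pooled6.selected == {(1, 0)}

    def test_residue_maps_align_numbering(self):
        a = sim.simulate_complex([(3, 0, 4.0)], peptide_length=2)
        b = sim.simulate_complex([(103, 0, 4.0)], peptide_length=2)
        sel = consensus_selection(
            [a, b],
            ContactConfig("min_atom", 5.0),
            residue_maps=[{3: 3}, {103: 3}],
        )
        assert sel.selected == {(3, 0)}


class TestSweep:
    def test_reference_reached_at_some_grid_point(self):
        cpx = sim.simulate_complex(
            [(1, 0, 3.0), (2, -1, 4.0)], peptide_length=3,
            extra_domain_residues=[9],
        )
        metric, threshold, similarity = sweep_thresholds([cpx], {1, 2})
        assert similarity == 1.0
        assert metric == "min_atom"  # tie with c_alpha broken by metric order

    def test_fixture_favouring_min_atom_at_5(self):
        """One residue's only contact sits at 4.9 Å and the Cα atoms are
        pushed 2 Å back: only (min_atom, 5 Å) reproduces the reference."""
        geometry = [(d, -(d % 3), 3.0 + 0.1 * d) for d in range(1, 14)] + [
            (14, 0, 4.9)
        ]
        cpx = sim.simulate_complex(
            geometry, peptide_length=5, ca_offset=2.0, extra_domain_residues=[50]
        )
        reference = set(range(1, 15))
        metric, threshold, similarity = sweep_thresholds([cpx], reference)
        assert (metric, threshold) == ("min_atom", 5.0)
        assert similarity == 1.0

    def test_empty_reference_rejected(self):
        cpx = sim.simulate_complex([(1, 0, 3.0)], peptide_length=2)
        with pytest.raises(ValueError):
            sweep_thresholds([cpx], set())


class TestJaccard:
    def test_values(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0
        assert jaccard({1}, {2}) == 0.0
        assert jaccard({1, 2}, {2, 3}) == pytest.approx(1 / 3)
        assert jaccard(set(), set()) == 1.0


class TestDerivePairModel:
    def test_planted_contacts_in_window(self):
        cpx = sim.simulate_complex(
            [(10, 0, 4.0), (20, -2, 4.2), (30, -4, 4.4)], peptide_length=5
        )
        derivation = derive_position_pair_model(cpx)
        assert derivation.domain_residues == (10, 20, 30)
        assert set(derivation.pair_model.pairs) == {(0, 0), (1, -2), (2, -4)}
        assert derivation.upstream_contacts == ()

    def test_upstream_contact_reported_not_modelled(self):
        cpx = sim.simulate_complex(
            [(10, 0, 4.0), (40, -6, 4.0)], peptide_length=7
        )
        derivation = derive_position_pair_model(cpx)
        assert derivation.pair_model.pairs == ((0, 0),)
        assert derivation.upstream_contacts == ((40, -6),)

    def test_empty_contact_set_warns(self):
        cpx = sim.simulate_complex([(10, 0, 12.0)], peptide_length=5)
        with pytest.warns(UserWarning):
            derivation = derive_position_pair_model(cpx)
        assert len(derivation.pair_model) == 0

    def test_explicit_map_reports_unmapped(self):
        cpx = sim.simulate_complex([(10, 0, 4.0), (20, -1, 4.0)], peptide_length=5)
        derivation = derive_position_pair_model(cpx, domain_position_map={10: 0})
        assert derivation.pair_model.pairs == ((0, 0),)
        assert derivation.unmapped == (20,)

    def test_reference_complex_yields_38_pairs_over_16_positions(
        self, reference_pair_model
    ):
        assert len(reference_pair_model) == 38
        assert reference_pair_model.n_domain_positions() == 16
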