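"""Distance-based selection of peptide-contacting PDZ residues.

Given one or more structures of the same PDZ domain bound to a peptide, a
(domain residue, peptide residue) pair is a contact when its distance —
averaged over the models of each complex (all NMR models, all crystal
copies supplied) — is at or below a threshold *in every complex* of that
domain.  Three residue-residue distance measures are supported: Cα-Cα,
mass-weighted centre-of-mass, and minimal atom distance.  A grid sweep over
measures and thresholds (0-40 Å) against a reference residue selection
identifies the best-matching rule; the minimal-atom distance at 5 Å is the
reference configuration used to derive the default position-pair model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import ComplexStructure, StructureError
from .model import PEPTIDE_WINDOW, PositionPairModel

METRICS = ("min_atom", "c_alpha", "center_of_mass")

#: Atomic masses (Da) for centre-of-mass computation over heavy atoms.
_ELEMENT_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974,
    "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}
_DEFAULT_MASS = 12.011


class MetricError(ValueError):
    """The requested distance measure is not applicable to a residue pair."""


@dataclass(frozen=True)
class ContactConfig:
    """A distance measure plus a threshold in Å (0-40)."""

    metric: str = "min_atom"
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if not 0 <= self.threshold <= 40:
            raise ValueError(f"threshold {self.threshold} outside [0, 40] Å")


def residue_distance(res_a, res_b, metric: str) -> float:
    """Distance in Å between two residues given as biotite AtomArrays."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if len(res_a) == 0 or len(res_b) == 0:
        raise MetricError("empty residue")
    if metric == "c_alpha":
        ca_a = res_a[res_a.atom_name == "CA"]
        ca_b = res_b[res_b.atom_name == "CA"]
        if len(ca_a) == 0 or len(ca_b) == 0:
            raise MetricError("Cα atom missing; c_alpha metric not applicable")
        return float(np.linalg.norm(ca_a.coord[0] - ca_b.coord[0]))
    if metric == "center_of_mass":
        return float(np.linalg.norm(_center_of_mass(res_a) - _center_of_mass(res_b)))
    # min_atom
    return float(cdist(res_a.coord, res_b.coord).min())


def _center_of_mass(res) -> np.ndarray:
    heavy = res[res.element != "H"]
    if len(heavy) == 0:
        heavy = res
    masses = np.array(
        [_ELEMENT_MASS.get(e.upper(), _DEFAULT_MASS) for e in heavy.element]
    )
    return (heavy.coord * masses[:, None]).sum(axis=0) / masses.sum()


def pair_mean_distances(
    complex_: ComplexStructure, metric: str
) -> dict[tuple[int, int], float]:
    """Mean distance over all models of one complex for every
    (domain residue id, peptide residue id) pair."""
    domain_ids = complex_.domain_residue_ids()
    peptide_ids = complex_.peptide_residue_ids()
    sums: dict[tuple[int, int], float] = {
        (d, p): 0.0 for d in domain_ids for p in peptide_ids
    }
    for model in range(complex_.n_models):
        for d in domain_ids:
            res_d = complex_.residue_atoms(model, complex_.domain_chain, d)
            for p in peptide_ids:
                res_p = complex_.residue_atoms(model, complex_.peptide_chain, p)
                sums[(d, p)] += residue_distance(res_d, res_p, metric)
    n = complex_.n_models
    return {key: total / n for key, total in sums.items()}


def complex_contact_pairs(
    complex_: ComplexStructure, config: ContactConfig
) -> set[tuple[int, int]]:
    """(domain residue id, peptide residue id) pairs whose model-averaged
    distance is at or below the threshold, for a single complex."""
    means = pair_mean_distances(complex_, config.metric)
    return {pair for pair, dist in means.items() if dist <= config.threshold}


@dataclass
class ContactSelection:
    """Consensus contacts of one PDZ domain across its complexes.

    ``selected`` holds (domain residue id, peptide offset) pairs, the offset
    counting 0 for p0 and negative upstream.  ``per_complex_means`` records
    the model-averaged distance of every selected pair in every complex.
    """

    pdz_id: str
    selected: set[tuple[int, int]] = field(default_factory=set)
    per_complex_means: dict[str, dict[tuple[int, int], float]] = field(
        default_factory=dict
    )

    def domain_residues(self) -> set[int]:
        return {d for d, _ in self.selected}


def consensus_selection(
    complexes: Sequence[ComplexStructure],
    config: ContactConfig,
    pdz_id: str = "",
    residue_maps: Sequence[Mapping[int, int]] | None = None,
    pooled: bool = False,
) -> ContactSelection:
    """Contacts accepted in *all* complexes of one PDZ domain.

    A (domain residue, peptide offset) pair is selected iff its per-complex
    mean distance is at or below the threshold in every complex.  Domain
    residues are matched across complexes by author numbering unless
    *residue_maps* supplies, per complex, a mapping from author residue
    number to a shared numbering (e.g. alignment columns).  Peptide residues
    are matched by their offset from the C-terminus.

    With ``pooled=True`` the alternative reading is used: the grand mean over
    all models of all complexes is compared against the threshold once.
    """
    if not complexes:
        raise ValueError("at least one complex is required")
    if residue_maps is not None and len(residue_maps) != len(complexes):
        raise ValueError("one residue map per complex is required")

    per_complex: list[dict[tuple[int, int], float]] = []
    model_counts: list[int] = []
    for i, cpx in enumerate(complexes):
        means = pair_mean_distances(cpx, config.metric)
        mapped: dict[tuple[int, int], float] = {}
        for (d, p), dist in means.items():
            if residue_maps is not None:
                if d not in residue_maps[i]:
                    raise StructureError(
                        f"complex {cpx.name or i}: domain residue {d} has no "
                        "entry in the residue correspondence map"
                    )
                d = residue_maps[i][d]
            mapped[(d, cpx.peptide_offset(p))] = dist
        per_complex.append(mapped)
        model_counts.append(cpx.n_models)

    common = set(per_complex[0])
    for means in per_complex[1:]:
        common &= set(means)

    if pooled:
        selected = set()
        total_models = sum(model_counts)
        for pair in common:
            grand = sum(m[pair] * n for m, n in zip(per_complex, model_counts))
            if grand / total_models <= config.threshold:
                selected.add(pair)
    else:
        selected = {
            pair
            for pair in common
            if all(means[pair] <= config.threshold for means in per_complex)
        }

    names = [cpx.name or f"complex{i}" for i, cpx in enumerate(complexes)]
    return ContactSelection(
        pdz_id=pdz_id,
        selected=selected,
        per_complex_means={
            name: {pair: means[pair] for pair in selected}
            for name, means in zip(names, per_complex)
        },
    )


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity of two sets; 1.0 when both are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


DEFAULT_THRESHOLD_GRID = tuple(np.arange(0.0, 40.0 + 1e-9, 0.5))


def sweep_thresholds(
    complexes: Sequence[ComplexStructure],
    reference_selection: set[int],
    metrics: Sequence[str] = METRICS,
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    pdz_id: str = "",
) -> tuple[str, float, float]:
    """Find the (metric, threshold) whose consensus domain-residue selection
    best matches a reference residue set, by Jaccard similarity.

    Ties are broken toward the smaller threshold, then by metric order
    (min_atom, c_alpha, center_of_mass).  Returns
    ``(metric, threshold, similarity)``.
    """
    if not reference_selection:
        raise ValueError("reference selection must be non-empty")
    metric_order = {m: i for i, m in enumerate(METRICS)}
    best: tuple[str, float, float] | None = None
    for metric in metrics:
        # one distance computation per metric; thresholds are applied on top
        per_complex = [pair_mean_distances(cpx, metric) for cpx in complexes]
        offsets = [
            {p: cpx.peptide_offset(p) for p in cpx.peptide_residue_ids()}
            for cpx in complexes
        ]
        for threshold in thresholds:
            selections = []
            for means, off in zip(per_complex, offsets):
                selections.append(
                    {(d, off[p]) for (d, p), dist in means.items() if dist <= threshold}
                )
            consensus = set.intersection(*selections) if selections else set()
            residues = {d for d, _ in consensus}
            sim = jaccard(residues, reference_selection)
            key = (-sim, threshold, metric_order[metric])
            if best is None or key < (-best[2], best[1], metric_order[best[0]]):
                best = (metric, float(threshold), sim)
    assert best is not None
    return best


@dataclass
class PairDerivation:
    """Outcome of deriving a position-pair model from a reference complex.

    ``pair_model`` covers contacts within the modelled peptide window
    (p0..p-4); ``domain_residues`` lists, ascending, the author residue
    numbers assigned to profile positions 0..n-1; ``upstream_contacts``
    reports contacts to peptide residues upstream of p-4, which are excluded
    from the model; ``unmapped`` lists contact residues absent from an
    explicitly supplied position map.
    """

    pair_model: PositionPairModel
    domain_residues: tuple[int, ...]
    upstream_contacts: tuple[tuple[int, int], ...]
    unmapped: tuple[int, ...] = ()


def derive_position_pair_model(
    reference_complex: ComplexStructure,
    config: ContactConfig = ContactConfig("min_atom", 5.0),
    domain_position_map: Mapping[int, int] | None = None,
) -> PairDerivation:
    """Derive the position-pair model from contacts in a reference complex.

    All (domain residue, peptide residue) contacts under *config* are mapped
    to (profile position index, peptide offset) pairs.  Contacts touching
    peptide residues upstream of p-4 are reported separately and excluded.
    Without an explicit *domain_position_map* the contacting domain residues
    themselves define the profile positions, in ascending residue order.
    """
    peptide_ids = reference_complex.peptide_residue_ids()
    if len(peptide_ids) > 10:
        raise StructureError(
            f"peptide chain has {len(peptide_ids)} residues; expected a short "
            "C-terminal peptide (<= 10)"
        )
    contacts = complex_contact_pairs(reference_complex, config)
    in_window: list[tuple[int, int]] = []
    upstream: list[tuple[int, int]] = []
    for d, p in sorted(contacts):
        offset = reference_complex.peptide_offset(p)
        if offset <= -PEPTIDE_WINDOW:
            upstream.append((d, offset))
        else:
            in_window.append((d, offset))

    unmapped: list[int] = []
    if domain_position_map is None:
        residues = tuple(sorted({d for d, _ in in_window}))
        index_of = {d: i for i, d in enumerate(residues)}
    else:
        residues = tuple(sorted(set(domain_position_map)))
        index_of = dict(domain_position_map)
        unmapped = sorted({d for d, _ in in_window if d not in index_of})
        in_window = [(d, o) for d, o in in_window if d in index_of]

    pairs = tuple(sorted({(index_of[d], o) for d, o in in_window}))
    if not pairs:
        warnings.warn("no contacts within the modelled peptide window")
    return PairDerivation(
        pair_model=PositionPairModel(pairs=pairs),
        domain_residues=residues,
        upstream_contacts=tuple(upstream),
        unmapped=tuple(unmapped),
    )
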