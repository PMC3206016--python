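"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be emulated offline: binary
domain x peptide interaction matrices drawn from a planted additive
sub-score model with label noise, proteomes with a controlled fraction of
planted PDZ-binding C-termini, toy two-chain complexes with planted
sub-threshold contacts, and 1:1 binding titrations with noise.  All
generators are deterministic under a fixed integer seed and emit a
ground-truth manifest sufficient to score downstream recovery.

Default study conditions (chosen once; see the methods note):

* planted sub-scores are zero-inflated Gaussian — two thirds of the
  combinations neutral, mirroring the sparse coverage of a trained table,
  the rest N(0, 0.5), the scale of decisive single-position contributions;
* the planted decision threshold is 0.5, the predictor's hit cutoff;
* peptide p0 residues are drawn from the hydrophobic set V, L, I, F, C, A
  with weight 0.9, as in pools of experimentally confirmed PDZ binders;
* titrations use nine analyte concentrations spanning 0.12-30 µM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc

from .io import (
    AMINO_ACIDS,
    ComplexStructure,
    InteractionDataset,
    InteractionRecord,
    ProteinRecord,
    SequenceError,
)
from .model import PEPTIDE_WINDOW, PositionPairModel, SubscoreTable
from .spr import BindingCurve, isotherm

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residues seen at p0 in the pool of peptides used to train the upstream
#: predictor (all experimentally binding peptides).
P0_TRAINING_POOL = "VLIFCA"

#: Default fraction of planted sub-score combinations left neutral.
NEUTRAL_FRACTION = 2.0 / 3.0

#: Standard deviation of non-neutral planted sub-scores.
SUBSCORE_SCALE = 0.5

#: Default analyte concentration series (µM): nine injections up to 30 µM.
DEFAULT_CONCENTRATIONS_UM = (0.12, 0.37, 1.11, 3.33, 5.0, 10.0, 15.0, 22.0, 30.0)


class GenerationError(RuntimeError):
    """A generator produced a degenerate dataset (e.g. an empty class)."""


@dataclass(frozen=True)
class SimulationSpec:
    """Reproducibility envelope for the generators: identical specs give
    bitwise-identical outputs."""

    seed: int = 0
    n_domains: int = 200
    n_peptides: int = 200
    motif_fraction: float = 0.1
    label_noise: float = 0.05
    titration_noise: float = 0.03

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


@dataclass
class PlantedModel:
    """The generating truth behind a synthetic interaction matrix."""

    subscore_table: SubscoreTable
    pair_model: PositionPairModel
    decision_threshold: float = 0.5
    label_noise: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")

    def dense_table(self) -> np.ndarray:
        """(n_pairs, 20, 20) array view of the planted table; absent
        combinations are exactly 0.0."""
        arr = np.zeros((len(self.pair_model), 20, 20))
        for (i, a, b), v in self.subscore_table.entries.items():
            arr[i, _AA_INDEX[a], _AA_INDEX[b]] = v
        return arr


def plant_subscore_table(
    pair_model: PositionPairModel,
    seed: int,
    neutral_fraction: float = NEUTRAL_FRACTION,
    scale: float = SUBSCORE_SCALE,
) -> SubscoreTable:
    """Draw a planted table: each combination is neutral (absent) with
    probability *neutral_fraction*, otherwise N(0, scale)."""
    rng = np.random.default_rng(seed)
    n_pairs = len(pair_model)
    active = rng.random((n_pairs, 20, 20)) >= neutral_fraction
    values = rng.normal(0.0, scale, (n_pairs, 20, 20))
    entries = {}
    for i in range(n_pairs):
        for ai in range(20):
            for bi in range(20):
                if active[i, ai, bi]:
                    entries[(i, AMINO_ACIDS[ai], AMINO_ACIDS[bi])] = float(
                        values[i, ai, bi]
                    )
    return SubscoreTable(entries)


def random_profiles(
    n_domains: int, n_positions: int, rng: np.random.Generator
) -> dict[str, str]:
    """Uniform-alphabet domain profiles keyed by synthetic PDZ ids."""
    letters = rng.integers(0, 20, size=(n_domains, n_positions))
    return {
        f"SYND{i:04d}-1/1": "".join(_AA[row]) for i, row in enumerate(letters)
    }


def random_peptides(
    n_peptides: int,
    rng: np.random.Generator,
    length: int = PEPTIDE_WINDOW,
    p0_pool: str = P0_TRAINING_POOL,
    p0_weight: float = 0.9,
) -> list[str]:
    """Uniform-alphabet peptides whose p0 residue is drawn from the
    hydrophobic pool with probability *p0_weight*."""
    body = rng.integers(0, 20, size=(n_peptides, length))
    peptides = []
    pool = list(p0_pool)
    for row in body:
        pep = "".join(_AA[row])
        if rng.random() < p0_weight:
            pep = pep[:-1] + pool[rng.integers(0, len(pool))]
        peptides.append(pep)
    return peptides


def score_matrix(
    planted: PlantedModel,
    profiles: Mapping[str, str],
    peptides: Sequence[str],
) -> np.ndarray:
    """True additive scores for every (domain, peptide) pair.

    Sub-scores are accumulated pair by pair in model order, so each entry
    equals, bit for bit, the sum computed by the scalar scoring routine.
    """
    prof_ids = list(profiles)
    prof_idx = np.array(
        [[_AA_INDEX[c] for c in profiles[p]] for p in prof_ids]
    )
    pep_idx = np.array(
        [[_AA_INDEX[c] for c in pep[-PEPTIDE_WINDOW:]] for pep in peptides]
    )
    dense = planted.dense_table()
    scores = np.zeros((len(prof_ids), len(peptides)))
    for i, (d, o) in enumerate(planted.pair_model.pairs):
        scores += dense[i][prof_idx[:, d][:, None], pep_idx[:, PEPTIDE_WINDOW - 1 + o]]
    return scores


@dataclass
class TrainingSimulation:
    """A synthetic interaction matrix with its generating truth."""

    profiles: dict[str, str]
    peptides: list[str]
    positives: InteractionDataset
    negatives: InteractionDataset
    true_scores: np.ndarray  # (n_domains, n_peptides)
    true_labels: np.ndarray  # bool, before label noise
    observed_labels: np.ndarray  # bool, after label noise
    planted: PlantedModel

    def manifest(self) -> dict:
        """JSON-serialisable ground truth for downstream recovery scoring."""
        ids = list(self.profiles)
        return {
            "domains": ids,
            "peptides": self.peptides,
            "decision_threshold": self.planted.decision_threshold,
            "label_noise": self.planted.label_noise,
            "true_scores": self.true_scores.tolist(),
            "true_labels": self.true_labels.astype(int).tolist(),
            "observed_labels": self.observed_labels.astype(int).tolist(),
        }


def simulate_training_data(
    planted: PlantedModel,
    n_domains: int,
    n_peptides: int,
    seed: int,
) -> TrainingSimulation:
    """Generate a labelled domain x peptide interaction matrix.

    Profiles and peptides are random; the true score of each pair comes from
    the planted additive model; the true label is (score > threshold),
    flipped with probability ``planted.label_noise``.  Raises
    :class:`GenerationError` if either class ends up empty.
    """
    rng = np.random.default_rng(seed)
    n_positions = planted.pair_model.n_domain_positions()
    profiles = random_profiles(n_domains, n_positions, rng)
    peptides = random_peptides(n_peptides, rng)
    scores = score_matrix(planted, profiles, peptides)
    true_labels = scores > planted.decision_threshold
    flips = rng.random(true_labels.shape) < planted.label_noise
    observed = np.logical_xor(true_labels, flips)

    pos_records, neg_records = [], []
    for i, pdz_id in enumerate(profiles):
        for j, pep in enumerate(peptides):
            rec = InteractionRecord(
                pdz_id=pdz_id,
                binder_name=f"pep{j:04d}",
                cterm_seq=pep,
                label="positive" if observed[i, j] else "negative_motif",
            )
            (pos_records if observed[i, j] else neg_records).append(rec)
    if not pos_records or not neg_records:
        raise GenerationError(
            "one label class is empty; lower |decision_threshold| or increase "
            "the matrix size so both interactions and non-interactions occur"
        )
    return TrainingSimulation(
        profiles=profiles,
        peptides=peptides,
        positives=InteractionDataset(pos_records),
        negatives=InteractionDataset(neg_records),
        true_scores=scores,
        true_labels=true_labels,
        observed_labels=observed,
        planted=planted,
    )


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------


@dataclass
class ProteomeSimulation:
    records: list[ProteinRecord]
    planted: dict[str, str]  # accession -> planted C-terminal motif

    def manifest(self) -> dict:
        return {"planted": self.planted, "n_proteins": len(self.records)}


def simulate_proteome(
    n_proteins: int,
    motif_fraction: float,
    motif_pool: Sequence[str],
    seed: int,
    length_range: tuple[int, int] = (50, 400),
) -> ProteomeSimulation:
    """Random protein sequences, a known fraction ending with motifs drawn
    from *motif_pool*."""
    rng = np.random.default_rng(seed)
    n_planted = int(round(motif_fraction * n_proteins))
    if motif_fraction > 0 and n_planted < 1:
        raise GenerationError("motif_fraction * n_proteins must be >= 1")
    if n_planted > 0 and not motif_pool:
        raise ValueError("motif_pool must be non-empty when planting binders")
    planted_idx = set(
        rng.choice(n_proteins, size=n_planted, replace=False).tolist()
    )
    records, planted = [], {}
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(_AA[rng.integers(0, 20, size=length)])
        accession = f"SYNP{i:05d}"
        if i in planted_idx:
            motif = motif_pool[int(rng.integers(0, len(motif_pool)))]
            seq = seq[: -len(motif)] + motif
            planted[accession] = motif
        records.append(ProteinRecord(accession=accession, sequence=seq))
    return ProteomeSimulation(records=records, planted=planted)


# ---------------------------------------------------------------------------
# Complexes
# ---------------------------------------------------------------------------

#: Canonical synthetic contact geometry: 38 (domain residue, peptide offset)
#: contacts over 16 domain residues and the p0..p-4 window, echoing the
#: pocket layout in which p0 and p-2 touch the most domain positions.
DEFAULT_CONTACT_GEOMETRY: tuple[tuple[int, int, float], ...] = tuple(
    (d, o, round(3.0 + 0.045 * k, 3))
    for k, (d, o) in enumerate(
        [(d, 0) for d in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)]
        + [(d, -1) for d in (3, 5, 7, 9, 11)]
        + [(d, -2) for d in (2, 4, 6, 8, 10, 12, 13, 14, 15, 16)]
        + [(d, -3) for d in (1, 4, 7, 10, 13, 16)]
        + [(d, -4) for d in (2, 6, 9, 12, 14, 15)]
        + [(16, -4)]
    )
)

_PEPTIDE_SPACING = 20.0  # Å between synthetic peptide residues


def simulate_complex(
    geometry: Iterable[tuple[int, int, float]],
    peptide_length: int = PEPTIDE_WINDOW,
    n_models: int = 1,
    jitter: float = 0.0,
    seed: int = 0,
    extra_domain_residues: Sequence[int] = (),
    decoy_atoms: int = 0,
    ca_offset: float = 0.0,
    domain_chain: str = "A",
    peptide_chain: str = "B",
    name: str = "synthetic",
) -> ComplexStructure:
    """Build a synthetic two-chain complex with planted contact distances.

    *geometry* lists ``(domain_residue_id, peptide_offset, distance_A)``
    constraints; with zero jitter the realised minimal atom distance of each
    listed pair equals its target exactly, and every unlisted
    domain-peptide residue pair is farther than 40 Å... more precisely, at
    least the peptide spacing (20 Å) away, so it is never selected at the
    thresholds of interest.  A domain residue listed against several peptide
    offsets receives one atom per contact (multi-atom residues are how real
    side chains touch several peptide positions at once).  ``decoy_atoms``
    adds per-residue far-side atoms to exercise minimal-atom searches.
    With ``ca_offset > 0`` each domain residue gets a dedicated Cα atom
    displaced *ca_offset* Å farther from the peptide (the contact atoms
    become side-chain atoms), so Cα and minimal-atom distances deliberately
    disagree.
    """
    geometry = list(geometry)
    seen: dict[tuple[int, int], float] = {}
    for d, o, dist in geometry:
        if dist < 0:
            raise ValueError(f"negative target distance for ({d}, {o})")
        if not -(peptide_length - 1) <= o <= 0:
            raise ValueError(
                f"peptide offset {o} outside chain of length {peptide_length}"
            )
        if (d, o) in seen and seen[(d, o)] != dist:
            raise ValueError(
                f"conflicting distances for domain residue {d} vs offset {o}"
            )
        seen[(d, o)] = dist

    # peptide spine along z; residue id j has offset j - peptide_length
    pep_z = {o: -_PEPTIDE_SPACING * (-o) for o in range(-(peptide_length - 1), 1)}

    atoms: list[tuple[str, int, str, np.ndarray]] = []  # chain, res_id, name, coord
    for o in sorted(pep_z):
        res_id = o + peptide_length
        atoms.append((peptide_chain, res_id, "CA", np.array([0.0, 0.0, pep_z[o]])))
        for k in range(decoy_atoms):
            atoms.append(
                (
                    peptide_chain,
                    res_id,
                    f"D{k+1}",
                    np.array([-(5.0 + 5.0 * k), 0.0, pep_z[o]]),
                )
            )

    # domain contact atoms: one per constraint, angular spread per peptide residue
    by_offset: dict[int, list[tuple[int, float]]] = {}
    for (d, o), dist in sorted(seen.items()):
        by_offset.setdefault(o, []).append((d, dist))
    domain_atoms: dict[int, list[tuple[str, np.ndarray]]] = {}
    for o, entries in by_offset.items():
        for k, (d, dist) in enumerate(entries):
            # spread contacts on a quarter arc on the +x side
            angle = (np.pi / 2) * (k / max(len(entries) - 1, 1) - 0.5) * 0.9
            coord = np.array(
                [dist * np.cos(angle), dist * np.sin(angle), pep_z[o]]
            )
            domain_atoms.setdefault(d, []).append(("", coord))
    for d in sorted(domain_atoms):
        base = domain_atoms[d][0][1]
        if ca_offset > 0:
            direction = base.copy()
            direction[2] = 0.0
            direction /= np.linalg.norm(direction)
            atoms.append((domain_chain, d, "CA", base + ca_offset * direction))
            names = [f"C{k+1}" for k in range(len(domain_atoms[d]))]
        else:
            names = ["CA"] + [f"C{k+1}" for k in range(1, len(domain_atoms[d]))]
        for name, (_, coord) in zip(names, domain_atoms[d]):
            atoms.append((domain_chain, d, name, coord))
        for k in range(decoy_atoms):
            atoms.append(
                (domain_chain, d, f"E{k+1}", base + np.array([5.0 + 5.0 * k, 0.0, 0.0]))
            )
    for d in extra_domain_residues:
        if d in domain_atoms:
            raise ValueError(f"extra domain residue {d} is also in the geometry")
        atoms.append((domain_chain, d, "CA", np.array([200.0, 0.0, -10.0 * d])))

    n = len(atoms)
    array = struc.AtomArray(n)
    array.chain_id = np.array([a[0] for a in atoms])
    array.res_id = np.array([a[1] for a in atoms])
    array.res_name = np.array(["ALA"] * n)
    array.atom_name = np.array([a[2] for a in atoms])
    array.element = np.array(["C"] * n)
    array.hetero = np.zeros(n, dtype=bool)
    base_coord = np.array([a[3] for a in atoms])

    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        arr = array.copy()
        arr.coord = base_coord + (
            rng.normal(0.0, jitter, base_coord.shape) if jitter > 0 else 0.0
        )
        models.append(arr)
    stack = struc.stack(models)
    return ComplexStructure(
        atoms=stack,
        domain_chain=domain_chain,
        peptide_chain=peptide_chain,
        name=name,
    )


def reference_complex() -> ComplexStructure:
    """The canonical synthetic reference complex: 16 domain residues making
    38 contacts to a five-residue peptide, all under 5 Å."""
    return simulate_complex(DEFAULT_CONTACT_GEOMETRY, name="reference")


def reference_pair_model() -> PositionPairModel:
    """The default position-pair model, derived from the synthetic reference
    complex with the minimal-atom 5 Å rule (38 pairs over 16 positions)."""
    from .contacts import ContactConfig, derive_position_pair_model

    derivation = derive_position_pair_model(
        reference_complex(), ContactConfig("min_atom", 5.0)
    )
    return derivation.pair_model


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------


def simulate_binding_curve(
    kd_uM: float,
    rmax_RU: float,
    concentrations_uM: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    noise_sd_fraction: float = 0.03,
    noise_sd_RU: float = 0.0,
    seed: int = 0,
    ligand_id: str = "peptide",
    analyte_id: str = "PDZ",
    analyte_mw: float = 55000.0,
    immobilized_level: float = 200.0,
) -> BindingCurve:
    """A noisy 1:1 titration: Req = Rmax*C/(Kd+C) plus multiplicative
    Gaussian noise of sd ``noise_sd_fraction * Req`` and optional additive
    noise of sd ``noise_sd_RU``."""
    if kd_uM <= 0 or rmax_RU <= 0:
        raise ValueError("Kd and Rmax must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations_uM, dtype=float)
    clean = isotherm(conc, rmax_RU, kd_uM)
    noisy = clean + rng.normal(0.0, 1.0, conc.shape) * noise_sd_fraction * clean
    if noise_sd_RU > 0:
        noisy = noisy + rng.normal(0.0, noise_sd_RU, conc.shape)
    return BindingCurve(
        ligand_id=ligand_id,
        analyte_id=analyte_id,
        concentrations_uM=conc,
        responses_RU=noisy,
        analyte_mw=analyte_mw,
        immobilized_level=immobilized_level,
    )


def make_short_construct(cterm10: str) -> str:
    """Short peptide construct: GSGAG followed by the last five wild-type
    residues (e.g. VMRLQSETSV -> GSGAGSETSV)."""
    if len(cterm10) < PEPTIDE_WINDOW:
        raise SequenceError(
            f"need at least {PEPTIDE_WINDOW} residues, got {len(cterm10)}"
        )
    return "GSGAG" + cterm10[-PEPTIDE_WINDOW:]


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1))
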