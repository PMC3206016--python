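"""Readers and writers for the standard inputs of the pipeline.

Handles three-column interaction/non-interaction tables, plain and aligned
FASTA, and two-chain PDZ-peptide complex structures in PDB format.

Position convention used throughout the package: peptide positions are
counted from the C-terminus, which is position p0; the residue immediately
upstream is p-1, and so on.  Sequences are always stored N-to-C, so the
*last* character of a stored peptide is p0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from biotite.structure import AtomArrayStack, stack as _stack
from biotite.structure.io.pdb import PDBFile

#: The standard 20-letter amino-acid alphabet.  Non-standard letters such as
#: "X" or "U" are rejected at parse time because sub-score tables are indexed
#: by this alphabet only.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Valid labels for interaction records: genuine interactions, literature
#: non-interactions whose peptide still carries a PDZ-binding motif, and
#: non-interactions whose motif was disrupted.
LABELS = ("positive", "negative_motif", "negative_nomotif")

_PDZ_ID_RE = re.compile(r"^(?P<protein>.+)-(?P<index>\d+)/(?P<total>\d+)$")


class DatasetParseError(ValueError):
    """A dataset file line could not be parsed."""


class SequenceError(ValueError):
    """A sequence violates the amino-acid alphabet or length contract."""


class StructureError(ValueError):
    """A coordinate file does not satisfy the two-chain complex contract."""


def parse_pdz_id(pdz_id: str) -> tuple[str, int, int]:
    """Split a domain identifier like ``"MAGI1-2/6"`` into
    ``(protein, domain_index, total_domains)``."""
    match = _PDZ_ID_RE.match(pdz_id)
    if match is None:
        raise DatasetParseError(
            f"PDZ identifier {pdz_id!r} is not of the form PROTEIN-i/n"
        )
    return match["protein"], int(match["index"]), int(match["total"])


def validate_peptide(seq: str, *, context: str = "peptide") -> str:
    """Check that *seq* is a non-empty uppercase 20-letter amino-acid string."""
    if not seq:
        raise SequenceError(f"{context}: empty sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise SequenceError(
            f"{context}: illegal amino-acid character(s) {sorted(bad)} in {seq!r}"
        )
    return seq


@dataclass(frozen=True)
class InteractionRecord:
    """One labelled (PDZ domain, C-terminal peptide) pair."""

    pdz_id: str
    binder_name: str
    cterm_seq: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        validate_peptide(self.cterm_seq, context=f"{self.pdz_id}/{self.binder_name}")
        parse_pdz_id(self.pdz_id)

    @property
    def p0(self) -> str:
        """C-terminal residue of the peptide."""
        return self.cterm_seq[-1]


@dataclass
class InteractionDataset:
    """An ordered collection of :class:`InteractionRecord`."""

    records: list[InteractionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def pdz_ids(self) -> set[str]:
        return {r.pdz_id for r in self.records}

    def pairs(self) -> list[tuple[str, str]]:
        """(pdz_id, peptide) keys in file order."""
        return [(r.pdz_id, r.cterm_seq) for r in self.records]


@dataclass(frozen=True)
class ProteinRecord:
    """A proteome entry; only the C-terminal residues are ever scored."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.accession}: empty sequence")


def read_interaction_dataset(path: str | Path, label: str) -> InteractionDataset:
    """Read a three-column interaction table (PDZ id, binder name, C-terminus).

    Lines starting with ``#`` and blank lines are skipped; columns beyond the
    third are ignored.  *label* is applied uniformly to all records.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise DatasetParseError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}"
                )
            try:
                records.append(
                    InteractionRecord(
                        pdz_id=fields[0],
                        binder_name=fields[1],
                        cterm_seq=fields[2],
                        label=label,
                    )
                )
            except (SequenceError, DatasetParseError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return InteractionDataset(records)


def write_interaction_dataset(dataset: InteractionDataset, path: str | Path) -> None:
    """Write a dataset back to the three-column tab-separated layout."""
    with open(path, "w") as fh:
        fh.write("# pdz_id\tbinder_name\tcterm_seq\n")
        for rec in dataset:
            fh.write(f"{rec.pdz_id}\t{rec.binder_name}\t{rec.cterm_seq}\n")


def extract_cterm(protein: ProteinRecord | str, k: int) -> str:
    """Return the last *k* residues of a protein, N-to-C (rightmost is p0)."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise SequenceError(
            f"sequence of length {len(seq)} is shorter than requested k={k}"
        )
    return seq[-k:]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a plain FASTA proteome into :class:`ProteinRecord` entries."""
    return [
        ProteinRecord(accession=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file (gap character ``-``) as id -> row."""
    alignment = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        alignment[rec.id] = str(rec.seq).upper()
    if not alignment:
        raise DatasetParseError(f"{path}: no sequences found")
    widths = {len(s) for s in alignment.values()}
    if len(widths) != 1:
        raise DatasetParseError(f"{path}: rows have differing widths {sorted(widths)}")
    return alignment


# ---------------------------------------------------------------------------
# PDB complexes
# ---------------------------------------------------------------------------


@dataclass
class ComplexStructure:
    """A PDZ-peptide complex: a multi-model two-chain coordinate set.

    All models of an NMR ensemble are retained; X-ray files with several
    complex copies in the asymmetric unit must be split into per-copy files
    (or chain pairs) by the caller.  Alternate locations are resolved to the
    highest-occupancy conformer at parse time.
    """

    atoms: AtomArrayStack
    domain_chain: str
    peptide_chain: str
    name: str = ""

    @property
    def n_models(self) -> int:
        return self.atoms.stack_depth()

    def _chain_residue_ids(self, chain: str) -> list[int]:
        mask = self.atoms.chain_id == chain
        res_ids = self.atoms.res_id[mask]
        return sorted(set(int(r) for r in res_ids))

    def domain_residue_ids(self) -> list[int]:
        """Author residue numbers of the domain chain, ascending."""
        return self._chain_residue_ids(self.domain_chain)

    def peptide_residue_ids(self) -> list[int]:
        """Author residue numbers of the peptide chain, ascending; the last
        one is the C-terminal residue p0."""
        return self._chain_residue_ids(self.peptide_chain)

    def peptide_offset(self, res_id: int) -> int:
        """Peptide position of a peptide-chain residue: 0 for p0, -1 for the
        residue upstream, etc."""
        ids = self.peptide_residue_ids()
        if res_id not in ids:
            raise StructureError(
                f"residue {res_id} not in peptide chain {self.peptide_chain}"
            )
        return ids.index(res_id) - (len(ids) - 1)

    def residue_atoms(self, model: int, chain: str, res_id: int):
        """AtomArray of one residue in one 0-based model."""
        arr = self.atoms[model]
        return arr[(arr.chain_id == chain) & (arr.res_id == res_id)]


def read_complex(
    path: str | Path, domain_chain: str, peptide_chain: str
) -> ComplexStructure:
    """Read a PDB file as a two-chain domain-peptide complex.

    All models in the file are retained.  Files that do not contain
    coordinates for both requested chains are rejected, mirroring the
    exclusion of single-chain entries from structural analyses.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(altloc="occupancy")
    if not isinstance(atoms, AtomArrayStack):
        atoms = _stack([atoms])  # pragma: no cover
    present = set(atoms.chain_id)
    for chain in (domain_chain, peptide_chain):
        if chain not in present:
            raise StructureError(
                f"{path}: chain {chain!r} absent; file contains chains "
                f"{sorted(present)} and is not a full complex"
            )
    if domain_chain == peptide_chain:
        raise StructureError("domain and peptide chain must differ")
    return ComplexStructure(
        atoms=atoms,
        domain_chain=domain_chain,
        peptide_chain=peptide_chain,
        name=Path(path).stem,
    )


def write_complex(complex_: ComplexStructure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(complex_.atoms)
    pdb.write(str(path))
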