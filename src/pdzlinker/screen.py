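"""Proteome-wide screening for PDZ-binding C-termini.

Every protein's last five residues are scored against every domain profile;
peptides reaching the decision cutoff are hits.  Because sub-score tables
give neutral 0.0 to unseen residues, a proteome-wide scan would otherwise
accept many C-termini that violate the near-universal requirement for a
hydrophobic residue at p0 — hence an additional p0 filter (allowed residues
C, Y, F, L, I, M, V, W, A) is applied to hit lists by default, and per-domain
hit counts are reported both before and after filtering.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping

from .io import ProteinRecord
from .model import (
    DEFAULT_CUTOFF,
    PEPTIDE_WINDOW,
    PDZProfile,
    PositionPairModel,
    SubscoreTable,
    p0_filter,
    score,
)

logger = logging.getLogger(__name__)

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ScreenHit:
    """One protein whose C-terminal peptide scored at or above the cutoff
    for one domain."""

    accession: str
    peptide: str
    pdz_id: str
    score: float
    passed_p0: bool


@dataclass
class ScreenResult:
    """All hits of a proteome screen plus per-domain tallies.

    ``unfiltered_counts`` counts every hit; ``filtered_counts`` only those
    passing the p0 filter.  ``hits`` holds the hits surviving the configured
    filtering mode.
    """

    hits: list[ScreenHit]
    unfiltered_counts: dict[str, int]
    filtered_counts: dict[str, int]
    n_proteins_scored: int
    n_proteins_skipped: int
    p0_filter_applied: bool = True

    def hits_for_domain(self, pdz_id: str) -> list[ScreenHit]:
        return [h for h in self.hits if h.pdz_id == pdz_id]

    def hits_by_accession(self) -> dict[str, list[ScreenHit]]:
        grouped: dict[str, list[ScreenHit]] = defaultdict(list)
        for hit in self.hits:
            grouped[hit.accession].append(hit)
        return dict(grouped)


def screen(
    proteome: Iterable[ProteinRecord],
    profiles: Mapping[str, PDZProfile],
    table: SubscoreTable,
    pair_model: PositionPairModel,
    cutoff: float = DEFAULT_CUTOFF,
    apply_filter: bool = True,
) -> ScreenResult:
    """Score every proteome C-terminus against every profile.

    Proteins shorter than five residues or with a non-standard terminal
    window (X, *, U ...) are skipped with a logged warning.  Per-domain hit
    counts are tallied before and after the p0 filter regardless of
    *apply_filter*; the retained hit list honours *apply_filter*.
    """
    if not profiles:
        raise ValueError("at least one PDZ profile is required")
    unfiltered: Counter[str] = Counter({pdz: 0 for pdz in profiles})
    filtered: Counter[str] = Counter({pdz: 0 for pdz in profiles})
    hits: list[ScreenHit] = []
    n_scored = n_skipped = 0
    for protein in proteome:
        if len(protein.sequence) < PEPTIDE_WINDOW:
            logger.warning(
                "skipping %s: shorter than %d residues", protein.accession, PEPTIDE_WINDOW
            )
            n_skipped += 1
            continue
        peptide = protein.sequence[-PEPTIDE_WINDOW:]
        if set(peptide) - _STANDARD:
            logger.warning(
                "skipping %s: non-standard residues in C-terminal window %s",
                protein.accession,
                peptide,
            )
            n_skipped += 1
            continue
        n_scored += 1
        passes_p0 = p0_filter(peptide)
        for pdz_id, profile in profiles.items():
            result = score(profile, peptide, table, pair_model, cutoff)
            if not result.is_hit:
                continue
            unfiltered[pdz_id] += 1
            if passes_p0:
                filtered[pdz_id] += 1
            if passes_p0 or not apply_filter:
                hits.append(
                    ScreenHit(
                        accession=protein.accession,
                        peptide=peptide,
                        pdz_id=pdz_id,
                        score=result.score,
                        passed_p0=passes_p0,
                    )
                )
    return ScreenResult(
        hits=hits,
        unfiltered_counts=dict(unfiltered),
        filtered_counts=dict(filtered),
        n_proteins_scored=n_scored,
        n_proteins_skipped=n_skipped,
        p0_filter_applied=apply_filter,
    )


@dataclass
class ScoreHistogram:
    """Frequencies of scores rounded (half-even) to two decimal places."""

    pdz_id: str
    bins: dict[float, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.bins.values())


def _round2(value: float) -> float:
    return float(
        Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    )


def score_histogram(hits: Iterable[ScreenHit | float], pdz_id: str = "") -> ScoreHistogram:
    """Histogram of hit scores: the rounded two-decimal score is the bin key."""
    bins: Counter[float] = Counter()
    for hit in hits:
        value = hit if isinstance(hit, (int, float)) else hit.score
        bins[_round2(value)] += 1
    return ScoreHistogram(pdz_id=pdz_id, bins=dict(sorted(bins.items())))


def assign_best_domain(
    hits_by_accession: Mapping[str, list[ScreenHit]],
) -> dict[str, set[str]]:
    """For each protein, the domain(s) for which it scored highest.

    Exact score ties credit every tied domain, which keeps the assignment
    independent of hit ordering.
    """
    assignment: dict[str, set[str]] = {}
    for accession, hits in hits_by_accession.items():
        if not hits:
            raise ValueError(f"{accession}: no hits to assign")
        best = max(h.score for h in hits)
        assignment[accession] = {h.pdz_id for h in hits if h.score == best}
    return assignment


def best_domain_tally(assignment: Mapping[str, set[str]]) -> dict[str, int]:
    """Per-domain counts of proteins assigned to it as their best domain."""
    tally: Counter[str] = Counter()
    for domains in assignment.values():
        for pdz_id in domains:
            tally[pdz_id] += 1
    return dict(tally)


def promiscuity_counts(
    hits_by_accession: Mapping[str, list[ScreenHit]],
    domain_family: Iterable[str],
) -> dict[int, int]:
    """Numbers of proteins hitting exactly k domains of a family.

    The counts over k sum to the number of distinct proteins with at least
    one hit within the family.
    """
    family = set(domain_family)
    counts: Counter[int] = Counter()
    for hits in hits_by_accession.values():
        k = len({h.pdz_id for h in hits if h.pdz_id in family})
        if k > 0:
            counts[k] += 1
    return dict(sorted(counts.items()))
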