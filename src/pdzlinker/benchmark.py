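"""Confusion-matrix evaluation of interaction predictions.

Predictions are compared against three-way test data: positives (published
interactions), motif-bearing negatives (non-interactions whose peptide still
carries a PDZ-binding motif) and motif-less negatives (non-interactions with
a disrupted motif).  Sensitivity is reported over positives; a false positive
rate is reported separately for each negative class.  Results can further be
stratified by whether the tested domain is orthologous to a domain of the
predictor's training set, to expose training bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import InteractionDataset, InteractionRecord

NEGATIVE_CLASSES = ("negative_motif", "negative_nomotif")


class EvaluationError(ValueError):
    """Predictions or datasets violate the evaluation contract."""


class UndefinedMetricError(ZeroDivisionError):
    """A rate was requested whose denominator is zero."""


@dataclass
class BenchmarkCounts:
    """Confusion-matrix tallies, with FP/TN kept per negative class."""

    tp: int = 0
    fn: int = 0
    fp_motif: int = 0
    tn_motif: int = 0
    fp_nomotif: int = 0
    tn_nomotif: int = 0

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    def n_negatives(self, negative_class: str) -> int:
        if negative_class == "negative_motif":
            return self.fp_motif + self.tn_motif
        if negative_class == "negative_nomotif":
            return self.fp_nomotif + self.tn_nomotif
        raise ValueError(f"unknown negative class {negative_class!r}")

    @property
    def total(self) -> int:
        return self.n_positives + self.n_negatives("negative_motif") + self.n_negatives(
            "negative_nomotif"
        )

    def __add__(self, other: "BenchmarkCounts") -> "BenchmarkCounts":
        return BenchmarkCounts(
            tp=self.tp + other.tp,
            fn=self.fn + other.fn,
            fp_motif=self.fp_motif + other.fp_motif,
            tn_motif=self.tn_motif + other.tn_motif,
            fp_nomotif=self.fp_nomotif + other.fp_nomotif,
            tn_nomotif=self.tn_nomotif + other.tn_nomotif,
        )


def check_duplicates(records: Iterable[InteractionRecord]) -> None:
    """Reject duplicate (pdz, peptide) pairs with conflicting labels; warn on
    identical duplicates."""
    seen: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.pdz_id, rec.cterm_seq)
        if key in seen:
            if seen[key] != rec.label:
                raise EvaluationError(
                    f"conflicting labels for {key}: {seen[key]} vs {rec.label}"
                )
            warnings.warn(f"duplicate record {key} with label {rec.label}")
        seen[key] = rec.label


def evaluate(
    dataset: InteractionDataset,
    predictions: Mapping[tuple[str, str], bool],
) -> BenchmarkCounts:
    """Tally a dataset against binary predictions keyed by (pdz_id, peptide).

    Every record must have a prediction; positives predicted True count as
    TP, negatives predicted True as FP in their class, etc.
    """
    missing = [
        (r.pdz_id, r.cterm_seq)
        for r in dataset
        if (r.pdz_id, r.cterm_seq) not in predictions
    ]
    if missing:
        raise EvaluationError(f"missing predictions for pairs: {missing[:10]}")
    counts = BenchmarkCounts()
    for rec in dataset:
        hit = predictions[(rec.pdz_id, rec.cterm_seq)]
        if rec.label == "positive":
            if hit:
                counts.tp += 1
            else:
                counts.fn += 1
        elif rec.label == "negative_motif":
            if hit:
                counts.fp_motif += 1
            else:
                counts.tn_motif += 1
        else:  # negative_nomotif
            if hit:
                counts.fp_nomotif += 1
            else:
                counts.tn_nomotif += 1
    return counts


def sensitivity(counts: BenchmarkCounts) -> float:
    """Percentage of true interactions correctly predicted: 100*TP/(TP+FN)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("no positives evaluated")
    return 100.0 * counts.tp / denom


def false_positive_rate(counts: BenchmarkCounts, negative_class: str) -> float:
    """Percentage of non-interactions wrongly predicted: 100*FP/(FP+TN),
    within one negative class."""
    if negative_class == "negative_motif":
        fp, tn = counts.fp_motif, counts.tn_motif
    elif negative_class == "negative_nomotif":
        fp, tn = counts.fp_nomotif, counts.tn_nomotif
    else:
        raise ValueError(f"unknown negative class {negative_class!r}")
    denom = fp + tn
    if denom == 0:
        raise UndefinedMetricError(f"no {negative_class} records evaluated")
    return 100.0 * fp / denom


@dataclass
class BenchmarkResult:
    """Headline metrics for one stratum, percentages in [0, 100].

    A metric is ``None`` when its denominator is zero (no records of that
    kind in the stratum).
    """

    stratum: str
    sensitivity: float | None
    fpr_motif: float | None
    fpr_nomotif: float | None
    n_pos: int
    n_neg_motif: int
    n_neg_nomotif: int

    @classmethod
    def from_counts(cls, counts: BenchmarkCounts, stratum: str = "all") -> "BenchmarkResult":
        def _maybe(fn, *args):
            try:
                return fn(*args)
            except UndefinedMetricError:
                return None

        return cls(
            stratum=stratum,
            sensitivity=_maybe(sensitivity, counts),
            fpr_motif=_maybe(false_positive_rate, counts, "negative_motif"),
            fpr_nomotif=_maybe(false_positive_rate, counts, "negative_nomotif"),
            n_pos=counts.n_positives,
            n_neg_motif=counts.n_negatives("negative_motif"),
            n_neg_nomotif=counts.n_negatives("negative_nomotif"),
        )


def stratify(
    dataset: InteractionDataset, ortholog_ids: Iterable[str]
) -> tuple[InteractionDataset, InteractionDataset]:
    """Partition a dataset by pdz_id membership in *ortholog_ids*.

    Returns ``(subset_in, subset_out)``; their union is the input and their
    intersection is empty.
    """
    ids = set(ortholog_ids)
    inside = InteractionDataset([r for r in dataset if r.pdz_id in ids])
    outside = InteractionDataset([r for r in dataset if r.pdz_id not in ids])
    return inside, outside


def benchmark_table(results: Iterable[BenchmarkResult]) -> pd.DataFrame:
    """Tabulate stratified results: metric rows vs. stratum columns, with
    percentages rounded to one decimal and counts alongside."""
    results = list(results)
    data = {}
    for res in results:
        data[res.stratum] = [
            None if res.sensitivity is None else round(res.sensitivity, 1),
            res.n_pos,
            None if res.fpr_motif is None else round(res.fpr_motif, 1),
            res.n_neg_motif,
            None if res.fpr_nomotif is None else round(res.fpr_nomotif, 1),
            res.n_neg_nomotif,
        ]
    index = [
        "sensitivity_pct",
        "n_positives",
        "fpr_motif_pct",
        "n_negatives_motif",
        "fpr_nomotif_pct",
        "n_negatives_nomotif",
    ]
    return pd.DataFrame(data, index=index)
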