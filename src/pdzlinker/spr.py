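"""Steady-state surface plasmon resonance (SPR) analysis.

The equilibrium response Req at each analyte concentration C is extracted by
averaging the sensorgram over a five-second window at equilibrium, then
fitted with the 1:1 Langmuir binding isotherm

    Req(C) = Rmax * C / (Kd + C)

by least squares over the total analyte concentration (no ligand-depletion
correction).  Because the highest injected concentration restricts the
largest Kd that can be measured, fits whose Kd exceeds the top concentration
— or whose fractional Kd standard error exceeds 50% — are flagged
unreliable.  For relative comparison across surfaces, equilibrium responses
are normalised by analyte molecular weight and immobilised ligand level,
both of which Req is directly proportional to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Relative Kd standard error above which a fit is flagged unreliable.
RELIABILITY_SE_FRACTION = 0.5


class FitError(RuntimeError):
    """The isotherm fit did not converge or the data are unusable."""


class InsufficientDataError(ValueError):
    """Too few points for the requested analysis."""


@dataclass
class BindingCurve:
    """A titration: equilibrium responses over analyte concentrations.

    concentrations are in µM (typically 8-10 values spanning 0-30 µM),
    responses in RU.  ``analyte_mw`` (Da) and ``immobilized_level`` (RU)
    carry the normalisation metadata of the measurement.
    """

    ligand_id: str
    analyte_id: str
    concentrations_uM: np.ndarray
    responses_RU: np.ndarray
    analyte_mw: float = np.nan
    immobilized_level: float = np.nan

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.responses_RU = np.asarray(self.responses_RU, dtype=float)
        if self.concentrations_uM.shape != self.responses_RU.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.concentrations_uM < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.responses_RU)):
            raise ValueError("responses must be finite")

    def __len__(self) -> int:
        return len(self.concentrations_uM)


def equilibrium_average(
    times_s: np.ndarray,
    signal_RU: np.ndarray,
    window_s: float = 5.0,
    t_end: float | None = None,
) -> float:
    """Average the sensorgram over a window at equilibrium.

    The window covers ``[t_end - window_s, t_end]``; *t_end* defaults to the
    end of the trace.  The window must lie within the recorded trace.
    """
    times = np.asarray(times_s, dtype=float)
    signal = np.asarray(signal_RU, dtype=float)
    if times.shape != signal.shape or times.size == 0:
        raise ValueError("times and signal must be equal-length, non-empty")
    if t_end is None:
        t_end = float(times[-1])
    t_start = t_end - window_s
    if t_start < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise ValueError(
            f"window [{t_start}, {t_end}] s outside trace "
            f"[{times[0]}, {times[-1]}] s"
        )
    mask = (times >= t_start - 1e-9) & (times <= t_end + 1e-9)
    if not mask.any():
        raise ValueError("no samples inside the averaging window")
    return float(signal[mask].mean())


def isotherm(concentration: np.ndarray, rmax: float, kd: float) -> np.ndarray:
    """1:1 Langmuir binding isotherm Req(C) = Rmax*C/(Kd + C)."""
    concentration = np.asarray(concentration, dtype=float)
    return rmax * concentration / (kd + concentration)


@dataclass
class IsothermFitResults:
    """A fitted 1:1 isotherm: estimates, uncertainties and reliability.

    ``reliable`` is False when the fitted Kd exceeds the highest injected
    concentration (extrapolation beyond the measured range) or when the
    fractional Kd standard error exceeds 50%.
    """

    curve: BindingCurve
    kd_uM: float
    rmax_RU: float
    kd_se: float
    rmax_se: float
    residual_sum: float
    reliable: bool
    unreliable_reasons: tuple[str, ...] = ()

    def predict(self, concentrations_uM: np.ndarray) -> np.ndarray:
        return isotherm(concentrations_uM, self.rmax_RU, self.kd_uM)

    def summary(self) -> str:
        lines = [
            f"Steady-state 1:1 isotherm fit: {self.curve.analyte_id} -> "
            f"{self.curve.ligand_id}",
            "-" * 58,
            f"n points:          {len(self.curve)}"
            f"  (Cmax = {self.curve.concentrations_uM.max():.3g} uM)",
            f"Kd:                {self.kd_uM:.4g} uM  (se {self.kd_se:.3g})",
            f"Rmax:              {self.rmax_RU:.4g} RU  (se {self.rmax_se:.3g})",
            f"residual sum:      {self.residual_sum:.4g} RU^2",
            f"reliable:          {self.reliable}",
        ]
        if self.unreliable_reasons:
            lines.append("flags:             " + "; ".join(self.unreliable_reasons))
        return "\n".join(lines)


class SteadyStateIsotherm:
    """1:1 steady-state binding model bound to one titration curve."""

    def __init__(self, curve: BindingCurve) -> None:
        nonzero = curve.concentrations_uM > 0
        if len(set(curve.concentrations_uM[nonzero].tolist())) < 3:
            raise InsufficientDataError(
                "at least 3 distinct non-zero concentrations are required"
            )
        self.curve = curve

    def fit(self) -> IsothermFitResults:
        conc = self.curve.concentrations_uM
        resp = self.curve.responses_RU
        rmax0 = max(float(resp.max()), 1e-6)
        kd0 = max(float(np.median(conc[conc > 0])), 1e-6)
        try:
            popt, pcov = optimize.curve_fit(
                isotherm,
                conc,
                resp,
                p0=(rmax0, kd0),
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                maxfev=10000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            raise FitError(f"isotherm fit failed: {exc}") from exc
        rmax, kd = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.diag(pcov))
        rmax_se, kd_se = float(perr[0]), float(perr[1])
        residuals = resp - isotherm(conc, rmax, kd)
        cmax = float(conc.max())
        reasons = []
        if kd > cmax:
            reasons.append(f"Kd {kd:.3g} uM exceeds Cmax {cmax:.3g} uM")
        if not np.isfinite(kd_se) or kd_se / kd > RELIABILITY_SE_FRACTION:
            reasons.append(
                f"fractional Kd se {kd_se / kd:.2g} exceeds "
                f"{RELIABILITY_SE_FRACTION}"
            )
        return IsothermFitResults(
            curve=self.curve,
            kd_uM=kd,
            rmax_RU=rmax,
            kd_se=kd_se,
            rmax_se=rmax_se,
            residual_sum=float((residuals**2).sum()),
            reliable=not reasons,
            unreliable_reasons=tuple(reasons),
        )


def fit_isotherm(curve: BindingCurve) -> IsothermFitResults:
    """Convenience wrapper: ``SteadyStateIsotherm(curve).fit()``."""
    return SteadyStateIsotherm(curve).fit()


def normalize_req(
    req_RU: float,
    analyte_mw: float,
    immobilized_level: float,
    reference: tuple[float, float],
) -> float:
    """Normalise an equilibrium response across analytes and surfaces.

    Req is directly proportional to the analyte molecular weight and to the
    amount of immobilised ligand, so responses are rescaled to a reference
    surface: ``Req * (MW_ref/MW) * (level_ref/level)``.
    """
    mw_ref, level_ref = reference
    for name, value in (
        ("analyte_mw", analyte_mw),
        ("immobilized_level", immobilized_level),
        ("reference MW", mw_ref),
        ("reference level", level_ref),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return req_RU * (mw_ref / analyte_mw) * (level_ref / immobilized_level)


def average_duplicates(values: Iterable[float]) -> float:
    """Combine replicate Req measurements (e.g. the duplicate 10 µM
    injections) by arithmetic mean."""
    values = list(values)
    if not values:
        raise InsufficientDataError("no replicate values supplied")
    return float(np.mean(values))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between prediction scores and binding signals."""

    r: float
    p_value: float
    n: int
    n_excluded: int = 0


def correlate_scores_signals(
    scores: Mapping, signals: Mapping
) -> CorrelationResult:
    """Pearson r (two-sided p) between prediction scores and measured
    signals over the pairs present in both mappings."""
    shared = sorted(set(scores) & set(signals))
    n_excluded = len(set(scores) | set(signals)) - len(shared)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared pairs for a correlation, got {len(shared)}"
        )
    x = np.array([scores[k] for k in shared], dtype=float)
    y = np.array([signals[k] for k in shared], dtype=float)
    r, p = _pearson(x, y)
    return CorrelationResult(r=r, p_value=p, n=len(shared), n_excluded=n_excluded)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r via the unit-vector distance identity r = 1 - |u - v|^2/2.

    This formulation is numerically stable near |r| = 1 and returns exactly
    +/-1.0 for (anti-)identical inputs, where the textbook dot-product form
    loses an ulp.  The two-sided p-value uses the usual t reference
    distribution with n-2 degrees of freedom.
    """
    n = len(x)
    u = x - x.mean()
    v = y - y.mean()
    norm_u, norm_v = np.linalg.norm(u), np.linalg.norm(v)
    if norm_u == 0 or norm_v == 0:
        raise InsufficientDataError("a constant input has no defined correlation")
    u = u / norm_u
    v = v / norm_v
    if float(u @ v) >= 0:
        r = 1.0 - float((u - v) @ (u - v)) / 2.0
    else:
        r = float((u + v) @ (u + v)) / 2.0 - 1.0
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, p


def heatmap_table(
    signals: Mapping[tuple[str, str], float],
    peptide_order: Sequence[str] | None = None,
    construct_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Arrange normalised signals as a peptide x PDZ-construct matrix.

    Keys of *signals* are (peptide_construct, pdz_construct).  Peptide rows
    keep their given order (short/long variants of the same protein should be
    adjacent); missing cells carry the marker ``"ND"`` (not determined).
    """
    peptides = list(peptide_order) if peptide_order is not None else sorted(
        {k[0] for k in signals}
    )
    constructs = list(construct_order) if construct_order is not None else sorted(
        {k[1] for k in signals}
    )
    data = [
        [signals.get((pep, pdz), "ND") for pdz in constructs] for pep in peptides
    ]
    return pd.DataFrame(data, index=peptides, columns=constructs)


def long_short_difference(
    signals: Mapping[tuple[str, str], float],
    protein: str,
    construct: str,
    long_suffix: str = "_10",
    short_suffix: str = "_05",
) -> float:
    """Interaction-intensity difference between the long (last ten wild-type
    residues) and short (GSGAG + last five) versions of one peptide."""
    try:
        long_v = signals[(protein + long_suffix, construct)]
        short_v = signals[(protein + short_suffix, construct)]
    except KeyError as exc:
        raise InsufficientDataError(
            f"missing long/short measurement for {protein} vs {construct}"
        ) from exc
    return float(long_v) - float(short_v)


def plot_heatmap(table: pd.DataFrame, ax=None):
    """Render a heat-map of a signal matrix; ND cells are left blank."""
    import matplotlib.pyplot as plt

    numeric = table.apply(pd.to_numeric, errors="coerce")
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.6 * len(table.columns), 1 + 0.3 * len(table))
        )
    mesh = ax.pcolormesh(numeric.to_numpy(dtype=float), cmap="viridis")
    ax.set_xticks(np.arange(len(table.columns)) + 0.5, table.columns, rotation=90)
    ax.set_yticks(np.arange(len(table)) + 0.5, table.index)
    ax.figure.colorbar(mesh, ax=ax, label="normalised Req (RU)")
    return ax
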