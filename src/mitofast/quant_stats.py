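"""Estimators and significance tests supporting the segregation analysis.

Growth rate / doubling time from OD600 curves, plate doubling time from cell
counts, fluorescence half-life from a chloramphenicol chase, relative mtDNA
copy number from qPCR Cq tables, relative growth-factor inference from
mixing-assay fractions, and the Monte-Carlo simulation-vs-measurement test
with Fisher combination across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import DecaySeries, GrowthCurve

__all__ = [
    "GrowthFit",
    "McTestResult",
    "fit_growth_rate",
    "plate_doubling_time",
    "fit_half_life",
    "qpcr_relative_cn",
    "infer_growth_factor",
    "mc_pvalue",
    "fisher_combine",
]


# ---------------------------------------------------------------------------
# growth and decay fits


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear exponential growth fit: rate r (per hour) and T_d = ln2 / r."""

    rate: float
    window: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("accepted fits require a positive growth rate")

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.rate


def _ols_loglinear(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of ln(y) regressed on t."""
    res = stats.linregress(t, np.log(y))
    return float(res.slope), float(res.rvalue) ** 2


def _auto_window(t: np.ndarray, od: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Exponential-phase heuristic: contiguous stretch with OD between twice the
    initial value and half the maximum, choosing the stretch with the best r^2
    (ties broken toward the longest, then the earliest)."""
    mask = (od >= 2.0 * od[0]) & (od <= od.max() / 2.0)
    best = None
    i = 0
    n = len(t)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i >= 4:
            sel = slice(i, j)
            slope, r2 = _ols_loglinear(t[sel], od[sel])
            key = (round(r2, 12), j - i, -i)
            if slope > 0 and (best is None or key > best[0]):
                best = (key, sel)
        i = j
    if best is None:
        return np.arange(n), (float(t[0]), float(t[-1]))  # fall back to the full curve
    sel = best[1]
    return np.arange(n)[sel], (float(t[sel][0]), float(t[sel][-1]))


def fit_growth_rate(
    curve: GrowthCurve, window: str | tuple[float, float] = "auto"
) -> GrowthFit:
    """OLS of ln(OD600) on time; returns the rate and the fit window used."""
    t = curve.times
    od = curve.od
    if window == "auto":
        idx, win = _auto_window(t, od)
    else:
        t0, t1 = window
        keep = (t >= t0) & (t <= t1)
        idx = np.flatnonzero(keep)
        win = (float(t0), float(t1))
    if len(idx) < 4:
        raise ValueError("need at least 4 points in the fit window")
    slope, r2 = _ols_loglinear(t[idx], od[idx])
    if slope <= 0:
        raise ValueError("fitted growth rate is non-positive (no exponential growth)")
    return GrowthFit(rate=slope, window=win, r_squared=r2)


def plate_doubling_time(n0: float, nf: float, hours: float) -> float:
    """Doubling time from initial and final cell counts: T_d = t * ln2 / ln(nf/n0)."""
    if n0 <= 0 or nf <= n0:
        raise ValueError("need nf > n0 > 0")
    if hours <= 0:
        raise ValueError("hours must be positive")
    return hours * math.log(2.0) / math.log(nf / n0)


def fit_half_life(series: DecaySeries) -> float:
    """Exponential-decay half-life (hours) from log-transformed medians.

    OLS slope s of ln(median) on time; half-life = ln2 / (-s).  Raises on a
    non-decaying series.
    """
    slope, _ = _ols_loglinear(series.times, series.medians)
    if slope >= 0:
        raise ValueError("series does not decay; cannot fit a half-life")
    return math.log(2.0) / (-slope)


# ---------------------------------------------------------------------------
# qPCR relative copy number


def qpcr_relative_cn(table: pd.DataFrame, reference_strain: str) -> dict[str, float]:
    """Relative mtDNA copy number per strain: COX1/ACT1 abundance vs a reference.

    Per replicate, abundance = 2^(Cq_ACT1 - Cq_COX1) (perfect efficiency);
    strain values are replicate means normalized so the reference is exactly 1.
    """
    required = {"strain", "target", "replicate", "cq"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    wide = table.pivot_table(
        index=["strain", "replicate"], columns="target", values="cq", aggfunc="mean"
    )
    for gene in ("ACT1", "COX1"):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValueError(f"every (strain, replicate) needs a {gene} Cq")
    abundance = 2.0 ** (wide["ACT1"] - wide["COX1"])
    strain_means = abundance.groupby(level="strain").mean()
    if reference_strain not in strain_means.index:
        raise ValueError(f"reference strain {reference_strain!r} absent from table")
    ref = float(strain_means.loc[reference_strain])
    out = {str(s): float(v) / ref for s, v in strain_means.items()}
    out[reference_strain] = 1.0
    return out


def infer_growth_factor(f_dark: float, generations: float) -> float:
    """Relative growth rate of the non-fluorescent strain from a mixing assay.

    Equal founder numbers grow exponentially for ``generations`` reference
    doubling times; a final non-fluorescent fraction f implies
    g_other = 1 + log2(f / (1 - f)) / G.
    """
    if not (0.0 < f_dark < 1.0):
        raise ValueError("f_dark must be strictly between 0 and 1")
    if generations <= 0:
        raise ValueError("generations must be positive")
    return 1.0 + math.log2(f_dark / (1.0 - f_dark)) / generations


# ---------------------------------------------------------------------------
# Monte-Carlo test and Fisher combination


@dataclass(frozen=True)
class McTestResult:
    """Replicate-level one-sided p-values combined with Fisher's method."""

    pvalues: tuple[float, ...]
    fisher_stat: float
    df: int
    combined_p: float

    def to_dict(self) -> dict:
        return {
            "pvalues": list(self.pvalues),
            "fisher_stat": self.fisher_stat,
            "df": self.df,
            "combined_p": self.combined_p,
        }


def mc_pvalue(
    observed: float,
    sim_values: Sequence[float],
    B: int = 10_000,
    seed: int | None = None,
    alternative: str = "sim_exceeds_obs",
) -> float:
    """Empirical one-sided p-value of one measurement against simulation runs.

    Draws B values with replacement from ``sim_values``.  For the default
    alternative ("the simulation exceeds the measurement") the p-value is the
    add-one-smoothed fraction of draws at or below the observation:
    p = (1 + #{draw <= observed}) / (B + 1); a small p means the observation
    lies below essentially the whole simulated distribution.
    """
    vals = np.asarray(sim_values, dtype=float)
    if vals.size == 0:
        raise ValueError("sim_values must not be empty")
    if np.unique(vals).size < 2:
        raise ValueError("need at least 2 distinct simulation values")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    draws = rng.choice(vals, size=B, replace=True)
    if alternative == "sim_exceeds_obs":
        extreme = int(np.sum(draws <= observed))
    elif alternative == "obs_exceeds_sim":
        extreme = int(np.sum(draws >= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + extreme) / (B + 1)


def fisher_combine(pvals: Sequence[float]) -> McTestResult:
    """Fisher's method: -2 * sum(ln p) ~ chi-square with 2k degrees of freedom."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    stat = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    combined = float(stats.chi2.sf(stat, df))
    return McTestResult(
        pvalues=tuple(float(x) for x in p), fisher_stat=stat, df=df, combined_p=combined
    )
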