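"""Orchestration of the headline comparison: FAST measurements vs simulation.

Per biological replicate the raw event table is gated, the fluorescence KDE
landmarks are located, and events are classified; the observed dark-cell
fractions are then tested against the distribution of simulated final variant
fractions (Monte-Carlo resampling per replicate, one-sided, combined across
replicates with Fisher's method).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import flow_gating as fg
from .quant_stats import McTestResult, fisher_combine, mc_pvalue
from .segregation_sim import SimConfig, SimResult, run_replicates

__all__ = ["ComparisonReport", "run_fast_report", "compare_fast_to_sim", "significance_stars"]

DEFAULT_ALPHA = 0.05
# significance tiers reported as stars in text output
_TIERS = ((0.001, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in _TIERS:
        if p < thr:
            return stars
    return "ns"


def run_fast_report(
    replicates: Sequence[pd.DataFrame],
    ratio_band: tuple[float, float] = fg.DEFAULT_RATIO_BAND,
    window_frac: float = fg.DEFAULT_WINDOW_FRAC,
    bandwidth: str | float = "auto",
) -> pd.DataFrame:
    """Gate and classify each replicate event table; one row per replicate.

    Unimodal replicates (no two-peak structure) are flagged ``excluded`` with
    NaN fractions rather than aborting the whole report.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    rows = []
    for i, events in enumerate(replicates):
        gated = fg.gate_scatter(events, ratio_band=ratio_band)
        n_debris = len(events) - len(gated)
        row: dict = {"replicate": i, "n_total": len(events), "n_debris": n_debris}
        try:
            profile = fg.estimate_kde(gated["fl1"], bandwidth=bandwidth)
            pv = fg.locate_peaks_valley(profile)
            res = fg.classify_events(gated, pv, window_frac=window_frac, n_debris=n_debris)
        except fg.UnimodalProfileError:
            row.update(
                excluded=True,
                f_dark=np.nan,
                f_het=np.nan,
                f_fluor=np.nan,
                peak_lo=np.nan,
                peak_hi=np.nan,
                valley=np.nan,
                window_lo=np.nan,
                window_hi=np.nan,
            )
            rows.append(row)
            continue
        row.update(
            excluded=False,
            f_dark=res.f_dark,
            f_het=res.f_het,
            f_fluor=res.f_fluor,
            peak_lo=pv.peak_lo,
            peak_hi=pv.peak_hi,
            valley=pv.valley,
            window_lo=res.window_lo,
            window_hi=res.window_hi,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Outcome of testing FAST dark fractions against matched simulations."""

    label: str
    observed: tuple[float, ...]
    sim_mean: float
    sim_sd: float
    sim_values: tuple[float, ...]
    test: McTestResult
    alpha: float = DEFAULT_ALPHA
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = (
            "simulation exceeds FAST" if self.test.combined_p < self.alpha else "consistent"
        )

    @property
    def stars(self) -> str:
        return significance_stars(self.test.combined_p)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "observed": list(self.observed),
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "sim_values": list(self.sim_values),
            "test": self.test.to_dict(),
            "alpha": self.alpha,
            "verdict": self.verdict,
            "stars": self.stars,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        test = McTestResult(
            pvalues=tuple(d["test"]["pvalues"]),
            fisher_stat=d["test"]["fisher_stat"],
            df=d["test"]["df"],
            combined_p=d["test"]["combined_p"],
        )
        return cls(
            label=d["label"],
            observed=tuple(d["observed"]),
            sim_mean=d["sim_mean"],
            sim_sd=d["sim_sd"],
            sim_values=tuple(d["sim_values"]),
            test=test,
            alpha=d["alpha"],
        )


def compare_fast_to_sim(
    observed_dark_fractions: Sequence[float],
    sim_config: SimConfig,
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    label: str = "",
    sim_result: SimResult | None = None,
    alternative: str = "sim_exceeds_obs",
) -> ComparisonReport:
    """Run the matched simulation and test each observed dark fraction against it.

    The comparison consumes dark (non-fluorescent) fractions after
    near-complete segregation; heteroplasmic-window events are excluded from
    both sides upstream.  A precomputed ``sim_result`` may be supplied to
    avoid re-simulating.
    """
    obs = [float(x) for x in observed_dark_fractions]
    if len(obs) == 0:
        raise ValueError("need at least one observed fraction")
    result = sim_result if sim_result is not None else run_replicates(sim_config)
    seeds = np.random.SeedSequence(seed if seed is not None else 0).generate_state(len(obs))
    pvals = [
        mc_pvalue(o, result.mean_h, B=B, seed=int(s), alternative=alternative)
        for o, s in zip(obs, seeds)
    ]
    test = fisher_combine(pvals)
    return ComparisonReport(
        label=label,
        observed=tuple(obs),
        sim_mean=result.grand_mean,
        sim_sd=result.sd,
        sim_values=tuple(float(x) for x in result.mean_h),
        test=test,
        alpha=alpha,
    )
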