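"""FAST gating: debris removal, KDE of the fluorescence channel, peak/valley
detection, and classification into dark / heteroplasmic / fluorescent fractions.

The classifier works on log10 fluorescence intensities.  After removing
debris on the FSC-H/FSC-A ratio, a Gaussian kernel density estimate of the
log10 signal is computed (Silverman's rule-of-thumb bandwidth).  The two
most prominent density maxima define the dark and fluorescent clusters; the
global density minimum strictly between them is the interpeak valley.  The
heteroplasmic window spans the valley +/- 10% of the interpeak distance, and
events are labelled dark (below), heteroplasmic (inside, bounds inclusive)
or fluorescent (above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "GatingError",
    "UnimodalProfileError",
    "KdeProfile",
    "PeakValley",
    "GatingResult",
    "validate_flow_table",
    "gate_scatter",
    "estimate_kde",
    "locate_peaks_valley",
    "classify_events",
    "dark_fraction_control",
]

GRID_POINTS = 512
DEFAULT_RATIO_BAND = (0.7, 1.3)
DEFAULT_WINDOW_FRAC = 0.10
DEFAULT_MIN_PROMINENCE = 0.05
MIN_EVENTS_FOR_KDE = 50


class GatingError(ValueError):
    """Degenerate input to the gating classifier."""


class UnimodalProfileError(GatingError):
    """Fewer than two sufficiently prominent peaks: sample looks unimodal.

    Callers should fall back to :func:`dark_fraction_control` with a
    non-fluorescent reference sample.
    """


# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class KdeProfile:
    """Kernel density estimate of log10 fluorescence."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        area = float(np.trapezoid(self.density, self.grid))
        if abs(area - 1.0) > 1e-3:
            raise ValueError(f"density must integrate to 1 (got {area:.5f})")


@dataclass(frozen=True)
class PeakValley:
    """Positions (log10 units) of the two major peaks and the interpeak valley."""

    peak_lo: float
    peak_hi: float
    valley: float

    def __post_init__(self) -> None:
        if not (self.peak_lo < self.valley < self.peak_hi):
            raise ValueError("must satisfy peak_lo < valley < peak_hi")

    @property
    def interpeak_distance(self) -> float:
        return self.peak_hi - self.peak_lo


@dataclass(frozen=True)
class GatingResult:
    """Counts and fractions from one classified event table.

    Fractions are of post-debris events; window bounds are log10 intensities.
    """

    n_total: int
    n_debris: int
    n_dark: int
    n_het: int
    n_fluor: int
    window_lo: float
    window_hi: float

    def __post_init__(self) -> None:
        if self.n_dark + self.n_het + self.n_fluor != self.n_total - self.n_debris:
            raise ValueError("class counts must sum to post-debris events")

    @property
    def n_cells(self) -> int:
        return self.n_total - self.n_debris

    @property
    def f_dark(self) -> float:
        return self.n_dark / self.n_cells

    @property
    def f_het(self) -> float:
        return self.n_het / self.n_cells

    @property
    def f_fluor(self) -> float:
        return self.n_fluor / self.n_cells

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_debris": self.n_debris,
            "n_dark": self.n_dark,
            "n_het": self.n_het,
            "n_fluor": self.n_fluor,
            "f_dark": self.f_dark,
            "f_het": self.f_het,
            "f_fluor": self.f_fluor,
            "window_lo": self.window_lo,
            "window_hi": self.window_hi,
        }


# ---------------------------------------------------------------------------
# operations


def validate_flow_table(events: pd.DataFrame) -> None:
    """Check the event-table contract: required columns, positive intensities."""
    for col in ("fsc_a", "fsc_h", "fl1"):
        if col not in events.columns:
            raise GatingError(f"event table lacks required column {col!r}")
        vals = events[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise GatingError(f"column {col!r} must be strictly positive and finite")


def gate_scatter(
    events: pd.DataFrame, ratio_band: tuple[float, float] = DEFAULT_RATIO_BAND
) -> pd.DataFrame:
    """Keep events whose fsc_h/fsc_a ratio falls inside ``ratio_band``.

    Events off the FSC-A ~ FSC-H diagonal are debris (dirt, agar).  Raises
    :class:`GatingError` if the input is empty or nothing survives.
    """
    if len(events) == 0:
        raise GatingError("empty event table")
    validate_flow_table(events)
    lo, hi = ratio_band
    if not (lo <= hi):
        raise GatingError("ratio_band must satisfy lo <= hi")
    ratio = events["fsc_h"].to_numpy(dtype=float) / events["fsc_a"].to_numpy(dtype=float)
    keep = (ratio >= lo) & (ratio <= hi)
    if not keep.any():
        raise GatingError("scatter gate removed every event (degenerate sample or band)")
    return events.loc[keep].reset_index(drop=True)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    if a <= 0:
        raise GatingError("cannot pick a bandwidth for constant data")
    return 0.9 * a * len(x) ** (-0.2)


def estimate_kde(fl1, bandwidth: str | float = "auto") -> KdeProfile:
    """Gaussian KDE of log10 intensities on a 512-point grid.

    The grid spans the data range extended by three bandwidths on either side.
    """
    x = np.asarray(fl1, dtype=float)
    if len(x) < MIN_EVENTS_FOR_KDE:
        raise GatingError(f"need at least {MIN_EVENTS_FOR_KDE} events, got {len(x)}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise GatingError("intensities must be strictly positive and finite")
    logx = np.log10(x)
    if bandwidth == "auto":
        bw = silverman_bandwidth(logx)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise GatingError("bandwidth must be positive")
    kde = stats.gaussian_kde(logx, bw_method=bw / float(np.std(logx, ddof=1)))
    grid = np.linspace(logx.min() - 3 * bw, logx.max() + 3 * bw, GRID_POINTS)
    density = kde(grid)
    return KdeProfile(grid=grid, density=density, bandwidth=bw)


def locate_peaks_valley(
    profile: KdeProfile, min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE
) -> PeakValley:
    """Find the two most prominent density maxima and the valley between them.

    Raises :class:`UnimodalProfileError` when fewer than two peaks clear the
    prominence threshold (``min_prominence_fraction`` of the density maximum).
    """
    dens = profile.density
    threshold = min_prominence_fraction * float(dens.max())
    peaks, props = signal.find_peaks(dens, prominence=threshold)
    if len(peaks) < 2:
        raise UnimodalProfileError(
            f"found {len(peaks)} peak(s) above prominence threshold; "
            "sample appears unimodal - use dark_fraction_control instead"
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    i_lo, i_hi = sorted(int(i) for i in top2)
    between = dens[i_lo + 1:i_hi]
    i_val = i_lo + 1 + int(np.argmin(between))
    return PeakValley(
        peak_lo=float(profile.grid[i_lo]),
        peak_hi=float(profile.grid[i_hi]),
        valley=float(profile.grid[i_val]),
    )


def classify_events(
    events: pd.DataFrame,
    pv: PeakValley,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    n_debris: int = 0,
) -> GatingResult:
    """Label post-debris events dark / heteroplasmic / fluorescent.

    The heteroplasmic window is centred on the valley with half-width
    ``window_frac`` times the interpeak distance, bounds inclusive (ties go
    to heteroplasmic).  ``n_debris`` is carried through for bookkeeping.
    """
    if window_frac <= 0:
        raise GatingError("window_frac must be positive")
    validate_flow_table(events)
    d = pv.interpeak_distance
    lo = pv.valley - window_frac * d
    hi = pv.valley + window_frac * d
    if lo <= pv.peak_lo or hi >= pv.peak_hi:
        raise GatingError(
            "heteroplasmic window extends beyond a peak - peaks too close together"
        )
    logx = np.log10(events["fl1"].to_numpy(dtype=float))
    n_dark = int(np.sum(logx < lo))
    n_het = int(np.sum((logx >= lo) & (logx <= hi)))
    n_fluor = int(np.sum(logx > hi))
    return GatingResult(
        n_total=len(events) + n_debris,
        n_debris=n_debris,
        n_dark=n_dark,
        n_het=n_het,
        n_fluor=n_fluor,
        window_lo=lo,
        window_hi=hi,
    )


def dark_fraction_control(
    events: pd.DataFrame, dark_control: pd.DataFrame, quantile: float = 0.999
) -> float:
    """Fraction of events at or below a threshold set from a non-fluorescent control.

    For unimodal samples where valley detection is impossible: the threshold
    is the given quantile of the control's fluorescence, so a fully dark
    sample reads ~1 and a fully fluorescent one reads ~0.
    """
    if len(dark_control) == 0:
        raise GatingError("empty dark control")
    if len(events) == 0:
        raise GatingError("empty event table")
    if not (0 < quantile < 1):
        raise GatingError("quantile must be in (0, 1)")
    validate_flow_table(events)
    validate_flow_table(dark_control)
    thr = float(np.quantile(dark_control["fl1"].to_numpy(dtype=float), quantile))
    x = events["fl1"].to_numpy(dtype=float)
    return float(np.mean(x <= thr))
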