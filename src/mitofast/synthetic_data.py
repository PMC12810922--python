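"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators here emulate the raw material the analysis consumes: flow-cytometry
event streams (log-normal fluorescence mixtures plus off-diagonal debris),
chloramphenicol-chase fluorescence decay series, OD600 growth curves, qPCR Cq
tables with known relative copy numbers, and 3-D mitochondrial skeleton vertex
tables with per-node channel intensities.  Each generator is deterministic
given its seed, and each emits exactly the table dialect its consuming module
validates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "DecaySeries",
    "GrowthCurve",
    "make_flow_mixture",
    "fig1e_like_spec",
    "make_decay_series",
    "make_growth_curve",
    "make_qpcr_table",
    "LineSpec",
    "make_vertex_table",
]


# ---------------------------------------------------------------------------
# flow-cytometry mixtures


@dataclass(frozen=True)
class MixtureComponent:
    name: str
    fraction: float
    mean_log10: float
    sd_log10: float


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for a synthetic flow-cytometry event table.

    Component fractions are fractions *of cells*; debris is added on top with
    probability ``debris_fraction`` per event and carries an fsc_h/fsc_a ratio
    drawn from ``debris_ratio_range`` (cells sit near ratio 1).
    """

    components: tuple[MixtureComponent, ...]
    n_events: int
    debris_fraction: float = 0.0
    fsc_mean_log10: float = 5.0
    fsc_sd_log10: float = 0.10
    debris_ratio_range: tuple[float, float] = (0.1, 0.6)
    cell_ratio_sd: float = 0.03
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not self.components:
            raise ValueError("at least one component is required")
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {total!r}")
        if not (0.0 <= self.debris_fraction < 1.0):
            raise ValueError("debris_fraction must be in [0, 1)")
        lo, hi = self.debris_ratio_range
        if not (0 < lo < hi):
            raise ValueError("debris_ratio_range must satisfy 0 < lo < hi")
        for c in self.components:
            if c.sd_log10 <= 0:
                raise ValueError(f"component {c.name!r} needs sd_log10 > 0")
            if not (0.0 <= c.fraction <= 1.0):
                raise ValueError(f"component {c.name!r} fraction out of [0, 1]")


def make_flow_mixture(spec: MixtureSpec) -> pd.DataFrame:
    """Draw a flow event table (columns fsc_a, fsc_h, fl1, truth_label) from a mixture spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events

    is_debris = rng.random(n) < spec.debris_fraction
    names = [c.name for c in spec.components]
    probs = np.array([c.fraction for c in spec.components])
    probs = probs / probs.sum()  # guard fp round-off within the 1e-9 gate
    comp_idx = rng.choice(len(names), size=n, p=probs)

    means = np.array([c.mean_log10 for c in spec.components])[comp_idx]
    sds = np.array([c.sd_log10 for c in spec.components])[comp_idx]
    fl1 = 10.0 ** rng.normal(means, sds)

    fsc_a = 10.0 ** rng.normal(spec.fsc_mean_log10, spec.fsc_sd_log10, size=n)
    ratio = rng.normal(1.0, spec.cell_ratio_sd, size=n)
    np.clip(ratio, 0.75, 1.25, out=ratio)

    labels = np.array(names, dtype=object)[comp_idx]
    if is_debris.any():
        nd = int(is_debris.sum())
        lo, hi = spec.debris_ratio_range
        ratio[is_debris] = rng.uniform(lo, hi, size=nd)
        # debris autofluorescence: dim, below the dimmest cell component
        dim = min(c.mean_log10 for c in spec.components) - 0.5
        fl1[is_debris] = 10.0 ** rng.normal(dim, 0.5, size=nd)
        labels[is_debris] = "debris"

    return pd.DataFrame(
        {
            "fsc_a": fsc_a,
            "fsc_h": fsc_a * ratio,
            "fl1": fl1,
            "truth_label": labels,
        }
    )


#: canonical log10-scale geometry for a segregated two-cluster population:
#: dark and fluorescent peaks two decades apart, both sd 0.32, intermediate
#: (heteroplasmic stand-in) centered at the midpoint with sd = 0.08 x the
#: interpeak distance.  Chosen so that (i) the interpeak density minimum
#: stays at the midpoint (a narrower spike would carve flanking dips and
#: displace the detected valley) and (ii) the valley +/-10% window recovers
#: the planted intermediate fraction: ~79% of the component lies inside the
#: window and main-component tail leakage compensates the remainder, making
#: the recovered fraction insensitive to residual valley wander.
_DARK_MEAN = 2.0
_FLUOR_MEAN = 4.0
_MAIN_SD = 0.32
_INTER_SD_FRAC = 0.08


def fig1e_like_spec(
    f_dark: float,
    f_het: float,
    f_fluor: float,
    n_events: int = 10_000,
    debris_fraction: float = 0.0,
    seed: int | None = None,
) -> MixtureSpec:
    """Three-component mixture emulating a segregated FAST microcolony population.

    The three fractions (dark / intermediate-at-valley / fluorescent) are
    normalized to sum exactly to 1 so printed percentages can be passed as-is.
    """
    total = f_dark + f_het + f_fluor
    if total <= 0:
        raise ValueError("fractions must be positive")
    d = _FLUOR_MEAN - _DARK_MEAN
    comps = (
        MixtureComponent("dark", f_dark / total, _DARK_MEAN, _MAIN_SD),
        MixtureComponent(
            "heteroplasmic", f_het / total, (_DARK_MEAN + _FLUOR_MEAN) / 2, _INTER_SD_FRAC * d
        ),
        MixtureComponent("fluorescent", f_fluor / total, _FLUOR_MEAN, _MAIN_SD),
    )
    return MixtureSpec(
        components=comps, n_events=n_events, debris_fraction=debris_fraction, seed=seed
    )


# ---------------------------------------------------------------------------
# decay series and growth curves


@dataclass(frozen=True)
class DecaySeries:
    """Fluorescence medians over time (hours) after translation shut-off."""

    times: np.ndarray
    medians: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.medians, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "medians", m)
        if t.shape != m.shape:
            raise ValueError("times and medians must have equal length")
        if len(t) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(m <= 0):
            raise ValueError("medians must be positive")


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 over time (hours)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)
        if t.shape != od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("OD values must be positive")


def make_decay_series(
    i0: float,
    half_life: float,
    times: Sequence[float],
    noise_sd_log: float = 0.0,
    seed: int | None = None,
) -> DecaySeries:
    """Exponential fluorescence decay: median(t) = i0 * 2^(-t / half_life)."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be >= 0")
    t = np.asarray(times, dtype=float)
    medians = i0 * 2.0 ** (-t / half_life)
    if noise_sd_log > 0:
        rng = np.random.default_rng(seed)
        medians = medians * np.exp(rng.normal(0.0, noise_sd_log, size=t.shape))
    return DecaySeries(times=t, medians=medians)


def make_growth_curve(
    od0: float,
    rate: float,
    duration: float,
    interval: float = 1.0 / 3.0,
    noise_sd_log: float = 0.0,
    seed: int | None = None,
) -> GrowthCurve:
    """Exponential OD600 growth sampled at plate-reader cadence (default 20 min).

    od(t) = od0 * exp(rate * t), with optional multiplicative log-normal noise.
    """
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration + 1e-9, interval)
    od = od0 * np.exp(rate * t)
    if noise_sd_log > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_sd_log, size=t.shape))
    return GrowthCurve(times=t, od=od)


# ---------------------------------------------------------------------------
# qPCR


def make_qpcr_table(
    strains: Sequence[tuple[str, float]],
    base_cq_act1: float = 20.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cq table (strain, target, replicate, cq) under a perfect-efficiency model.

    For a strain with true relative mtDNA copy number c (COX1 per ACT1,
    relative to a nominal 1x), Cq_COX1 = Cq_ACT1 - log2(c): one extra cycle
    per two-fold template difference.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for name, cn in strains:
        if cn <= 0:
            raise ValueError(f"strain {name!r}: copy number must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for name, cn in strains:
        for rep in range(1, replicates + 1):
            e1 = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            e2 = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((name, "ACT1", rep, base_cq_act1 + e1))
            rows.append((name, "COX1", rep, base_cq_act1 - math.log2(cn) + e2))
    return pd.DataFrame(rows, columns=["strain", "target", "replicate", "cq"])


# ---------------------------------------------------------------------------
# mitochondrial skeleton vertex tables


@dataclass(frozen=True)
class LineSpec:
    """One straight polyline of the synthetic skeleton."""

    n_points: int
    spacing: float = 0.11           # µm, typical xy voxel pitch of the source images
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("each line needs at least 2 points")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not any(self.direction):
            raise ValueError("direction must be non-zero")


ChannelFn = Callable[[np.ndarray], np.ndarray]


def make_vertex_table(
    lines: Sequence[LineSpec],
    channels: Mapping[str, float | ChannelFn],
    seed: int | None = None,
) -> pd.DataFrame:
    """Skeleton vertex table: line_id, point_id, x, y, z, one column per channel.

    Channel values may be constants or callables evaluated on the (n, 3)
    coordinate array of each line.  A ``compartment`` column is emitted when
    any line declares one.
    """
    if not lines:
        raise ValueError("at least one line is required")
    frames = []
    for lid, line in enumerate(lines):
        d = np.asarray(line.direction, dtype=float)
        d = d / np.linalg.norm(d)
        steps = np.arange(line.n_points)[:, None] * line.spacing
        pts = np.asarray(line.origin, dtype=float) + steps * d
        df = pd.DataFrame(
            {
                "line_id": lid,
                "point_id": np.arange(line.n_points),
                "x": pts[:, 0],
                "y": pts[:, 1],
                "z": pts[:, 2],
            }
        )
        for ch, fn in channels.items():
            vals = fn(pts) if callable(fn) else np.full(line.n_points, float(fn))
            vals = np.asarray(vals, dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"channel {ch!r} produced negative intensities")
            df[ch] = vals
        if line.compartment is not None:
            df["compartment"] = line.compartment
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if "compartment" in out.columns:
        out["compartment"] = out["compartment"].astype(object)
    return out
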