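"""Skeleton-level mitochondrial network metrics on vertex tables.

A vertex table is one row per skeleton node (line_id, point_id, x, y, z in
micrometres) plus one column per fluorescence channel and, optionally, a
``compartment`` label assigning nodes to the two parental halves of a zygote
(P1 / P2) or to the daughter.  Metrics: total network length (summed
Euclidean segment lengths per line), ratiometric channel summaries (per-node
mean of ratios, or ratio of channel sums), and P2/P1 compartment ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NetworkSummary",
    "RatioSummary",
    "validate_vertex_table",
    "network_length",
    "ratiometric_summary",
    "compartment_ratio",
]

_COORDS = ["x", "y", "z"]
_META = {"line_id", "point_id", "x", "y", "z", "compartment"}


@dataclass(frozen=True)
class NetworkSummary:
    total_length: float
    per_line: dict[int, float]
    n_lines: int
    n_nodes: int


@dataclass(frozen=True)
class RatioSummary:
    mode: str
    numerator: str
    denominator: str
    value: float
    n_nodes: int
    n_excluded: int = 0


def validate_vertex_table(vt: pd.DataFrame, require_consecutive: bool = True) -> None:
    """Check the vertex-table contract.

    Consecutive point indices per line are required only for metrics that
    walk segments (length); intensity summaries accept arbitrary node subsets.
    """
    missing = {"line_id", "point_id", "x", "y", "z"} - set(vt.columns)
    if missing:
        raise ValueError(f"vertex table lacks columns {sorted(missing)}")
    if len(vt) == 0:
        raise ValueError("vertex table is empty")
    coords = vt[_COORDS].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if require_consecutive:
        for lid, grp in vt.groupby("line_id"):
            pid = grp["point_id"].to_numpy()
            if not np.array_equal(pid, np.arange(pid.min(), pid.min() + len(pid))):
                raise ValueError(f"line {lid}: point indices must be consecutive")


def network_length(vt: pd.DataFrame) -> NetworkSummary:
    """Total skeleton length: per line, the sum of Euclidean distances between
    consecutive nodes; lines with a single node contribute zero (with a warning)."""
    validate_vertex_table(vt)
    per_line: dict[int, float] = {}
    for lid, grp in vt.sort_values("point_id").groupby("line_id"):
        pts = grp[_COORDS].to_numpy(dtype=float)
        if len(pts) < 2:
            warnings.warn(f"line {lid} has fewer than 2 points; contributes 0 length")
            per_line[lid] = 0.0
            continue
        per_line[lid] = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return NetworkSummary(
        total_length=float(sum(per_line.values())),
        per_line=per_line,
        n_lines=len(per_line),
        n_nodes=len(vt),
    )


def _channel(vt: pd.DataFrame, name: str) -> np.ndarray:
    if name not in vt.columns or name in _META:
        raise ValueError(f"channel {name!r} not present in vertex table")
    vals = vt[name].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"channel {name!r} has negative intensities")
    return vals


def ratiometric_summary(
    vt: pd.DataFrame, numerator: str, denominator: str, mode: str = "per_node_mean"
) -> RatioSummary:
    """Two-channel ratio along the network.

    ``per_node_mean`` averages num/den over nodes (zero-denominator nodes are
    excluded and counted); ``summed`` is sum(num)/sum(den).
    """
    validate_vertex_table(vt, require_consecutive=False)
    num = _channel(vt, numerator)
    den = _channel(vt, denominator)
    if mode == "per_node_mean":
        ok = den > 0
        if not ok.any():
            raise ValueError("denominator channel is zero at every node")
        value = float(np.mean(num[ok] / den[ok]))
        used, excluded = int(ok.sum()), int((~ok).sum())
    elif mode == "summed":
        total = float(den.sum())
        if total == 0:
            raise ValueError("denominator channel sums to zero")
        value = float(num.sum()) / total
        used, excluded = len(vt), 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RatioSummary(
        mode=mode,
        numerator=numerator,
        denominator=denominator,
        value=value,
        n_nodes=used,
        n_excluded=excluded,
    )


def compartment_ratio(
    vt: pd.DataFrame,
    numerator: str,
    denominator: str,
    mode: str = "per_node_mean",
    compartments: tuple[str, str] = ("P2", "P1"),
) -> float:
    """Ratio of a ratiometric summary between two labelled compartments.

    Default is P2 relative to P1 (the mutant-mtDNA parent relative to the
    intact-mtDNA parent of a zygote).
    """
    if "compartment" not in vt.columns:
        raise ValueError("vertex table has no compartment column")
    top, bottom = compartments
    values = {}
    for label in (top, bottom):
        sub = vt[vt["compartment"] == label]
        if len(sub) == 0:
            raise ValueError(f"compartment {label!r} absent from vertex table")
        values[label] = ratiometric_summary(sub, numerator, denominator, mode).value
    if values[bottom] == 0:
        raise ValueError(f"compartment {bottom!r} summary is zero; ratio undefined")
    return values[top] / values[bottom]
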