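"""Tab-separated table dialects shared by the generators and the analysis.

All tables are plain TSV with a one-line header.  Column names are fixed:
flow events (fsc_a, fsc_h, fl1[, truth_label]), decay series (time_h, median),
growth curves (time_h, od), qPCR (strain, target, replicate, cq), vertex
tables (line_id, point_id, x, y, z, <channels...>[, compartment]).  Extra
columns in vertex tables are tolerated (real MitoGraph exports carry more
fields).  Flow readers subsample to the acquisition cap of 10,000 events
with a fixed seed when the file is larger.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import DecaySeries, GrowthCurve

__all__ = [
    "EVENT_CAP",
    "read_flow_table",
    "write_flow_table",
    "read_decay_series",
    "write_decay_series",
    "read_growth_curve",
    "write_growth_curve",
    "read_qpcr_table",
    "write_qpcr_table",
    "read_vertex_table",
    "write_vertex_table",
]

EVENT_CAP = 10_000


def read_flow_table(
    path: str | Path, max_events: int | None = EVENT_CAP, seed: int = 0
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"fsc_a", "fsc_h", "fl1"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if max_events is not None and len(df) > max_events:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(df), size=max_events, replace=False))
        df = df.iloc[keep].reset_index(drop=True)
    return df


def write_flow_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_decay_series(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path, sep="\t")
    return DecaySeries(times=df["time_h"].to_numpy(), medians=df["median"].to_numpy())


def write_decay_series(series: DecaySeries, path: str | Path) -> None:
    pd.DataFrame({"time_h": series.times, "median": series.medians}).to_csv(
        path, sep="\t", index=False
    )


def read_growth_curve(path: str | Path) -> GrowthCurve:
    df = pd.read_csv(path, sep="\t")
    return GrowthCurve(times=df["time_h"].to_numpy(), od=df["od"].to_numpy())


def write_growth_curve(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"time_h": curve.times, "od": curve.od}).to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"strain", "target", "replicate", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vertex_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"line_id", "point_id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_vertex_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
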