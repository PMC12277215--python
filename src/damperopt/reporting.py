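"""Stride-normalized curve aggregation, peak extraction, table export.

Time series are cut at touchdowns, linearly resampled onto a common
0-100% gait-cycle axis (101 points by default), and averaged across
cycles.  Peaks are reported separately for the Stance and Swing windows,
split at the Toe-Off index (the ipsilateral Lift Off -> Swing
transition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CycleCurves",
    "normalize_to_gait_cycle",
    "peak_metrics",
    "export_heatmap_table",
    "read_heatmap_table",
    "curves_to_frame",
]


@dataclass
class CycleCurves:
    cycles: np.ndarray  # (n_cycles, n_points)
    mean: np.ndarray
    std: np.ndarray
    name: str = ""
    units: str = ""

    @property
    def n_points(self) -> int:
        return self.cycles.shape[1]

    @property
    def pct(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_points)


def normalize_to_gait_cycle(
    series: np.ndarray,
    strides: Sequence[tuple[int, int]],
    n_points: int = 101,
    name: str = "",
    units: str = "",
) -> CycleCurves:
    """Resample each stride to ``n_points`` and average across cycles.

    Each stride ``[i0, i1)`` is resampled including the closing touchdown
    sample, so 0% and 100% are both touchdowns.
    """
    if len(strides) == 0:
        raise ValueError("no strides to normalize")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    series = np.asarray(series, dtype=float)
    target = np.linspace(0.0, 1.0, n_points)
    rows = []
    for i0, i1 in strides:
        if i1 >= len(series):
            i1 = len(series) - 1
        seg = series[i0 : i1 + 1]
        if len(seg) < 2:
            raise ValueError(f"stride [{i0}, {i1}) too short to resample")
        src = np.linspace(0.0, 1.0, len(seg))
        rows.append(np.interp(target, src, seg))
    cycles = np.vstack(rows)
    return CycleCurves(
        cycles=cycles,
        mean=cycles.mean(axis=0),
        std=cycles.std(axis=0),
        name=name,
        units=units,
    )


def peak_metrics(curves: CycleCurves, toe_off_index: int) -> dict:
    """Max/min (value and % location) within Stance and Swing windows."""
    n = curves.n_points
    if not 0 < toe_off_index < n:
        raise ValueError(f"toe_off_index must be in (0, {n}), got {toe_off_index}")
    pct = curves.pct
    out = {}
    for window, sl in (
        ("stance", slice(0, toe_off_index + 1)),
        ("swing", slice(toe_off_index + 1, n)),
    ):
        seg = curves.mean[sl]
        seg_pct = pct[sl]
        if seg.size == 0:
            continue
        out[f"{window}_max"] = float(seg.max())
        out[f"{window}_max_pct"] = float(seg_pct[int(seg.argmax())])
        out[f"{window}_min"] = float(seg.min())
        out[f"{window}_min_pct"] = float(seg_pct[int(seg.argmin())])
    return out


def curves_to_frame(curves: CycleCurves) -> pd.DataFrame:
    return pd.DataFrame({"pct": curves.pct, "mean": curves.mean, "std": curves.std})


def export_heatmap_table(table: pd.DataFrame, path) -> pd.DataFrame:
    """Write a long-format ``c, pattern_mask, cost`` CSV of the design grid.

    The table is completed to the full cross product of observed damping
    values and pattern masks; cells never evaluated are written as ``NA``.
    Values round-trip bit-exactly through the CSV.
    """
    required = {"c", "pattern_mask", "cost"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    full = pd.MultiIndex.from_product(
        [np.unique(table["c"]), np.unique(table["pattern_mask"])],
        names=["c", "pattern_mask"],
    )
    out = (
        table.set_index(["c", "pattern_mask"])["cost"]
        .reindex(full)
        .reset_index()
    )
    # repr() guarantees shortest round-trip formatting; pandas' default
    # formatter truncates to 16 significant digits when na_rep is set
    out.to_csv(
        path, index=False, na_rep="NA", float_format=lambda v: repr(float(v))
    )
    return out


def read_heatmap_table(path) -> pd.DataFrame:
    """Read a heat-map CSV back with exact (round-trip) float parsing."""
    return pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
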