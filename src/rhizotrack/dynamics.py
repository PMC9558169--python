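"""Time-series analysis of root traits.

The headline quantity is the net growth rate of root length density,

    RLD_NGR(n) = (RLD_n - RLD_{n-1}) / d,

the finite difference of root length density between consecutive frames
divided by the elapsed days ``d``.  Negative values indicate net
senescence outpacing elongation.  Irregular sampling is handled by using
the true day gap; no smoothing is applied to exported values.

Per-root dynamics come from tracking a single root's connected component
across a registered series and measuring it in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, label

from .catalog import ScaleCalibration
from .traits import FrameGeometry, measure_traits, skeletonize_mask

__all__ = ["DynamicsSeries", "RootTrack", "rld_ngr", "track_root", "growth_rate"]


@dataclass
class DynamicsSeries:
    """Table of day, RLD, day gap and RLD net growth rate."""

    table: pd.DataFrame  # columns: day, RLD, d, RLD_NGR

    def __len__(self) -> int:
        return len(self.table)


def rld_ngr(trait_series: pd.DataFrame) -> DynamicsSeries:
    """Net growth rate of root length density from a trait table.

    ``trait_series`` needs columns ``day`` and ``RLD_cm_per_cm3`` (or
    ``RLD``).  Rows are sorted by day; at least two rows, no duplicate
    days.  The first row's rate is undefined (NaN).
    """
    df = trait_series.copy()
    col = "RLD_cm_per_cm3" if "RLD_cm_per_cm3" in df.columns else "RLD"
    if col not in df.columns or "day" not in df.columns:
        raise ValueError("trait series must have 'day' and an RLD column")
    if len(df) < 2:
        raise ValueError("need at least 2 rows to difference")
    if df["day"].duplicated().any():
        raise ValueError("duplicate days in trait series")
    df = df.sort_values("day", ignore_index=True)
    day = df["day"].to_numpy(dtype=float)
    rld = df[col].to_numpy(dtype=float)
    d = np.diff(day)
    ngr = np.diff(rld) / d
    out = pd.DataFrame(
        {
            "day": df["day"],
            "RLD": rld,
            "d": np.concatenate([[np.nan], d]),
            "RLD_NGR": np.concatenate([[np.nan], ngr]),
        }
    )
    return DynamicsSeries(out)


@dataclass
class RootTrack:
    """Per-day length/diameter of one tracked root."""

    root_id: str
    days: list[int]
    length_cm: list[float]
    diameter_mm: list[float]
    truncated: bool = False  # root vanished before the series ended


def _overlap_component(
    labels: np.ndarray, n_labels: int, region: np.ndarray
) -> np.ndarray | None:
    """Union of connected components overlapping ``region``.

    A union, not just the best match: a crossing root can slice the
    tracked region into several components that all belong to the same
    tracked root.
    """
    if n_labels == 0:
        return None
    ids = np.unique(labels[region])
    ids = ids[ids > 0]
    if ids.size == 0:
        return None
    return np.isin(labels, ids)


_STRUCT8 = np.ones((3, 3), dtype=bool)


def track_root(
    masks,
    seed_region: np.ndarray,
    calibration: ScaleCalibration,
    days=None,
    *,
    root_id: str = "track",
    margin_px: int = 12,
    prune_len_mm: float = 0.8,
) -> RootTrack:
    """Follow one root through an aligned mask series and measure it daily.

    ``seed_region`` is the tracked region of interest — in practice the
    region an analyst draws around the root of interest.  It must contain
    part of exactly one root on the first day; measurement is restricted
    to it throughout, so a parent or crossing root outside the region
    cannot inflate the track.  Each day the connected component of
    ``mask & seed_region`` overlapping the previous day's component
    (dilated by ``margin_px`` to allow for growth and residual drift) is
    measured via the trait pipeline.  If the root disappears, the track
    is truncated and flagged.
    """
    masks = [m.mask if hasattr(m, "mask") else np.asarray(m).astype(bool) for m in masks]
    if days is None:
        days = list(range(1, len(masks) + 1))
    days = list(days)
    if len(days) != len(masks):
        raise ValueError("days and masks must pair up")

    roi = np.asarray(seed_region).astype(bool)
    labels, n = label(masks[0] & roi, structure=_STRUCT8)
    comp = _overlap_component(labels, n, roi)
    if comp is None:
        raise ValueError("seed region contains no root pixels on the first day")

    geometry = FrameGeometry(A=1.0, DOF=1.0)
    out_days: list[int] = []
    lengths: list[float] = []
    diameters: list[float] = []
    truncated = False
    for i, (day, m) in enumerate(zip(days, masks)):
        if i > 0:
            search = binary_dilation(comp, structure=_STRUCT8, iterations=margin_px)
            labels, n = label(m & roi, structure=_STRUCT8)
            nxt = _overlap_component(labels, n, search)
            if nxt is None:
                truncated = True
                break
            comp = nxt
        g = skeletonize_mask(comp, calibration, prune_len_mm)
        t = measure_traits(g, calibration, geometry, day=day)
        out_days.append(day)
        lengths.append(t.RL)
        diameters.append(t.AD)
    return RootTrack(root_id, out_days, lengths, diameters, truncated)


def growth_rate(track: RootTrack) -> pd.DataFrame:
    """Finite-difference growth rates of a tracked root.

    Returns a table (day, length_rate_cm_per_day, diameter_rate_mm_per_day)
    from the second tracked day onward, dividing by the actual day gap.
    """
    if len(track.days) < 2:
        raise ValueError("need at least 2 tracked days")
    day = np.asarray(track.days, dtype=float)
    length = np.asarray(track.length_cm, dtype=float)
    diam = np.asarray(track.diameter_mm, dtype=float)
    d = np.diff(day)
    return pd.DataFrame(
        {
            "day": track.days[1:],
            "length_rate_cm_per_day": np.diff(length) / d,
            "diameter_rate_mm_per_day": np.diff(diam) / d,
        }
    )
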