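"""Seeded synthetic root systems with exact ground truth, rendered as
scanner-like frames.

The generator stands in for greenhouse rhizotron data in every test: it
grows a taproot plus first- and second-order laterals as piecewise-linear
polylines (constant per-root elongation rate, heading jitter per step,
laterals emerging at Poisson-spaced positions along their parent), assigns
exponential lifespans with right-censoring at the observation horizon, and
optionally decorates roots with root hairs that are born shortly after
their anchor point appears and later become distorted.

Because every polyline is built from fixed-length sub-steps, the visible
arc length of root ``i`` at day ``t`` is available in closed form::

    L_i(t) = min(L0 + rate_i * (t - emergence_i), total_i)   for t >= emergence_i

which makes total root length, per-root elongation rates, hair counts and
event days exact oracles for the measurement modules.

Rendering emulates a flatbed scan of roots pressed against soil: a dark
textured background, bright ("white") live roots, darker brown senescent
roots that stay in the segmentation mask, and fine hairs that are drawn
only at hair-grade resolution.  All randomness is driven by a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .catalog import (
    HAIR_DPI_THRESHOLD,
    ImageRecord,
    ImageSeries,
    ScaleCalibration,
    write_catalog,
    write_image,
    write_mask,
)

__all__ = [
    "RootSystemParams",
    "RenderConfig",
    "HairTruth",
    "RootTruth",
    "RootSystemTruth",
    "grow_root_system",
    "render_frame",
    "render_series",
    "render_root_mask",
    "render_subject_roi",
    "generate_series",
]


@dataclass
class RootSystemParams:
    """Growth-model parameters (lengths mm, rates mm/day, times days)."""

    frame_width_mm: float = 100.0
    frame_height_mm: float = 100.0
    horizon_days: int = 15
    #: arc length a root shows on its emergence day (a visible nub)
    initial_length_mm: float = 2.5

    taproot_rate_mm_per_day: float = 6.0
    taproot_diameter_mm: float = 1.2

    n_lateral1: int = 12
    lateral1_rate_mean: float = 3.0
    lateral1_rate_sd: float = 0.6
    lateral1_diameter_mm: float = 0.6
    lateral1_angle_deg: float = 55.0
    #: mean arc-length gap between successive lateral attachment points
    lateral_spacing_mm: float = 2.5

    n_lateral2: int = 4
    lateral2_rate_mean: float = 1.5
    lateral2_diameter_mm: float = 0.35

    #: diameter at the tip as a fraction of the basal diameter
    tip_taper: float = 0.45
    #: per-step standard deviation of the AR(1) curvature noise
    heading_jitter_deg: float = 1.0
    step_mm: float = 0.5

    #: mean of the exponential lateral-root lifespan; None disables senescence
    lifespan_mean_days: float | None = 30.0

    #: hairs per mm of root axis (0 disables hairs)
    hairs_per_mm: float = 0.0
    hair_length_range_mm: tuple[float, float] = (0.2, 0.8)
    hair_lifespan_mean_days: float | None = 12.0

    def validate(self) -> None:
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        for name in (
            "taproot_rate_mm_per_day",
            "lateral1_rate_mean",
            "lateral2_rate_mean",
            "initial_length_mm",
            "step_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lateral1 < 0 or self.n_lateral2 < 0:
            raise ValueError("lateral counts must be >= 0")
        lo, hi = self.hair_length_range_mm
        if not (0 < lo <= hi):
            raise ValueError("hair_length_range_mm must satisfy 0 < lo <= hi")


@dataclass
class RenderConfig:
    """Scanner-emulation parameters.

    Brightness is on the 0-255 luminance scale and must satisfy
    live > senescent > soil mean so that live/senescent status is
    decidable from brightness while both remain segmentable from soil.
    """

    dpi: int = 150
    seed: int = 0
    hair_dpi_threshold: int = HAIR_DPI_THRESHOLD

    soil_base: float = 70.0
    soil_texture_sigma_px: float = 3.0
    soil_contrast: float = 14.0
    noise_sigma: float = 5.0

    live_brightness: float = 205.0
    senescent_brightness: float = 115.0
    hair_brightness: float = 185.0

    soil_tint: tuple[float, float, float] = (1.0, 0.82, 0.62)
    live_tint: tuple[float, float, float] = (1.0, 0.97, 0.90)
    senescent_tint: tuple[float, float, float] = (1.0, 0.72, 0.50)

    hair_width_mm: float = 0.015
    #: sinusoidal bend of a distorted hair: amplitude (fraction of hair
    #: length) and number of cycles; gives arc/chord well above 1.5
    distort_amplitude: float = 0.18
    distort_cycles: float = 2.5

    def __post_init__(self) -> None:
        if not (self.live_brightness > self.senescent_brightness > self.soil_base):
            raise ValueError(
                "require live > senescent > soil brightness for status calls"
            )


@dataclass
class HairTruth:
    """A single root hair anchored on its parent's centerline."""

    hair_id: str
    anchor_s_mm: float  # arc position along the parent polyline
    side: int  # +1 / -1
    angle_deg: float  # from the local parent heading
    length_mm: float
    birth_day: int
    distortion_day: int | None

    def __post_init__(self) -> None:
        if self.distortion_day is not None and self.distortion_day <= self.birth_day:
            raise ValueError("distortion_day must exceed birth_day")


@dataclass
class RootTruth:
    root_id: str
    order: str  # taproot | lateral1 | lateral2
    parent_id: str | None
    polyline: np.ndarray  # (N, 2) x,y in mm
    cum_s: np.ndarray  # (N,) cumulative arc length, cum_s[0] = 0
    diameters_mm: np.ndarray  # (N,) monotone non-increasing tip-ward
    emergence_day: int
    senescence_day: int | None
    rate_mm_per_day: float
    initial_length_mm: float
    hairs: list[HairTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.senescence_day is not None and self.senescence_day <= self.emergence_day:
            raise ValueError("senescence_day must exceed emergence_day")
        if np.any(np.diff(self.diameters_mm) > 1e-9):
            raise ValueError("diameter must be non-increasing tip-ward")

    @property
    def total_length_mm(self) -> float:
        return float(self.cum_s[-1])

    def length_at(self, day: float) -> float:
        """Closed-form visible arc length at ``day`` (0 before emergence)."""
        if day < self.emergence_day:
            return 0.0
        grown = self.initial_length_mm + self.rate_mm_per_day * (day - self.emergence_day)
        return float(min(grown, self.total_length_mm))

    def is_senescent(self, day: float) -> bool:
        return self.senescence_day is not None and day >= self.senescence_day

    def point_at(self, s: float) -> tuple[np.ndarray, float]:
        """Interpolated (x, y) and local heading (radians) at arc position s."""
        s = float(np.clip(s, 0.0, self.total_length_mm))
        x = np.interp(s, self.cum_s, self.polyline[:, 0])
        y = np.interp(s, self.cum_s, self.polyline[:, 1])
        i = int(np.clip(np.searchsorted(self.cum_s, s) - 1, 0, len(self.cum_s) - 2))
        d = self.polyline[i + 1] - self.polyline[i]
        return np.array([x, y]), math.atan2(d[1], d[0])


@dataclass
class RootSystemTruth:
    roots: list[RootTruth]
    params: RootSystemParams
    sow_day: int = 0
    seed: int = 0

    def root(self, root_id: str) -> RootTruth:
        for r in self.roots:
            if r.root_id == root_id:
                return r
        raise KeyError(root_id)

    def total_length_mm(self, day: float) -> float:
        """Closed-form total visible root length at ``day`` (oracle for RL)."""
        return sum(r.length_at(day) for r in self.roots)

    def mean_diameter_mm(self, day: float) -> float:
        """Length-weighted mean diameter of all visible root arc (oracle
        for the AD trait); exact because the taper is linear in arc length."""
        num = den = 0.0
        for r in self.roots:
            length = r.length_at(day)
            if length <= 0:
                continue
            base, tip = float(r.diameters_mm[0]), float(r.diameters_mm[-1])
            mean_d = base - (base - tip) * length / (2.0 * r.total_length_mm)
            num += mean_d * length
            den += length
        return num / den if den else 0.0

    def rl_table(self, days) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": list(days), "RL_cm": [self.total_length_mm(d) / 10.0 for d in days]}
        )

    def root_events_table(self) -> pd.DataFrame:
        horizon = self.params.horizon_days
        rows = []
        for r in self.roots:
            censored = r.senescence_day is None or r.senescence_day > horizon
            rows.append(
                {
                    "root_id": r.root_id,
                    "order": r.order,
                    "parent_id": r.parent_id or "",
                    "emergence_day": r.emergence_day,
                    "end_day": horizon if censored else r.senescence_day,
                    "censored": censored,
                    "rate_mm_per_day": r.rate_mm_per_day,
                }
            )
        return pd.DataFrame(rows)

    def hair_events_table(self) -> pd.DataFrame:
        horizon = self.params.horizon_days
        rows = []
        for r in self.roots:
            for h in r.hairs:
                censored = h.distortion_day is None or h.distortion_day > horizon
                rows.append(
                    {
                        "hair_id": h.hair_id,
                        "root_id": r.root_id,
                        "anchor_s_mm": h.anchor_s_mm,
                        "length_mm": h.length_mm,
                        "birth_day": h.birth_day,
                        "end_day": horizon if censored else h.distortion_day,
                        "censored": censored,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "hair_id", "root_id", "anchor_s_mm", "length_mm",
                "birth_day", "end_day", "censored",
            ],
        )


# ---------------------------------------------------------------------------
# growth


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def _wander(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    total_len: float,
    step: float,
    jitter_rad: float,
    bounds: tuple[float, float],
    avoid_pts: np.ndarray | None = None,
    avoid_dist: float = 2.0,
    avoid_after: float = 3.0,
) -> np.ndarray:
    """Smoothly curving walk of fixed-length steps; exact arc length.

    Curvature follows an AR(1) process (persistent, gentle bends) and the
    heading weakly reverts to its initial direction — a simple tropism that
    keeps roots from curling onto themselves.  When ``avoid_pts`` (points
    of already-grown roots, mm) come within ``avoid_dist``, the heading
    steers away — roots explore free soil rather than bundling along each
    other.  Avoidance starts ``avoid_after`` mm from the base so a lateral
    can leave its parent's flank.  The heading is reflected at a 1.5 mm
    margin from the frame bounds; nothing changes the step length, so arc
    length stays exact.
    """
    margin = 1.5
    w, h = bounds
    n = max(2, int(math.ceil(total_len / step)) + 1)
    pts = np.empty((n, 2))
    pts[0] = start
    remaining = total_len
    p = start.astype(float).copy()
    heading0 = heading
    kappa = 0.0
    grown = 0.0
    i = 1
    while remaining > 1e-9 and i < n:
        ds = min(step, remaining)
        kappa = 0.8 * kappa + rng.normal(0.0, jitter_rad)
        heading = heading + kappa + 0.04 * _wrap_angle(heading0 - heading)
        if avoid_pts is not None and len(avoid_pts) and grown > avoid_after:
            delta = avoid_pts - p
            d2 = np.einsum("ij,ij->i", delta, delta)
            j = int(np.argmin(d2))
            if d2[j] < avoid_dist * avoid_dist:
                away = math.atan2(-delta[j, 1], -delta[j, 0])
                heading = heading + np.clip(
                    _wrap_angle(away - heading), -0.25, 0.25
                )
        d = np.array([math.cos(heading), math.sin(heading)])
        nxt = p + d * ds
        # reflect only when the step actually points outward
        if (nxt[0] < margin and d[0] < 0) or (nxt[0] > w - margin and d[0] > 0):
            heading = math.pi - heading
            d = np.array([math.cos(heading), math.sin(heading)])
            nxt = p + d * ds
        if (nxt[1] < margin and d[1] < 0) or (nxt[1] > h - margin and d[1] > 0):
            heading = -heading
            d = np.array([math.cos(heading), math.sin(heading)])
            nxt = p + d * ds
        nxt[0] = np.clip(nxt[0], 0.2, w - 0.2)
        nxt[1] = np.clip(nxt[1], 0.2, h - 0.2)
        pts[i] = nxt
        p = nxt
        remaining -= ds
        grown += ds
        i += 1
    return pts[:i]


def _cum_arc(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _taper(cum_s: np.ndarray, base_d: float, tip_frac: float) -> np.ndarray:
    total = max(cum_s[-1], 1e-9)
    return base_d * (1.0 - (1.0 - tip_frac) * cum_s / total)


def _attach_positions(
    rng: np.random.Generator, n: int, spacing: float, lo: float, hi: float,
    min_gap: float = 1.5,
) -> np.ndarray:
    """Poisson-spaced positions in [lo, hi] with a refractory minimum gap.

    Lateral primordia initiate at spatially separated sites along the
    parent axis, so gaps are ``min_gap`` plus an exponential excess with
    the requested mean spacing.  Exactly ``n`` positions are returned.
    """
    excess = max(spacing - min_gap, 0.25)
    gaps = min_gap + rng.exponential(excess, size=n)
    pos = lo + np.cumsum(gaps)
    overflow = pos > hi
    pos[overflow] = rng.uniform(lo, hi, size=int(overflow.sum()))
    return np.sort(pos)


def _arrival_day(parent: RootTruth, s: float) -> int:
    """First day the parent's visible length covers arc position ``s``."""
    extra = max(0.0, s - parent.initial_length_mm)
    return parent.emergence_day + int(math.ceil(extra / parent.rate_mm_per_day))


def _draw_lifespan(
    rng: np.random.Generator, mean: float | None, emergence: int, horizon: int
) -> int | None:
    if mean is None:
        return None
    span = max(2, int(round(rng.exponential(mean))))
    day = emergence + span
    return day if day <= horizon else None


def _grow_hairs(
    rng: np.random.Generator, root: RootTruth, params: RootSystemParams
) -> list[HairTruth]:
    if params.hairs_per_mm <= 0:
        return []
    spacing = 1.0 / params.hairs_per_mm
    hairs: list[HairTruth] = []
    s = 1.0 + spacing * rng.uniform(0.5, 1.0)
    side = 1
    k = 0
    lo, hi = params.hair_length_range_mm
    while s < root.total_length_mm - 0.5:
        birth = _arrival_day(root, s) + 1
        if birth <= params.horizon_days:
            distortion = None
            if params.hair_lifespan_mean_days is not None:
                span = max(1, int(round(rng.exponential(params.hair_lifespan_mean_days))))
                if birth + span <= params.horizon_days:
                    distortion = birth + span
            hairs.append(
                HairTruth(
                    hair_id=f"{root.root_id}_h{k:03d}",
                    anchor_s_mm=float(s),
                    side=side,
                    angle_deg=float(rng.uniform(70.0, 110.0)),
                    length_mm=float(rng.uniform(lo, hi)),
                    birth_day=birth,
                    distortion_day=distortion,
                )
            )
            k += 1
        side = -side
        s += spacing * rng.uniform(0.7, 1.3)
    return hairs


def grow_root_system(params: RootSystemParams, seed: int = 0) -> RootSystemTruth:
    """Grow a deterministic synthetic root system.

    Returns a :class:`RootSystemTruth` whose per-root closed-form lengths,
    event days and hair annotations serve as exact oracles.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    bounds = (params.frame_width_mm, params.frame_height_mm)
    jit = math.radians(params.heading_jitter_deg)
    roots: list[RootTruth] = []

    stride = max(1, int(round(1.0 / params.step_mm)))
    occupied: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def coarse(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return poly[::stride], _cum_arc(poly)[::stride]

    def avoid_for(parent_id: str, s: float) -> np.ndarray:
        """Occupied points, excluding the parent near the attachment so a
        new lateral can leave its parent's flank but steers away from
        everything else from the start."""
        arrs = []
        for rid, (pts, cum) in occupied.items():
            if rid == parent_id:
                keep = np.abs(cum - s) > 4.0
                if keep.any():
                    arrs.append(pts[keep])
            else:
                arrs.append(pts)
        return np.concatenate(arrs)

    # taproot: starts near the top center, grows downwards for the horizon
    tap_total = params.initial_length_mm + params.taproot_rate_mm_per_day * params.horizon_days
    start = np.array([params.frame_width_mm / 2 + rng.uniform(-2, 2), 2.0])
    poly = _wander(rng, start, math.pi / 2, tap_total, params.step_mm, jit * 0.5, bounds)
    occupied["tap"] = coarse(poly)
    cum = _cum_arc(poly)
    taproot = RootTruth(
        root_id="tap",
        order="taproot",
        parent_id=None,
        polyline=poly,
        cum_s=cum,
        diameters_mm=_taper(cum, params.taproot_diameter_mm, params.tip_taper),
        emergence_day=0,
        senescence_day=None,  # the main axis outlives the observation window
        rate_mm_per_day=params.taproot_rate_mm_per_day,
        initial_length_mm=params.initial_length_mm,
    )
    roots.append(taproot)

    # first-order laterals at Poisson-spaced positions along the taproot
    attach1 = _attach_positions(
        rng, params.n_lateral1, params.lateral_spacing_mm,
        lo=3.0, hi=0.8 * taproot.total_length_mm,
    )
    lat1: list[RootTruth] = []
    for j, s in enumerate(attach1):
        emergence = _arrival_day(taproot, s) + 1
        rate = float(
            np.clip(rng.normal(params.lateral1_rate_mean, params.lateral1_rate_sd),
                    0.5, None)
        )
        total = params.initial_length_mm + rate * max(1, params.horizon_days - emergence)
        base, heading = taproot.point_at(s)
        side = 1 if j % 2 == 0 else -1
        ang = heading + side * math.radians(params.lateral1_angle_deg + rng.uniform(-10, 10))
        # emerge at the parent's flank: the truth length is the protruding arc
        parent_r = float(np.interp(s, taproot.cum_s, taproot.diameters_mm)) / 2.0
        base = base + parent_r * np.array([math.cos(ang), math.sin(ang)])
        poly = _wander(rng, base, ang, total, params.step_mm, jit, bounds,
                       avoid_pts=avoid_for("tap", s), avoid_after=0.5)
        occupied[f"l1_{j:02d}"] = coarse(poly)
        cum = _cum_arc(poly)
        root = RootTruth(
            root_id=f"l1_{j:02d}",
            order="lateral1",
            parent_id="tap",
            polyline=poly,
            cum_s=cum,
            diameters_mm=_taper(cum, params.lateral1_diameter_mm, params.tip_taper),
            emergence_day=emergence,
            senescence_day=_draw_lifespan(
                rng, params.lifespan_mean_days, emergence, params.horizon_days
            ),
            rate_mm_per_day=rate,
            initial_length_mm=params.initial_length_mm,
        )
        lat1.append(root)
    roots.extend(lat1)

    # second-order laterals on first-order parents
    for j in range(params.n_lateral2 if lat1 else 0):
        parent = lat1[j % len(lat1)]
        s = float(rng.uniform(0.3, 0.7) * parent.total_length_mm)
        emergence = _arrival_day(parent, s) + 1
        if emergence >= params.horizon_days:
            emergence = params.horizon_days - 1
        rate = float(np.clip(rng.normal(params.lateral2_rate_mean, 0.3), 0.4, None))
        total = params.initial_length_mm + rate * max(1, params.horizon_days - emergence)
        base, heading = parent.point_at(s)
        side = 1 if j % 2 == 0 else -1
        ang = heading + side * math.radians(params.lateral1_angle_deg + rng.uniform(-10, 10))
        parent_r = float(np.interp(s, parent.cum_s, parent.diameters_mm)) / 2.0
        base = base + parent_r * np.array([math.cos(ang), math.sin(ang)])
        poly = _wander(rng, base, ang, total, params.step_mm, jit, bounds,
                       avoid_pts=avoid_for(parent.root_id, s), avoid_after=0.5)
        occupied[f"l2_{j:02d}"] = coarse(poly)
        cum = _cum_arc(poly)
        roots.append(
            RootTruth(
                root_id=f"l2_{j:02d}",
                order="lateral2",
                parent_id=parent.root_id,
                polyline=poly,
                cum_s=cum,
                diameters_mm=_taper(cum, params.lateral2_diameter_mm, params.tip_taper),
                emergence_day=emergence,
                senescence_day=_draw_lifespan(
                    rng, params.lifespan_mean_days, emergence, params.horizon_days
                ),
                rate_mm_per_day=rate,
                initial_length_mm=params.initial_length_mm,
            )
        )

    for r in roots:
        r.hairs = _grow_hairs(rng, r, params)

    return RootSystemTruth(roots=roots, params=params, seed=seed)


# ---------------------------------------------------------------------------
# rendering


def _stamp_polyline(
    target: np.ndarray,
    pts_px: np.ndarray,
    radii_px: np.ndarray,
) -> None:
    """OR disks of per-point radius into a boolean raster along a polyline."""
    h, w = target.shape
    rmax_all = int(math.ceil(radii_px.max())) if len(radii_px) else 0
    # cache circular footprints by rounded radius
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for (x, y), r in zip(pts_px, radii_px):
        rr = round(r * 4) / 4
        if rr not in cache:
            n = int(math.ceil(rr))
            oy, ox = np.mgrid[-n : n + 1, -n : n + 1]
            sel = oy * oy + ox * ox <= rr * rr + 1e-9
            cache[rr] = (oy[sel], ox[sel])
        oy, ox = cache[rr]
        cy, cx = int(round(y)), int(round(x))
        ys = oy + cy
        xs = ox + cx
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        target[ys[ok], xs[ok]] = True
    del rmax_all


def _sample_root(
    root: RootTruth, visible_len: float, mm_per_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample centerline points (px) and radii (px) up to ``visible_len``."""
    ds = 0.5 * mm_per_px  # half-pixel spacing in mm
    s = np.arange(0.0, visible_len + ds, ds)
    s = np.clip(s, 0.0, min(visible_len, root.total_length_mm))
    x = np.interp(s, root.cum_s, root.polyline[:, 0]) / mm_per_px
    y = np.interp(s, root.cum_s, root.polyline[:, 1]) / mm_per_px
    d = np.interp(s, root.cum_s, root.diameters_mm)
    radii = np.maximum(d / 2.0 / mm_per_px, 1.0)
    return np.column_stack([x, y]), radii


def _hair_polyline(
    root: RootTruth, hair: HairTruth, distorted: bool, config: RenderConfig
) -> np.ndarray:
    """Hair centerline in mm; straight when intact, sinusoidal when distorted.

    The hair protrudes from the parent's surface, so ``length_mm`` is the
    visible arc an analyst would measure from the root flank to the tip.
    """
    center, heading = root.point_at(hair.anchor_s_mm)
    ang = heading + hair.side * math.radians(hair.angle_deg)
    d = np.array([math.cos(ang), math.sin(ang)])
    parent_r = float(np.interp(hair.anchor_s_mm, root.cum_s, root.diameters_mm)) / 2.0
    base = center + parent_r * d
    perp = np.array([-d[1], d[0]])
    t = np.linspace(0.0, 1.0, 40)
    pts = base[None, :] + np.outer(t * hair.length_mm, d)
    if distorted:
        amp = config.distort_amplitude * hair.length_mm
        wave = np.sin(2 * math.pi * config.distort_cycles * t) * amp * np.sin(math.pi * t)
        pts = pts + np.outer(wave, perp)
    return pts


def _resample_polyline(pts: np.ndarray, ds: float) -> np.ndarray:
    cum = _cum_arc(pts)
    s = np.arange(0.0, cum[-1] + ds, ds)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])


def _frame_shape(params: RootSystemParams, dpi: int) -> tuple[int, int]:
    h = int(round(params.frame_height_mm / 25.4 * dpi))
    w = int(round(params.frame_width_mm / 25.4 * dpi))
    return h, w


def render_root_mask(
    truth: RootSystemTruth,
    day: int,
    config: RenderConfig,
    root_ids: list[str] | None = None,
    full_extent: bool = False,
) -> np.ndarray:
    """Binary mask of selected roots at ``day`` (all roots by default).

    With ``full_extent=True`` each selected root is drawn at its final
    (horizon) length regardless of day — useful for building per-root
    regions of interest.
    """
    mm_per_px = 25.4 / config.dpi
    h, w = _frame_shape(truth.params, config.dpi)
    mask = np.zeros((h, w), dtype=bool)
    for root in truth.roots:
        if root_ids is not None and root.root_id not in root_ids:
            continue
        vis = root.total_length_mm if full_extent else root.length_at(day)
        if vis <= 0:
            continue
        pts, radii = _sample_root(root, vis, mm_per_px)
        _stamp_polyline(mask, pts, radii)
    return mask


def render_subject_roi(
    truth: RootSystemTruth,
    root_id: str,
    config: RenderConfig,
    margin_px: int = 2,
    exclusion_margin_px: int = 1,
) -> np.ndarray:
    """Region of interest for lifespan analysis of one root.

    The root's own full-extent footprint (dilated by ``margin_px``) minus
    the dilated footprints of every other root, so that the parent near
    the attachment point and any crossing root cannot trigger emergence
    or contaminate the brightness-based status call.
    """
    from scipy.ndimage import binary_dilation

    own = render_root_mask(truth, 0, config, root_ids=[root_id], full_extent=True)
    others = render_root_mask(
        truth, 0, config,
        root_ids=[r.root_id for r in truth.roots if r.root_id != root_id],
        full_extent=True,
    )
    struct = np.ones((3, 3), dtype=bool)
    roi = binary_dilation(own, structure=struct, iterations=margin_px)
    if others.any():
        roi &= ~binary_dilation(others, structure=struct,
                                iterations=exclusion_margin_px)
    return roi


def render_frame(
    truth: RootSystemTruth, day: int, config: RenderConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one frame.

    Returns ``(image, mask, hair_mask)``: an (H, W, 3) uint8 scanner-like
    image, the boolean root mask (all roots with emergence_day <= day,
    including senescent ones), and the boolean hair mask (empty below the
    hair-resolution threshold).  Deterministic in (truth, day, config).
    """
    if day < truth.sow_day:
        raise ValueError(f"day {day} is before sowing day {truth.sow_day}")
    mm_per_px = 25.4 / config.dpi
    h, w = _frame_shape(truth.params, config.dpi)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, config.dpi, day]))

    # textured soil background; the speckle field is a property of the pot,
    # not the day, so consecutive frames of a series share it (this is what
    # makes cross-correlation registration of real series work)
    soil_rng = np.random.default_rng(np.random.SeedSequence([config.seed, config.dpi]))
    speckle = gaussian_filter(soil_rng.standard_normal((h, w)), config.soil_texture_sigma_px)
    sd = speckle.std()
    if sd > 0:
        speckle *= config.soil_contrast / sd
    intensity = config.soil_base + speckle
    tint = np.empty((h, w, 3))
    tint[:] = config.soil_tint

    mask = np.zeros((h, w), dtype=bool)
    hair_mask = np.zeros((h, w), dtype=bool)
    draw_hairs = config.dpi >= config.hair_dpi_threshold

    for root in truth.roots:
        vis = root.length_at(day)
        if vis <= 0:
            continue
        pts, radii = _sample_root(root, vis, mm_per_px)
        body = np.zeros((h, w), dtype=bool)
        _stamp_polyline(body, pts, radii)
        mask |= body
        if root.is_senescent(day):
            bright, tnt = config.senescent_brightness, config.senescent_tint
        else:
            bright, tnt = config.live_brightness, config.live_tint
        intensity[body] = bright + rng.normal(0.0, 3.0)
        tint[body] = tnt

        if draw_hairs:
            hr = max(config.hair_width_mm / 2.0 / mm_per_px, 1.0)
            for hair in root.hairs:
                if hair.birth_day > day or hair.anchor_s_mm > vis:
                    continue
                distorted = (
                    hair.distortion_day is not None and day >= hair.distortion_day
                )
                poly = _hair_polyline(root, hair, distorted, config)
                pts_px = _resample_polyline(poly, 0.5 * mm_per_px) / mm_per_px
                seg = np.zeros((h, w), dtype=bool)
                _stamp_polyline(seg, pts_px, np.full(len(pts_px), hr))
                hair_mask |= seg
                paint = seg & ~mask
                intensity[paint] = config.hair_brightness
                tint[paint] = config.live_tint

    intensity = intensity + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(intensity[..., None] * tint, 0, 255).astype(np.uint8)
    return image, mask, hair_mask


def render_series(
    truth: RootSystemTruth, days, config: RenderConfig
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Render frames for each day; returns (images, masks, hair_masks)."""
    days = list(days)
    if not days or any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be non-empty and strictly increasing")
    images, masks, hair_masks = [], [], []
    for d in days:
        img, m, hm = render_frame(truth, d, config)
        images.append(img)
        masks.append(m)
        hair_masks.append(hm)
    return images, masks, hair_masks


def generate_series(
    truth: RootSystemTruth,
    days,
    config: RenderConfig,
    out_dir: str | Path,
    pot_id: str = "pot01",
) -> ImageSeries:
    """Render a daily series to disk alongside its ground-truth tables.

    Writes ``<pot>_d<day>_<dpi>dpi.png`` frames, ``truth_masks/`` PNG masks,
    CSV truth tables (per-day RL, per-root events, per-hair events) and a
    catalog manifest.  Returns the resulting :class:`ImageSeries`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks, hair_masks = render_series(truth, days, config)
    records = []
    for d, img, m in zip(days, images, masks):
        name = f"{pot_id}_d{d:03d}_{config.dpi}dpi.png"
        write_image(img, out_dir / name)
        write_mask(m, out_dir / "truth_masks" / name)
        records.append(
            ImageRecord(
                path=out_dir / name,
                pot_id=pot_id,
                day=int(d),
                dpi=config.dpi,
                resolution_class=(
                    "hair" if config.dpi >= config.hair_dpi_threshold else "morphology"
                ),
                pixels=img,
            )
        )
    series = ImageSeries(
        pot_id=pot_id,
        records=records,
        frame_width_cm=truth.params.frame_width_mm / 10.0,
        frame_height_cm=truth.params.frame_height_mm / 10.0,
    )
    truth.rl_table(days).to_csv(out_dir / "truth_rl.csv", index=False, lineterminator="\n")
    truth.root_events_table().to_csv(
        out_dir / "truth_root_events.csv", index=False, lineterminator="\n"
    )
    truth.hair_events_table().to_csv(
        out_dir / "truth_hair_events.csv", index=False, lineterminator="\n"
    )
    write_catalog(series, out_dir / "catalog.csv")
    return series
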