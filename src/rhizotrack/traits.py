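"""Morphological root traits from binary masks.

The mask is reduced to its medial axis (topology-preserving thinning) and
turned into an 8-connected pixel graph whose nodes carry a local radius
from the Euclidean distance transform.  Traits then follow directly:

* total root length **RL** (cm): skeleton length measured per maximal
  skeleton path with a short moving-average smoothing of the pixel
  coordinates, which removes the orientation-dependent staircase bias of
  plain chain-code counting (edges still carry 1 / sqrt(2) pixel weights
  for pruning and the cylinder models);
* average diameter **AD** (mm): mean over skeleton nodes of the local
  width, i.e. ``2 * (EDT - 0.5)`` pixels (the half-pixel term corrects the
  center-to-center distance to the shape boundary);
* surface area **RSA** (cm^2) and volume **RV** (cm^3): per-edge cylinder
  model using the mean local radius of the edge's endpoints;
* root length density **RLD** (cm/cm^3): ``RL / (A * DOF)`` with A the
  observed frame area and DOF the imaged depth of soil (default 0.25 cm).

Short spurs produced by thinning are pruned below a configurable physical
length so boundary roughness does not inflate RL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .catalog import ImageSeries, ScaleCalibration

__all__ = [
    "SkeletonGraph",
    "RootTraits",
    "FrameGeometry",
    "skeletonize_mask",
    "measure_traits",
    "traits_for_series",
]

SQRT2 = float(np.sqrt(2.0))

#: half-pixel correction from EDT (distance to nearest background pixel
#: center) to the true half-width of the shape
RADIUS_CORRECTION_PX = 0.5


def smooth_path_length_px(path) -> float:
    """Length of a pixel path after 5-point moving-average smoothing.

    Smoothing the integer pixel coordinates before summing segment
    lengths removes the orientation-dependent staircase bias (up to ~8%)
    of chain-code counting; endpoints are kept fixed.
    """
    pts = np.asarray(path, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) >= 7:
        kern = np.ones(5) / 5.0
        sm = pts.copy()
        sm[2:-2, 0] = np.convolve(pts[:, 0], kern, mode="valid")
        sm[2:-2, 1] = np.convolve(pts[:, 1], kern, mode="valid")
        pts = sm
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class FrameGeometry:
    """Observed frame area A (cm^2) and depth of imaged soil DOF (cm)."""

    A: float
    DOF: float = 0.25

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"frame area must be positive, got {self.A}")
        if self.DOF <= 0:
            raise ValueError(f"depth-of-soil must be positive, got {self.DOF}")


@dataclass
class SkeletonGraph:
    """Medial-axis pixel graph of a root mask.

    Nodes are (row, col) skeleton pixels with attribute ``radius`` (the
    raw EDT value in pixels); edges carry ``length`` in pixel units
    (1 or sqrt(2)).
    """

    graph: nx.Graph
    calibration: ScaleCalibration
    shape: tuple[int, int] = (0, 0)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def total_length_px(self) -> float:
        """Raw chain-code length: sum of 1 / sqrt(2) edge weights."""
        return float(
            sum(d["length"] for _, _, d in self.graph.edges(data=True))
        )

    def smoothed_length_px(self) -> float:
        """Digitization-bias-corrected skeleton length.

        The 1/sqrt(2) chain-code sum overestimates digitized curves by up
        to ~8% at intermediate orientations; measuring each maximal
        skeleton path after a 5-point moving-average smoothing of its
        pixel coordinates removes that staircase bias (sub-1% error on
        ribbons of any orientation).
        """
        g = self.graph
        total = 0.0
        visited: set[tuple] = set()
        measure = smooth_path_length_px

        breakpoints = [n for n in g.nodes if g.degree(n) != 2]
        for s in breakpoints:
            for nb in g.neighbors(s):
                if (s, nb) in visited:
                    continue
                path = [s, nb]
                visited.add((s, nb))
                visited.add((nb, s))
                prev, cur = s, nb
                while g.degree(cur) == 2:
                    nxt = next(x for x in g.neighbors(cur) if x != prev)
                    if (cur, nxt) in visited:
                        break
                    visited.add((cur, nxt))
                    visited.add((nxt, cur))
                    path.append(nxt)
                    prev, cur = cur, nxt
                total += measure(path)
        # pure cycles (every node degree 2) have no breakpoint to start from
        for u, v in g.edges:
            if (u, v) in visited:
                continue
            path = [u, v]
            visited.add((u, v))
            visited.add((v, u))
            prev, cur = u, v
            while cur != u:
                nxt = next(x for x in g.neighbors(cur) if x != prev)
                visited.add((cur, nxt))
                visited.add((nxt, cur))
                path.append(nxt)
                prev, cur = cur, nxt
            total += measure(path)
        return total


@dataclass(frozen=True)
class RootTraits:
    """WinRhizo-style per-frame morphology summary."""

    RL: float  # total root length, cm
    AD: float  # average root diameter, mm
    RSA: float  # total root surface area, cm^2
    RV: float  # root volume, cm^3
    RLD: float  # root length density, cm/cm^3
    day: int = -1


def _build_pixel_graph(skel: np.ndarray, edt: np.ndarray) -> nx.Graph:
    """8-connected graph over skeleton pixels.

    A diagonal edge is skipped when the two pixels share an orthogonal
    skeleton neighbour, so pixel triangles at junctions are not counted
    twice.
    """
    g = nx.Graph()
    coords = np.argwhere(skel)
    for r, c in coords:
        g.add_node((int(r), int(c)), radius=float(edt[r, c]))
    on = skel
    h, w = skel.shape

    def both(dr: int, dc: int):
        r0 = max(0, -dr)
        r1 = min(h, h - dr)
        c0 = max(0, -dc)
        c1 = min(w, w - dc)
        a = on[r0:r1, c0:c1]
        b = on[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        rr, cc = np.nonzero(a & b)
        return rr + r0, cc + c0

    # orthogonal steps
    for dr, dc in ((0, 1), (1, 0)):
        rr, cc = both(dr, dc)
        g.add_edges_from(
            (( int(r), int(c)), (int(r + dr), int(c + dc)), {"length": 1.0})
            for r, c in zip(rr, cc)
        )
    # diagonal steps without an orthogonal shortcut
    for dr, dc in ((1, 1), (1, -1)):
        rr, cc = both(dr, dc)
        for r, c in zip(rr, cc):
            r2, c2 = r + dr, c + dc
            if on[r, c2] or on[r2, c]:
                continue
            g.add_edge((int(r), int(c)), (int(r2), int(c2)), length=SQRT2)
    return g


def _prune_spurs(g: nx.Graph, prune_len_px: float) -> None:
    """Iteratively remove endpoint branches shorter than ``prune_len_px``
    that terminate at a junction (isolated short components are kept:
    filtering noise components is the segmentation stage's job)."""
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        for ep in endpoints:
            if ep not in g or g.degree(ep) != 1:
                continue
            path = [ep]
            length = 0.0
            cur, prev = ep, None
            hit_junction = False
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length"]
                if g.degree(nxt) >= 3:
                    hit_junction = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
                if length > prune_len_px:
                    break
            if hit_junction and length <= prune_len_px:
                g.remove_nodes_from(path)
                changed = True


def skeletonize_mask(
    mask: np.ndarray,
    calibration: ScaleCalibration,
    prune_len_mm: float = 1.0,
) -> SkeletonGraph:
    """Thin ``mask`` to its medial-axis graph with per-node radii.

    An empty mask yields an empty graph (not an error).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return SkeletonGraph(nx.Graph(), calibration, mask.shape)
    skel = skeletonize(mask)
    edt = distance_transform_edt(mask)
    g = _build_pixel_graph(skel, edt)
    if prune_len_mm > 0:
        _prune_spurs(g, prune_len_mm / calibration.mm_per_px)
    return SkeletonGraph(g, calibration, mask.shape)


def measure_traits(
    graph: SkeletonGraph,
    calibration: ScaleCalibration,
    geometry: FrameGeometry,
    day: int = -1,
) -> RootTraits:
    """Compute RL, AD, RSA, RV and RLD from a skeleton graph."""
    if geometry.A <= 0 or geometry.DOF <= 0:
        raise ValueError("invalid frame geometry")
    mmpp = calibration.mm_per_px
    g = graph.graph
    if g.number_of_edges() == 0:
        # no measurable length: all traits vanish together
        return RootTraits(0.0, 0.0, 0.0, 0.0, 0.0, day)

    rl_mm = graph.smoothed_length_px() * mmpp
    radii = np.array([d["radius"] for _, d in g.nodes(data=True)])
    r_mm = np.maximum(radii - RADIUS_CORRECTION_PX, 0.25) * mmpp
    ad_mm = float(np.mean(2.0 * r_mm))

    rsa_mm2 = 0.0
    rv_mm3 = 0.0
    for u, v, d in g.edges(data=True):
        ru = max(g.nodes[u]["radius"] - RADIUS_CORRECTION_PX, 0.25) * mmpp
        rv_ = max(g.nodes[v]["radius"] - RADIUS_CORRECTION_PX, 0.25) * mmpp
        r = 0.5 * (ru + rv_)
        ell = d["length"] * mmpp
        rsa_mm2 += np.pi * (2.0 * r) * ell
        rv_mm3 += np.pi * r * r * ell

    rl_cm = rl_mm / 10.0
    return RootTraits(
        RL=rl_cm,
        AD=ad_mm,
        RSA=rsa_mm2 / 100.0,
        RV=rv_mm3 / 1000.0,
        RLD=rl_cm / (geometry.A * geometry.DOF),
        day=day,
    )


def traits_for_series(
    series: ImageSeries,
    masks,
    geometry: FrameGeometry,
    *,
    prune_len_mm: float = 1.0,
) -> pd.DataFrame:
    """Per-day trait table for a series and its per-frame masks.

    ``masks`` is one binary mask per frame, in series (day) order.
    Returns a DataFrame with columns day, RL_cm, AD_mm, RSA_cm2, RV_cm3,
    RLD_cm_per_cm3.
    """
    masks = list(masks)
    if len(masks) != len(series):
        raise ValueError(
            f"{len(masks)} masks for {len(series)} frames — day mismatch"
        )
    cal = series.calibration
    rows = []
    for rec, m in zip(series.records, masks):
        m = m.mask if hasattr(m, "mask") else np.asarray(m)
        if m.shape[0] == 0 or m.ndim != 2:
            raise ValueError(f"bad mask for day {rec.day}")
        g = skeletonize_mask(m, cal, prune_len_mm)
        t = measure_traits(g, cal, geometry, day=rec.day)
        rows.append(
            {
                "day": rec.day,
                "RL_cm": t.RL,
                "AD_mm": t.AD,
                "RSA_cm2": t.RSA,
                "RV_cm3": t.RV,
                "RLD_cm_per_cm3": t.RLD,
            }
        )
    return pd.DataFrame(rows).sort_values("day", ignore_index=True)
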