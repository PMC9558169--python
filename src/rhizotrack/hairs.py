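"""Root-hair length and density from hair-grade (high-dpi) masks.

Hairs are separated from the root axis by local width on the skeleton:
nodes whose Euclidean-distance-transform width is at least
``axis_min_width_mm`` form the axis; thin side branches below
``hair_max_width_mm`` whose path length falls in a plausibility band are
counted as hairs.  A hair's length runs from the axis centerline to its
tip (the short gap between the thin branch and the axis is bridged along
the skeleton), and density is hairs per mm of axis skeleton in the
analyzed window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .catalog import ScaleCalibration
from .traits import RADIUS_CORRECTION_PX, skeletonize_mask, smooth_path_length_px

__all__ = ["HairParams", "HairMeasure", "SampledHairLengths",
           "detect_hairs", "sample_hair_lengths"]


@dataclass
class HairParams:
    """Width/length thresholds separating axis from hairs (all mm)."""

    axis_min_width_mm: float = 0.08
    hair_max_width_mm: float = 0.04
    hair_min_len_mm: float = 0.05
    hair_max_len_mm: float = 1.5
    #: scans below this dpi cannot resolve hairs
    min_dpi: int = 4800


@dataclass
class HairMeasure:
    """Hairs detected on one root axis window."""

    region_id: str
    hair_paths: list[list[tuple[int, int]]]  # skeleton (row, col) paths, axis->tip
    hair_lengths_mm: list[float]
    axis_length_mm: float

    @property
    def n_hairs(self) -> int:
        return len(self.hair_lengths_mm)

    @property
    def density_per_mm(self) -> float:
        return self.n_hairs / self.axis_length_mm

    @property
    def mean_length_mm(self) -> float:
        return float(np.mean(self.hair_lengths_mm)) if self.hair_lengths_mm else 0.0


def detect_hairs(
    mask_highres: np.ndarray,
    calibration: ScaleCalibration,
    params: HairParams | None = None,
    *,
    region_id: str = "window",
) -> HairMeasure:
    """Detect hairs on the root axis of a high-resolution binary mask.

    The mask should contain the root body and its hairs (e.g. the union
    of root and hair masks of a rendered frame, or a real segmentation at
    hair-grade dpi).
    """
    params = params or HairParams()
    if calibration.dpi < params.min_dpi:
        raise ValueError(
            f"resolution insufficient for hairs: {calibration.dpi} dpi < "
            f"{params.min_dpi} dpi"
        )
    mmpp = calibration.mm_per_px
    # prune below the minimum hair length so true hairs survive
    sk = skeletonize_mask(mask_highres, calibration,
                          prune_len_mm=0.6 * params.hair_min_len_mm)
    g = sk.graph

    def width_mm(node) -> float:
        r = g.nodes[node]["radius"] - RADIUS_CORRECTION_PX
        return max(2.0 * r, 1.0) * mmpp

    axis_nodes = {n for n in g.nodes if width_mm(n) >= params.axis_min_width_mm}
    if not axis_nodes:
        raise ValueError("no root axis found (no skeleton node wide enough)")
    thin_nodes = {n for n in g.nodes if width_mm(n) < params.hair_max_width_mm}

    # axis length: skeleton restricted to axis nodes
    axis_sub = g.subgraph(axis_nodes)
    axis_len_mm = sum(d["length"] for _, _, d in axis_sub.edges(data=True)) * mmpp
    if axis_len_mm <= 0:
        raise ValueError("degenerate root axis")

    # graph distance from the axis through any node (bridges the
    # intermediate-width shoulder between axis and thin branch)
    dist, paths = nx.multi_source_dijkstra(g, axis_nodes, weight="length")

    hair_paths: list[list[tuple[int, int]]] = []
    hair_lengths: list[float] = []
    for comp in nx.connected_components(g.subgraph(thin_nodes)):
        reachable = [n for n in comp if n in dist]
        if not reachable:
            continue  # floating debris, not rooted on the axis
        tip = max(reachable, key=lambda n: dist[n])
        # hair length is measured from the root *surface*: the skeleton
        # path starts on/near the axis centerline, so subtract the local
        # axis radius at the attachment node; the path itself is measured
        # with staircase smoothing
        attach = paths[tip][0]
        r_attach = max(g.nodes[attach]["radius"] - RADIUS_CORRECTION_PX, 0.0)
        length_mm_ = max(smooth_path_length_px(paths[tip]) - r_attach, 0.0) * mmpp
        if params.hair_min_len_mm <= length_mm_ <= params.hair_max_len_mm:
            hair_paths.append([tuple(p) for p in paths[tip]])
            hair_lengths.append(float(length_mm_))

    return HairMeasure(
        region_id=region_id,
        hair_paths=hair_paths,
        hair_lengths_mm=hair_lengths,
        axis_length_mm=float(axis_len_mm),
    )


@dataclass(frozen=True)
class SampledHairLengths:
    """A seeded without-replacement sample of hair lengths.

    Mirrors the manual protocol of measuring a handful of randomly chosen
    hairs, reported side by side with the full-population mean.
    """

    sampled_lengths_mm: tuple[float, ...]
    sampled_mean_mm: float
    population_mean_mm: float
    k_requested: int


def sample_hair_lengths(
    measure: HairMeasure, k: int = 5, seed: int = 0
) -> SampledHairLengths:
    """Sample ``k`` hairs without replacement (all hairs if fewer)."""
    if measure.n_hairs == 0:
        raise ValueError("no hairs to sample")
    rng = np.random.default_rng(seed)
    n = measure.n_hairs
    idx = rng.choice(n, size=min(k, n), replace=False)
    sampled = tuple(measure.hair_lengths_mm[i] for i in idx)
    return SampledHairLengths(
        sampled_lengths_mm=sampled,
        sampled_mean_mm=float(np.mean(sampled)),
        population_mean_mm=measure.mean_length_mm,
        k_requested=k,
    )
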