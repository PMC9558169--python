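"""Emergence/senescence events and survival analysis of roots and hairs.

A root's lifespan is the number of days between its first appearance in
the frame and the day its appearance turns brown; a hair's lifespan ends
when the hair becomes twisted and bent.  Operationally:

* frames are registered by integer-pixel translation to the first frame
  (scanner-fixed pots drift only by translation);
* a root region of interest (ROI) *emerges* on the first day it contains
  at least ``min_area`` segmented pixels;
* a root is *senescent* once the median brightness of its pixels drops
  below a threshold (live roots render bright/white, senescent roots dark
  brown);
* a hair is *distorted* once the tortuosity of its skeleton path — arc
  length over endpoint chord — exceeds a threshold (default 1.5);
* subjects still alive at the last frame are right-censored there.

Survival curves use the product-limit (Kaplan-Meier) estimator
``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` implemented here; the median
lifespan is the smallest observed event time with S(t) <= 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .catalog import to_grayscale

logger = logging.getLogger(__name__)

__all__ = [
    "RootEvent",
    "SurvivalCurve",
    "GroupComparison",
    "align_series",
    "classify_status",
    "hair_status",
    "extract_events",
    "kaplan_meier",
    "compare_groups",
]

SUBJECT_TYPES = ("lateral_root", "hair_order1", "hair_order2")

#: median brightness (0-255) at or above which root pixels count as live
LIVE_MIN_BRIGHTNESS = 160.0

#: skeleton-path tortuosity above which a hair counts as distorted
TORTUOSITY_THRESHOLD = 1.5


@dataclass(frozen=True)
class RootEvent:
    """(emergence, end, censored) of one root or hair."""

    subject_id: str
    subject_type: str
    emergence_day: int
    end_day: int
    censored: bool

    def __post_init__(self) -> None:
        if self.subject_type not in SUBJECT_TYPES:
            raise ValueError(f"unknown subject type {self.subject_type!r}")
        if self.end_day < self.emergence_day:
            raise ValueError("end_day must be >= emergence_day")

    @property
    def lifespan_days(self) -> int:
        return self.end_day - self.emergence_day


# ---------------------------------------------------------------------------
# registration


def align_series(
    frames,
    *,
    max_shift: int = 20,
    min_confidence: float = 0.2,
) -> list[tuple[int, int]]:
    """Integer translation of each frame relative to the first.

    The offset ``(dy, dx)`` is the displacement of the frame's content
    relative to the first frame: rolling the frame by ``(-dy, -dx)``
    aligns it.  Estimated by the cross-correlation peak (FFT); offsets
    beyond ``max_shift`` or with correlation below ``min_confidence``
    fall back to (0, 0) with a warning.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to align")
    ref = to_grayscale(np.asarray(frames[0], dtype=float))
    ref = ref - ref.mean()
    fr = np.fft.rfft2(ref)
    h, w = ref.shape
    offsets: list[tuple[int, int]] = [(0, 0)]
    for frame in frames[1:]:
        g = to_grayscale(np.asarray(frame, dtype=float))
        g = g - g.mean()
        # corr(s) = sum_x g(x) ref(x - s): peaks at the displacement of g
        corr = np.fft.irfft2(np.fft.rfft2(g) * np.conj(fr), s=ref.shape)
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
        dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
        denom = np.linalg.norm(ref) * np.linalg.norm(g)
        conf = corr[peak] / denom if denom > 0 else 0.0
        if abs(dy) > max_shift or abs(dx) > max_shift or conf < min_confidence:
            warnings.warn(
                f"alignment failed (shift ({dy},{dx}), confidence {conf:.2f}); "
                "using (0, 0)",
                stacklevel=2,
            )
            offsets.append((0, 0))
        else:
            offsets.append((int(dy), int(dx)))
    return offsets


def unshift(array: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Roll a frame/mask back by its offset, aligning it to the first frame."""
    return np.roll(array, (-offset[0], -offset[1]), axis=(0, 1))


# ---------------------------------------------------------------------------
# status calls


def classify_status(
    image: np.ndarray,
    mask_roi: np.ndarray,
    live_min_brightness: float = LIVE_MIN_BRIGHTNESS,
) -> str:
    """'live' or 'senescent' from the median brightness of root pixels.

    A median exactly at the threshold counts as live.
    """
    mask_roi = np.asarray(mask_roi).astype(bool)
    if not mask_roi.any():
        raise ValueError("empty ROI")
    gray = to_grayscale(image)
    med = float(np.median(gray[mask_roi]))
    return "live" if med >= live_min_brightness else "senescent"


def hair_status(
    skeleton_path, threshold: float = TORTUOSITY_THRESHOLD
) -> str:
    """'intact' or 'distorted' from the tortuosity of a hair skeleton path.

    Tortuosity is the path arc length divided by the endpoint chord
    distance; a perfectly straight hair scores 1.
    """
    path = np.asarray(skeleton_path, dtype=float)
    if path.ndim != 2 or len(path) < 3:
        raise ValueError("degenerate hair path (need >= 3 nodes)")
    arc = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
    chord = float(np.linalg.norm(path[-1] - path[0]))
    if chord == 0:
        return "distorted"  # closed curl
    return "distorted" if arc / chord > threshold else "intact"


# ---------------------------------------------------------------------------
# event extraction


def _hair_path_in_roi(mask_roi: np.ndarray, calibration) -> np.ndarray | None:
    """Longest skeleton path of the (thin) structure inside a hair ROI."""
    import networkx as nx

    from .traits import skeletonize_mask

    sk = skeletonize_mask(mask_roi, calibration, prune_len_mm=0.0)
    g = sk.graph
    if g.number_of_edges() < 2:
        return None
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    # two-sweep farthest-node heuristic for the longest path of a curve
    a = next(iter(comp))
    dist_a = nx.single_source_dijkstra_path_length(sub, a, weight="length")
    b = max(dist_a, key=dist_a.get)
    dist_b, paths_b = nx.single_source_dijkstra(sub, b, weight="length")
    c = max(dist_b, key=dist_b.get)
    return np.asarray(paths_b[c], dtype=float)


def extract_events(
    masks,
    images,
    rois: dict,
    days,
    *,
    calibration=None,
    offsets: list[tuple[int, int]] | None = None,
    min_area: int = 15,
    live_min_brightness: float = LIVE_MIN_BRIGHTNESS,
    tortuosity_threshold: float = TORTUOSITY_THRESHOLD,
) -> list[RootEvent]:
    """Determine (emergence, end, censored) for each subject ROI.

    ``rois`` maps subject_id to ``(subject_type, roi_mask)`` in the
    coordinates of the first (reference) frame.  Emergence is the first
    day the segmented mask populates the ROI with at least ``min_area``
    pixels; the end day is the first subsequent day the status call
    (brightness for roots, tortuosity for hairs) reports senescence or
    distortion; otherwise the subject is censored at the last day.
    Subjects whose ROI is never populated are dropped with a warning.
    """
    days = list(days)
    masks = [m.mask if hasattr(m, "mask") else np.asarray(m).astype(bool) for m in masks]
    images = list(images)
    if not (len(days) == len(masks) == len(images)):
        raise ValueError("days, masks and images must pair up")
    if offsets is not None:
        masks = [unshift(m, o) for m, o in zip(masks, offsets)]
        images = [unshift(np.asarray(im), o) for im, o in zip(images, offsets)]

    events: list[RootEvent] = []
    for subject_id, (subject_type, roi) in rois.items():
        if subject_type not in SUBJECT_TYPES:
            raise ValueError(f"unknown subject type {subject_type!r}")
        roi = np.asarray(roi).astype(bool)
        emergence = None
        end_day = None
        for day, m, im in zip(days, masks, images):
            inside = m & roi
            if emergence is None:
                if int(inside.sum()) >= min_area:
                    emergence = day
                else:
                    continue
            elif not inside.any():
                continue  # segmentation missed the subject this frame
            if subject_type == "lateral_root":
                status = classify_status(im, inside, live_min_brightness)
                dead = status == "senescent"
            else:
                path = _hair_path_in_roi(inside, calibration)
                dead = path is not None and (
                    hair_status(path, tortuosity_threshold) == "distorted"
                )
            if dead:
                end_day = day
                break
        if emergence is None:
            warnings.warn(f"subject {subject_id}: ROI never populated; dropped",
                          stacklevel=2)
            continue
        censored = end_day is None
        events.append(
            RootEvent(
                subject_id=subject_id,
                subject_type=subject_type,
                emergence_day=int(emergence),
                end_day=int(days[-1] if censored else end_day),
                censored=censored,
            )
        )
    return events


# ---------------------------------------------------------------------------
# survival analysis


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over event (death) times."""

    times: tuple[float, ...]  # distinct death times, increasing
    at_risk: tuple[int, ...]  # n_i just before each death time
    deaths: tuple[int, ...]  # d_i at each death time
    survival: tuple[float, ...]  # S(t_i)
    median: float | None  # smallest t with S(t) <= 0.5, None if never

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention, S(0) = 1."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def _durations(events) -> tuple[np.ndarray, np.ndarray]:
    if len(events) == 0:
        raise ValueError("no events")
    if all(isinstance(e, RootEvent) for e in events):
        dur = np.array([e.lifespan_days for e in events], dtype=float)
        obs = np.array([not e.censored for e in events], dtype=bool)
    else:  # (duration, observed) pairs
        dur = np.array([e[0] for e in events], dtype=float)
        obs = np.array([bool(e[1]) for e in events], dtype=bool)
    return dur, obs


def kaplan_meier(events) -> SurvivalCurve:
    """Kaplan-Meier product-limit survival curve of lifespans.

    ``events`` is a list of :class:`RootEvent` or of ``(duration,
    observed)`` pairs (observed=False means right-censored).  Censored
    subjects remain in the risk set through their censoring time and
    leave it afterwards.
    """
    dur, obs = _durations(events)
    if not obs.any() and np.all(dur[~obs] == 0):
        raise ValueError("all subjects censored at time 0; no information")
    death_times = np.unique(dur[obs])
    s = 1.0
    times, at_risk, deaths, surv = [], [], [], []
    median = None
    for t in death_times:
        n_i = int(np.sum(dur >= t))
        d_i = int(np.sum((dur == t) & obs))
        s *= 1.0 - d_i / n_i
        times.append(float(t))
        at_risk.append(n_i)
        deaths.append(d_i)
        surv.append(s)
        if median is None and s <= 0.5 + 1e-12:  # tolerate float ties at 1/2
            median = float(t)
    return SurvivalCurve(
        times=tuple(times),
        at_risk=tuple(at_risk),
        deaths=tuple(deaths),
        survival=tuple(surv),
        median=median,
    )


def plot_survival(curves: dict, path) -> None:
    """Write a step plot of one or more survival curves to ``path``.

    ``curves`` maps a label to a :class:`SurvivalCurve`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], np.asarray(c.times)])
        s = np.concatenate([[1.0], np.asarray(c.survival)])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("lifespan (days)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class GroupComparison:
    median_a: float | None
    median_b: float | None
    median_difference: float | None  # b - a; None if either median undefined
    logrank_chi_sq: float
    logrank_p: float


def compare_groups(events_a, events_b) -> GroupComparison:
    """Median-lifespan difference and log-rank test between two groups.

    The log-rank chi-square and p-value come from the standard two-group
    test (lifelines).  Requires at least two uncensored events per group;
    an undefined median leaves the difference undefined but the log-rank
    statistic is still computed.
    """
    dur_a, obs_a = _durations(events_a)
    dur_b, obs_b = _durations(events_b)
    if obs_a.sum() < 2 or obs_b.sum() < 2:
        raise ValueError("each group needs >= 2 uncensored events")
    km_a = kaplan_meier(events_a)
    km_b = kaplan_meier(events_b)
    if np.array_equal(dur_a, dur_b) and np.array_equal(obs_a, obs_b):
        # identical samples carry no evidence of a difference
        chi, p = 0.0, 1.0
    else:
        from lifelines.statistics import logrank_test

        res = logrank_test(dur_a, dur_b, event_observed_A=obs_a,
                           event_observed_B=obs_b)
        chi, p = float(res.test_statistic), float(res.p_value)
    diff = None
    if km_a.median is not None and km_b.median is not None:
        diff = km_b.median - km_a.median
    return GroupComparison(
        median_a=km_a.median,
        median_b=km_b.median,
        median_difference=diff,
        logrank_chi_sq=chi,
        logrank_p=p,
    )
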