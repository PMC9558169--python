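"""Root segmentation: classical baseline, trainable encoder-decoder, metrics.

The trainable model follows the encoder-decoder pattern used for cluttered
root scenes: a small strided CNN encoder, atrous spatial pyramid pooling
(parallel dilated convolutions over the deepest features) for multi-scale
context, and a decoder that upsamples with sub-pixel convolution (pixel
shuffle) instead of interpolation so thin root trajectories are not blurred
away.  Sub-pixel upsampling is applied at every decoder stage.  The model
is deliberately small — a few thousand parameters — because the synthetic
scenes it is scored on are desk-scale; the architecture pattern, not the
capacity, is the point.

A classical baseline (`threshold_segment`: background flattening, adaptive
thresholding, morphological cleanup) plays the role of a non-learned
reference segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.ndimage import binary_opening, label, uniform_filter
from skimage.filters import threshold_local
from skimage.morphology import disk
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import nn
from .catalog import ScaleCalibration, to_grayscale

__all__ = [
    "RootMask",
    "SegScores",
    "SubPixelRootSegmenter",
    "threshold_segment",
    "train_model",
    "predict_mask",
    "evaluate",
    "compare_trait_agreement",
]


@dataclass
class RootMask:
    """A binary segmentation aligned to its source frame."""

    mask: np.ndarray
    provenance: str = "model"  # classical | model | manual | truth

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.provenance not in ("classical", "model", "manual", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def density(self) -> float:
        return float(self.mask.mean())


def _as_mask_array(m) -> np.ndarray:
    if isinstance(m, RootMask):
        return m.mask
    return np.asarray(m).astype(bool)


@dataclass(frozen=True)
class SegScores:
    """Overlap metrics between a mask and a reference; all in [0, 1]."""

    iou: float
    dice: float
    precision: float
    recall: float


def evaluate(mask, reference) -> SegScores:
    """IoU/Dice/precision/recall of ``mask`` against ``reference``.

    Two empty masks are in perfect agreement (all scores 1).
    """
    a = _as_mask_array(mask)
    b = _as_mask_array(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    inter = float(np.logical_and(a, b).sum())
    union = float(np.logical_or(a, b).sum())
    na, nb = float(a.sum()), float(b.sum())
    if union == 0:
        return SegScores(1.0, 1.0, 1.0, 1.0)
    iou = inter / union
    return SegScores(
        iou=iou,
        dice=2.0 * iou / (1.0 + iou),
        precision=inter / na if na else (1.0 if nb == 0 else 0.0),
        recall=inter / nb if nb else (1.0 if na == 0 else 0.0),
    )


# ---------------------------------------------------------------------------
# classical baseline


def threshold_segment(
    image: np.ndarray,
    *,
    flatten_size: int = 35,
    block_size: int = 51,
    offset: float = 20.0,
    opening_radius: int = 1,
    min_area: int = 30,
) -> RootMask:
    """Classical brightness-based segmentation of a soil-background frame.

    Pipeline: remove the smooth background with a large local-mean filter,
    adaptively threshold the flattened brightness (a pixel must exceed its
    neighbourhood mean by ``offset`` grey levels), open with a small disk
    and drop components below ``min_area`` pixels.  Deterministic.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    gray = to_grayscale(image)
    flat = gray - uniform_filter(gray, size=flatten_size)
    thresh = threshold_local(flat, block_size=block_size, method="gaussian",
                             offset=-offset)
    binary = flat > thresh
    if opening_radius > 0:
        binary = binary_opening(binary, structure=disk(opening_radius))
    if min_area > 1 and binary.any():
        lbl, _ = label(binary, structure=np.ones((3, 3), dtype=bool))
        sizes = np.bincount(lbl.ravel())
        keep = sizes >= min_area
        keep[0] = False
        binary = keep[lbl]
    return RootMask(binary, provenance="classical")


# ---------------------------------------------------------------------------
# trainable encoder-decoder


class SubPixelRootSegmenter(BaseEstimator):
    """Trainable encoder-decoder root segmenter (numpy, CPU).

    Parameters
    ----------
    enc_channels : tuple of int
        Channel widths of the encoder; the first entry is the full-resolution
        stem, each subsequent entry adds a stride-2 stage.  The total
        downsampling factor is ``2 ** (len(enc_channels) - 1)`` and is undone
        by the same number of x2 sub-pixel upsampling stages, so the two
        always match.
    aspp_rates : tuple of int
        Dilation rates of the parallel atrous convolutions; at least three
        distinct positive integers.
    aspp_channels : int
        Channels of each atrous branch and of the fused context map.
    epochs, lr, batch_size : training schedule (Adam).
    patch_size : int
        Side of the square training patches (and prediction tiles).
    patches_per_frame : int
        Patches sampled per frame per epoch; half are centered on a random
        foreground pixel so thin roots are not swamped by background.
    w_bce, w_dice : float
        Weights of the cross-entropy and Dice terms of the loss.
    random_state : int
        Seeds initialization, patch sampling and augmentation.

    Attributes
    ----------
    params_ : list of nn.Tensor
        Learned weights.
    loss_history_ : list of float
        Mean training loss per epoch.
    """

    def __init__(
        self,
        enc_channels: tuple[int, ...] = (8, 16, 16),
        aspp_rates: tuple[int, ...] = (1, 2, 4),
        aspp_channels: int = 16,
        epochs: int = 10,
        lr: float = 5e-3,
        batch_size: int = 8,
        patch_size: int = 64,
        patches_per_frame: int = 14,
        w_bce: float = 1.0,
        w_dice: float = 1.0,
        random_state: int = 0,
    ):
        self.enc_channels = enc_channels
        self.aspp_rates = aspp_rates
        self.aspp_channels = aspp_channels
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.patches_per_frame = patches_per_frame
        self.w_bce = w_bce
        self.w_dice = w_dice
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _validate_config(self) -> None:
        if len(self.enc_channels) < 2:
            raise ValueError("need at least one stride-2 encoder stage")
        rates = tuple(self.aspp_rates)
        if len(rates) < 3 or len(set(rates)) != len(rates) or min(rates) < 1:
            raise ValueError("aspp_rates must be >=3 distinct positive integers")
        if self.patch_size % self._downsample() != 0:
            raise ValueError("patch_size must be divisible by the downsampling factor")

    def _downsample(self) -> int:
        return 2 ** (len(self.enc_channels) - 1)

    def _build(self, rng: np.random.Generator) -> None:
        T = nn.Tensor
        he = nn.he_init
        enc = list(self.enc_channels)
        self._layers: dict[str, tuple[nn.Tensor, nn.Tensor]] = {}

        def add(name: str, co: int, ci: int, k: int) -> None:
            self._layers[name] = (
                T(he(rng, (co, ci, k, k)), name=f"{name}.w"),
                T(np.zeros(co), name=f"{name}.b"),
            )

        add("stem", enc[0], 3, 3)
        for i in range(1, len(enc)):
            add(f"down{i}", enc[i], enc[i - 1], 3)
        for r in self.aspp_rates:
            add(f"aspp{r}", self.aspp_channels, enc[-1], 3)
        add("aspp_proj", self.aspp_channels,
            self.aspp_channels * len(self.aspp_rates), 1)

        cur = self.aspp_channels
        self._dec_ch = []
        for i in range(len(enc) - 1, 0, -1):
            dch = max(4, enc[i - 1] // 2)
            self._dec_ch.append(dch)
            add(f"up{i}", 4 * dch, cur, 1)  # channels for the x2 pixel shuffle
            add(f"fuse{i}", max(8, dch), dch + enc[i - 1], 3)
            cur = max(8, dch)
        add("head", 1, cur, 1)
        self.params_ = [t for pair in self._layers.values() for t in pair]

    def _forward(self, x: np.ndarray) -> nn.Tensor:
        L = self._layers
        t = nn.Tensor(x)
        feats = [nn.relu(nn.conv2d(t, *L["stem"]))]
        for i in range(1, len(self.enc_channels)):
            feats.append(nn.relu(nn.conv2d(feats[-1], *L[f"down{i}"], stride=2)))
        branches = [
            nn.relu(nn.conv2d(feats[-1], *L[f"aspp{r}"], dilation=r))
            for r in self.aspp_rates
        ]
        u = nn.relu(nn.conv2d(nn.concat(branches), *L["aspp_proj"]))
        for i in range(len(self.enc_channels) - 1, 0, -1):
            u = nn.pixel_shuffle(nn.conv2d(u, *L[f"up{i}"]), 2)
            u = nn.relu(nn.conv2d(nn.concat([u, feats[i - 1]]), *L[f"fuse{i}"]))
        return nn.conv2d(u, *L["head"])

    # -- training ----------------------------------------------------------

    @staticmethod
    def _normalize(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        return img.transpose(2, 0, 1) / 255.0 - 0.5

    def _sample_patch(
        self, rng: np.random.Generator, img: np.ndarray, msk: np.ndarray,
        fg_coords: np.ndarray | None,
    ) -> tuple[np.ndarray, np.ndarray]:
        ps = self.patch_size
        _, h, w = img.shape
        if fg_coords is not None and len(fg_coords) and rng.random() < 0.5:
            r, c = fg_coords[rng.integers(len(fg_coords))]
            y0 = int(np.clip(r - ps // 2 + rng.integers(-8, 9), 0, h - ps))
            x0 = int(np.clip(c - ps // 2 + rng.integers(-8, 9), 0, w - ps))
        else:
            y0 = int(rng.integers(0, h - ps + 1))
            x0 = int(rng.integers(0, w - ps + 1))
        xa = img[:, y0 : y0 + ps, x0 : x0 + ps]
        ya = msk[y0 : y0 + ps, x0 : x0 + ps]
        k = int(rng.integers(4))
        xa = np.rot90(xa, k, axes=(1, 2))
        ya = np.rot90(ya, k)
        if rng.random() < 0.5:
            xa = xa[:, :, ::-1]
            ya = ya[:, ::-1]
        # photometric jitter: scanners and pots differ slightly in gain
        # and offset, and root/soil brightness varies between plants
        xa = xa * rng.uniform(0.9, 1.1) + rng.uniform(-0.04, 0.04)
        return np.ascontiguousarray(xa), np.ascontiguousarray(ya)

    def fit(self, frames, masks) -> "SubPixelRootSegmenter":
        """Train on paired frames and binary truth masks."""
        self._validate_config()
        if len(frames) == 0:
            raise ValueError("empty training set")
        if len(frames) != len(masks):
            raise ValueError("frames and masks must pair up")
        xs, ys, fgs = [], [], []
        for f, m in zip(frames, masks):
            m = _as_mask_array(m)
            f = np.asarray(f)
            if f.shape[:2] != m.shape:
                raise ValueError(f"frame {f.shape[:2]} vs mask {m.shape} mismatch")
            if min(m.shape) < self.patch_size:
                raise ValueError(
                    f"frame smaller than patch_size {self.patch_size}: {m.shape}"
                )
            xs.append(self._normalize(f))
            ys.append(m.astype(np.float64))
            coords = np.argwhere(m)
            fgs.append(coords if len(coords) else None)

        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        opt = nn.Adam(self.params_, lr=self.lr)
        self.loss_history_ = []
        n_frames = len(xs)
        for _epoch in range(self.epochs):
            order = rng.permutation(n_frames).repeat(self.patches_per_frame)
            rng.shuffle(order)
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = [self._sample_patch(rng, xs[i], ys[i], fgs[i]) for i in idx]
                xb = np.stack([b[0] for b in batch])
                yb = np.stack([b[1] for b in batch])[:, None]
                opt.zero_grad()
                logits = self._forward(xb)
                loss = nn.bce_dice_loss(logits, yb, self.w_bce, self.w_dice)
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            if not np.isfinite(losses).all():
                raise FloatingPointError("non-finite training loss")
            self.loss_history_.append(float(np.mean(losses)))
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise NotFittedError("model is not trained; call fit() first")

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel root probability map, same height/width as the input.

        Frames larger than the patch size are tiled with 25% overlap and
        stitched from tile centers.
        """
        self._check_fitted()
        x = self._normalize(np.asarray(image))
        _, h, w = x.shape
        ps = self.patch_size
        ds = self._downsample()

        def run(tile: np.ndarray) -> np.ndarray:
            logits = self._forward(tile[None])
            return nn.sigmoid(logits.data[0, 0])

        if h <= ps and w <= ps:
            hp = -(-max(h, ds) // ds) * ds
            wp = -(-max(w, ds) // ds) * ds
            xp = np.pad(x, ((0, 0), (0, hp - h), (0, wp - w)), mode="reflect")
            return run(xp)[:h, :w]

        hp = max(h, ps)
        wp = max(w, ps)
        xp = np.pad(x, ((0, 0), (0, hp - h), (0, wp - w)), mode="reflect")
        overlap = ps // 4
        stride = ps - overlap
        margin = overlap // 2
        acc = np.zeros((hp, wp))
        cnt = np.zeros((hp, wp))
        ys = sorted({min(y, hp - ps) for y in range(0, hp, stride)})
        xs_ = sorted({min(xx, wp - ps) for xx in range(0, wp, stride)})
        for y0 in ys:
            for x0 in xs_:
                p = run(xp[:, y0 : y0 + ps, x0 : x0 + ps])
                t0 = 0 if y0 == 0 else margin
                l0 = 0 if x0 == 0 else margin
                t1 = ps if y0 + ps == hp else ps - margin
                l1 = ps if x0 + ps == wp else ps - margin
                acc[y0 + t0 : y0 + t1, x0 + l0 : x0 + l1] += p[t0:t1, l0:l1]
                cnt[y0 + t0 : y0 + t1, x0 + l0 : x0 + l1] += 1
        assert cnt.min() > 0
        return (acc / cnt)[:h, :w]

    def predict(self, image: np.ndarray, threshold: float = 0.5) -> RootMask:
        """Thresholded probability map as a :class:`RootMask`."""
        return RootMask(self.predict_proba(image) > threshold, provenance="model")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize weights and config to a single ``.npz`` checkpoint."""
        self._check_fitted()
        arrays = {}
        for name, (wt, bt) in self._layers.items():
            arrays[f"{name}.w"] = wt.data
            arrays[f"{name}.b"] = bt.data
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.get_params()).encode(), dtype=np.uint8
            ),
            __loss__=np.asarray(self.loss_history_),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubPixelRootSegmenter":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            for k in ("enc_channels", "aspp_rates"):
                cfg[k] = tuple(cfg[k])
            model = cls(**cfg)
            model._build(np.random.default_rng(0))
            for name, (wt, bt) in model._layers.items():
                wt.data = data[f"{name}.w"].copy()
                bt.data = data[f"{name}.b"].copy()
            model.loss_history_ = list(data["__loss__"])
        return model


def train_model(frames, truth_masks, config: dict | None = None) -> SubPixelRootSegmenter:
    """Convenience wrapper: build a :class:`SubPixelRootSegmenter` and fit it."""
    model = SubPixelRootSegmenter(**(config or {}))
    return model.fit(frames, truth_masks)


def predict_mask(
    model: SubPixelRootSegmenter, image: np.ndarray, threshold: float = 0.5
) -> RootMask:
    return model.predict(image, threshold=threshold)


# ---------------------------------------------------------------------------
# trait-level agreement


def compare_trait_agreement(
    masks_auto,
    masks_ref,
    calibration: ScaleCalibration,
    *,
    prune_len_mm: float = 1.0,
) -> dict[str, float]:
    """Coefficient of determination (squared Pearson r) per trait.

    Measures RL, AD, RSA and RV on both mask sets through the trait
    pipeline and regresses automatic against reference values, mirroring
    the agreement analysis used to validate learned segmentation against
    manual tracing.  Requires at least 3 pairs.
    """
    from .traits import FrameGeometry, measure_traits, skeletonize_mask

    if len(masks_auto) != len(masks_ref):
        raise ValueError("mask lists must pair up")
    if len(masks_auto) < 3:
        raise ValueError("need >= 3 mask pairs for a stable R^2")
    geometry = FrameGeometry(A=1.0, DOF=1.0)  # RLD not compared here
    vals: dict[str, list[list[float]]] = {
        t: [[], []] for t in ("RL", "AD", "RSA", "RV")
    }
    for a, r in zip(masks_auto, masks_ref):
        for k, m in enumerate((a, r)):
            g = skeletonize_mask(_as_mask_array(m), calibration, prune_len_mm)
            tr = measure_traits(g, calibration, geometry)
            vals["RL"][k].append(tr.RL)
            vals["AD"][k].append(tr.AD)
            vals["RSA"][k].append(tr.RSA)
            vals["RV"][k].append(tr.RV)

    out = {}
    for trait, (auto, ref) in vals.items():
        auto = np.asarray(auto)
        ref = np.asarray(ref)
        if np.allclose(auto, ref):
            out[trait] = 1.0
        elif np.std(auto) == 0 or np.std(ref) == 0:
            out[trait] = 0.0
        else:
            out[trait] = float(stats.pearsonr(auto, ref)[0] ** 2)
    return out
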