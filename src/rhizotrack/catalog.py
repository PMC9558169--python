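"""Raster I/O, per-pot time-series catalogs and physical-scale calibration.

Frames come off a flatbed scanner pressed against the viewing panel of a
rhizotron pot.  Each file encodes the pot identifier, the day after sowing
and the scan resolution in its name; a series is the set of frames for one
pot at one resolution, ordered by day.  Lower-resolution scans (around
1200 dpi in practice, any value from 50 dpi) serve root morphology and
lifespan analysis; very high resolution scans (default threshold 4800 dpi)
resolve root hairs.

All physical conversions derive from the scan dpi alone:
``mm_per_px = 25.4 / dpi`` and ``px_per_cm = dpi / 2.54``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default filename convention: ``<pot>_d<day>_<dpi>dpi.<ext>`` with a
#: zero-padded day, e.g. ``pot03_d001_1200dpi.png``.
DEFAULT_PATTERN = (
    r"(?P<pot>[A-Za-z0-9-]+)_d(?P<day>\d+)_(?P<dpi>\d+)dpi\.(?:png|tif|tiff)$"
)

DPI_MIN = 50
DPI_MAX = 4800

#: Scans at or above this dpi are classed as root-hair resolution.
HAIR_DPI_THRESHOLD = 4800

#: Default physical face of the observation panel, cm (width, height).
#: The scanned window may be smaller; override per series.
DEFAULT_FRAME_CM = (20.0, 34.0)


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-physical-unit conversion for a given scan resolution."""

    dpi: float
    mm_per_px: float
    px_per_cm: float

    @classmethod
    def from_dpi(cls, dpi: float) -> "ScaleCalibration":
        if dpi <= 0:
            raise ValueError(f"dpi must be positive, got {dpi}")
        return cls(dpi=dpi, mm_per_px=25.4 / dpi, px_per_cm=dpi / 2.54)


def calibrate(dpi: float) -> ScaleCalibration:
    """Return the :class:`ScaleCalibration` for ``dpi`` dots per inch."""
    return ScaleCalibration.from_dpi(dpi)


@dataclass
class ImageRecord:
    """One time-stamped scanner frame of a pot.

    ``pixels`` is loaded lazily: it is ``None`` until :meth:`load` is
    called (or the record was constructed in memory).
    """

    path: Path | None
    pot_id: str
    day: int
    dpi: int
    resolution_class: str = "morphology"
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        if not (DPI_MIN <= self.dpi <= DPI_MAX):
            raise ValueError(
                f"dpi {self.dpi} outside supported range [{DPI_MIN}, {DPI_MAX}]"
            )
        if self.resolution_class not in ("morphology", "hair"):
            raise ValueError(f"unknown resolution class {self.resolution_class!r}")

    def load(self) -> np.ndarray:
        """Read and cache the RGB raster from disk."""
        if self.pixels is None:
            if self.path is None:
                raise ValueError("record has neither pixels nor a path")
            self.pixels = read_image(self.path)
        return self.pixels

    @property
    def calibration(self) -> ScaleCalibration:
        return ScaleCalibration.from_dpi(self.dpi)


@dataclass
class ImageSeries:
    """Daily frames of one pot at one resolution, sorted by day."""

    pot_id: str
    records: list[ImageRecord] = field(default_factory=list)
    frame_width_cm: float = DEFAULT_FRAME_CM[0]
    frame_height_cm: float = DEFAULT_FRAME_CM[1]

    def __post_init__(self) -> None:
        if self.frame_width_cm <= 0 or self.frame_height_cm <= 0:
            raise ValueError("frame dimensions must be positive")
        self.records.sort(key=lambda r: r.day)
        days = [r.day for r in self.records]
        if len(set(days)) != len(days):
            raise ValueError(f"duplicate days in series {self.pot_id}: {days}")
        dpis = {r.dpi for r in self.records}
        if len(dpis) > 1:
            raise ValueError(f"mixed dpi within series {self.pot_id}: {sorted(dpis)}")

    @property
    def days(self) -> list[int]:
        return [r.day for r in self.records]

    @property
    def dpi(self) -> int:
        if not self.records:
            raise ValueError("empty series has no dpi")
        return self.records[0].dpi

    @property
    def calibration(self) -> ScaleCalibration:
        return ScaleCalibration.from_dpi(self.dpi)

    @property
    def frame_area_cm2(self) -> float:
        """Observed frame area A, cm^2 (denominator of root length density)."""
        return self.frame_width_cm * self.frame_height_cm

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _classify_resolution(dpi: int, hair_dpi_threshold: int) -> str:
    return "hair" if dpi >= hair_dpi_threshold else "morphology"


def load_series(
    directory: str | Path,
    naming_pattern: str = DEFAULT_PATTERN,
    *,
    pot_id: str | None = None,
    dpi: int | None = None,
    hair_dpi_threshold: int = HAIR_DPI_THRESHOLD,
    frame_width_cm: float = DEFAULT_FRAME_CM[0],
    frame_height_cm: float = DEFAULT_FRAME_CM[1],
) -> ImageSeries:
    """Scan ``directory`` for frames matching ``naming_pattern``.

    The pattern must expose named groups ``pot``, ``day`` and ``dpi``.
    Files that do not match are skipped with a warning; a duplicate
    (pot, day, dpi) combination or an empty directory is an error.  If the
    directory holds several pots or resolutions, disambiguate with
    ``pot_id`` / ``dpi``.
    """
    directory = Path(directory)
    rx = re.compile(naming_pattern)
    found: dict[tuple[str, int, int], Path] = {}
    for path in sorted(directory.iterdir() if directory.is_dir() else []):
        m = rx.match(path.name)
        if m is None:
            if path.is_file():
                logger.warning("skipping %s: name does not match pattern", path.name)
            continue
        key = (m.group("pot"), int(m.group("day")), int(m.group("dpi")))
        if key in found:
            raise ValueError(
                f"duplicate frame for pot={key[0]} day={key[1]} dpi={key[2]}: "
                f"{found[key].name} and {path.name}"
            )
        found[key] = path

    if pot_id is not None:
        found = {k: v for k, v in found.items() if k[0] == pot_id}
    if dpi is not None:
        found = {k: v for k, v in found.items() if k[2] == dpi}
    if not found:
        raise ValueError(f"no frames found in {directory}")

    pots = {k[0] for k in found}
    if len(pots) > 1:
        raise ValueError(f"multiple pots in {directory}: {sorted(pots)}; pass pot_id=")
    dpis = {k[2] for k in found}
    if len(dpis) > 1:
        raise ValueError(f"multiple resolutions in {directory}: {sorted(dpis)}; pass dpi=")

    records = [
        ImageRecord(
            path=path,
            pot_id=pot,
            day=day,
            dpi=d,
            resolution_class=_classify_resolution(d, hair_dpi_threshold),
        )
        for (pot, day, d), path in sorted(found.items())
    ]
    return ImageSeries(
        pot_id=records[0].pot_id,
        records=records,
        frame_width_cm=frame_width_cm,
        frame_height_cm=frame_height_cm,
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF frame as an (H, W, 3) uint8 array."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask losslessly: foreground white (255), background black.

    Raises ``ValueError`` for non-binary input.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask is not binary; values {vals[:10]}")
        mask = mask.astype(bool)
    write_image(mask.astype(np.uint8) * 255, path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to a boolean array."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance of an RGB frame as float in [0, 255]."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114


def write_catalog(series: ImageSeries | Sequence[ImageSeries], path: str | Path) -> None:
    """Serialize one or more series to a CSV manifest (pot_id, day, dpi, path)."""
    if isinstance(series, ImageSeries):
        series = [series]
    rows = [
        {"pot_id": r.pot_id, "day": r.day, "dpi": r.dpi,
         "path": str(r.path) if r.path is not None else ""}
        for s in series
        for r in s.records
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["pot_id", "day", "dpi", "path"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_catalog(
    path: str | Path,
    *,
    hair_dpi_threshold: int = HAIR_DPI_THRESHOLD,
    frame_width_cm: float = DEFAULT_FRAME_CM[0],
    frame_height_cm: float = DEFAULT_FRAME_CM[1],
) -> list[ImageSeries]:
    """Load series from a CSV manifest written by :func:`write_catalog`."""
    df = pd.read_csv(path)
    out = []
    for (pot, dpi), grp in df.groupby(["pot_id", "dpi"], sort=True):
        records = [
            ImageRecord(
                path=Path(row.path) if row.path else None,
                pot_id=str(pot),
                day=int(row.day),
                dpi=int(dpi),
                resolution_class=_classify_resolution(int(dpi), hair_dpi_threshold),
            )
            for row in grp.itertuples()
        ]
        out.append(
            ImageSeries(
                pot_id=str(pot),
                records=records,
                frame_width_cm=frame_width_cm,
                frame_height_cm=frame_height_cm,
            )
        )
    return out
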