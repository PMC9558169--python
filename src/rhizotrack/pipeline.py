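"""Batch orchestration: catalog -> segment -> traits -> dynamics -> hairs
-> lifespan, with a reproducibility manifest.

Every run writes a plain-text ``manifest.txt`` recording the software
version, a hash of the effective configuration, the seeds, and per-stage
status, which together suffice to reproduce the run.  Output tables are
CSV with a fixed float format so reruns under identical config and seeds
are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import binary_dilation, label

from . import __version__
from .catalog import ImageSeries, load_series, write_catalog, write_mask
from .config import PipelineConfig, to_dict
from .dynamics import rld_ngr
from .hairs import detect_hairs
from .lifespan import align_series, extract_events, kaplan_meier
from .segmentation import SubPixelRootSegmenter, threshold_segment
from .synthetic import RenderConfig, generate_series, grow_root_system
from .traits import FrameGeometry, traits_for_series

logger = logging.getLogger(__name__)

STAGES = ("catalog", "segment", "traits", "dynamics", "hairs", "lifespan")

_CSV_KW = dict(index=False, lineterminator="\n", float_format="%.10g")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _config_hash(config: PipelineConfig) -> str:
    text = yaml.safe_dump(to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_manifest(path: Path, config: PipelineConfig, status: dict[str, str]) -> None:
    lines = [
        f"version={__version__}",
        f"config_sha256={_config_hash(config)}",
        f"seed={config.seed}",
    ]
    lines += [f"stage_{s}={status.get(s, 'pending')}" for s in STAGES]
    path.write_text("\n".join(lines) + "\n")


def simulate(config: PipelineConfig, seed: int | None = None) -> ImageSeries:
    """Write a synthetic dataset (frames + truth tables) to ``input_dir``.

    Parameters are validated before any file is written.
    """
    sim = config.simulate
    sim.growth.validate()
    render = sim.render
    if seed is not None:
        render = RenderConfig(**{**to_dict(config)["simulate"]["render"], "seed": seed})
        growth_seed = seed
    else:
        growth_seed = render.seed
    truth = grow_root_system(sim.growth, seed=growth_seed)
    return generate_series(
        truth, sim.days(), render, config.input_dir, pot_id=sim.pot_id
    )


def run_pipeline(
    config: PipelineConfig,
    skip: tuple[str, ...] = (),
) -> dict:
    """Execute the full workflow; returns a dict of in-memory results.

    Stages listed in ``skip`` are marked skipped; a stage failure aborts
    the run, leaving partial outputs plus a manifest marking the failed
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    manifest = out / "manifest.txt"
    results: dict = {}

    def fail(stage: str, exc: Exception):
        status[stage] = "failed"
        _write_manifest(manifest, config, status)
        raise PipelineError(stage, str(exc)) from exc

    # -- catalog -----------------------------------------------------------
    stage = "catalog"
    try:
        series = load_series(
            config.input_dir,
            config.naming_pattern,
            pot_id=config.pot_id,
            dpi=config.dpi,
            hair_dpi_threshold=config.hair_dpi_threshold,
            frame_width_cm=config.frame_width_cm,
            frame_height_cm=config.frame_height_cm,
        )
        for rec in series:
            rec.load()
        write_catalog(series, out / "catalog.csv")
        results["series"] = series
        status[stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- segmentation ------------------------------------------------------
    stage = "segment"
    try:
        seg = config.segmentation
        masks = []
        if seg.method == "model":
            if not seg.model_path:
                raise ValueError("segmentation.method=model requires model_path")
            model = SubPixelRootSegmenter.load(seg.model_path)
        for rec in series:
            if seg.method == "threshold":
                m = threshold_segment(
                    rec.pixels,
                    flatten_size=seg.flatten_size,
                    block_size=seg.block_size,
                    offset=seg.offset,
                    opening_radius=seg.opening_radius,
                    min_area=seg.min_area,
                )
            else:
                m = model.predict(rec.pixels, threshold=seg.threshold)
            masks.append(m)
            write_mask(
                m.mask, out / "masks" / f"{rec.pot_id}_d{rec.day:03d}_mask.png"
            )
        results["masks"] = masks
        status[stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- traits ------------------------------------------------------------
    stage = "traits"
    try:
        geometry = FrameGeometry(A=series.frame_area_cm2, DOF=config.traits.dof_cm)
        trait_table = traits_for_series(
            series, [m.mask for m in masks], geometry,
            prune_len_mm=config.traits.prune_len_mm,
        )
        trait_table.to_csv(out / "traits.csv", **_CSV_KW)
        results["traits"] = trait_table
        status[stage] = "completed"
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- dynamics ----------------------------------------------------------
    stage = "dynamics"
    if stage in skip:
        status[stage] = "skipped"
    else:
        try:
            dyn = rld_ngr(trait_table)
            dyn.table.to_csv(out / "dynamics.csv", **_CSV_KW)
            results["dynamics"] = dyn
            status[stage] = "completed"
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # -- hairs -------------------------------------------------------------
    stage = "hairs"
    if stage in skip:
        status[stage] = "skipped"
    elif series.dpi < config.hairs.min_dpi:
        logger.info("hair stage skipped: %d dpi below hair threshold", series.dpi)
        status[stage] = "skipped"
    else:
        try:
            rows = []
            for rec, m in zip(series.records, masks):
                hm = detect_hairs(m.mask, series.calibration, config.hairs,
                                  region_id=f"day{rec.day}")
                rows.append(
                    {
                        "region": hm.region_id,
                        "day": rec.day,
                        "n_hairs": hm.n_hairs,
                        "axis_mm": hm.axis_length_mm,
                        "density_per_mm": hm.density_per_mm,
                        "mean_len_mm": hm.mean_length_mm,
                    }
                )
            hair_table = pd.DataFrame(rows)
            hair_table.to_csv(out / "hairs.csv", **_CSV_KW)
            results["hairs"] = hair_table
            status[stage] = "completed"
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # -- lifespan ----------------------------------------------------------
    stage = "lifespan"
    if stage in skip:
        status[stage] = "skipped"
    else:
        try:
            ls = config.lifespan
            images = [rec.pixels for rec in series]
            offsets = (
                align_series(images, max_shift=ls.max_shift)
                if len(images) >= 2
                else [(0, 0)] * len(images)
            )
            # subjects: connected components of the final-frame mask
            final = masks[-1].mask
            labels, n = label(final, structure=np.ones((3, 3), dtype=bool))
            rois = {}
            for k in range(1, n + 1):
                comp = labels == k
                if comp.sum() < ls.roi_min_area:
                    continue
                roi = binary_dilation(
                    comp, structure=np.ones((3, 3), dtype=bool),
                    iterations=ls.roi_margin_px,
                )
                rois[f"root{k:03d}"] = ("lateral_root", roi)
            events = extract_events(
                [m.mask for m in masks], images, rois, series.days,
                calibration=series.calibration,
                offsets=offsets,
                min_area=ls.min_area,
                live_min_brightness=ls.live_min_brightness,
                tortuosity_threshold=ls.tortuosity_threshold,
            )
            ev_table = pd.DataFrame(
                [
                    {
                        "subject_id": e.subject_id,
                        "type": e.subject_type,
                        "emergence_day": e.emergence_day,
                        "end_day": e.end_day,
                        "censored": e.censored,
                    }
                    for e in events
                ],
                columns=["subject_id", "type", "emergence_day", "end_day", "censored"],
            )
            ev_table.to_csv(out / "events.csv", **_CSV_KW)
            results["events"] = events
            if events:
                curve = kaplan_meier(events)
                surv = pd.DataFrame(
                    {
                        "t": curve.times,
                        "n_at_risk": curve.at_risk,
                        "d": curve.deaths,
                        "S": curve.survival,
                    }
                )
                surv.to_csv(out / "survival.csv", **_CSV_KW)
                results["survival"] = curve
            status[stage] = "completed"
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    _write_manifest(manifest, config, status)
    results["status"] = status
    return results
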