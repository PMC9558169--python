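import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhizotrack.catalog import calibrate
from rhizotrack.segmentation import SubPixelRootSegmenter
from rhizotrack.synthetic import (
    RenderConfig,
    RootSystemParams,
    grow_root_system,
    render_frame,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic root system (seed 1)."""
    return grow_root_system(RootSystemParams(), seed=1)


@pytest.fixture(scope="session")
def default_render():
    return RenderConfig(seed=1)


@pytest.fixture(scope="session")
def frame_day10(default_truth, default_render):
    """(image, mask, hair_mask) of the default system at day 10."""
    return render_frame(default_truth, 10, default_render)


def _small_scene_pairs(seeds, days):
    """Frames/masks of reduced scenes (40 mm window) for fast model tests."""
    params = RootSystemParams(
        frame_width_mm=40.0, frame_height_mm=40.0, horizon_days=10,
        taproot_rate_mm_per_day=3.5, n_lateral1=5, n_lateral2=2,
    )
    frames, masks = [], []
    for seed in seeds:
        truth = grow_root_system(params, seed=seed)
        cfg = RenderConfig(seed=seed)
        for day in days:
            img, m, _ = render_frame(truth, day, cfg)
            frames.append(img)
            masks.append(m)
    return frames, masks


@pytest.fixture(scope="session")
def small_training_set():
    return _small_scene_pairs(seeds=(0, 1), days=(5, 7, 9))


@pytest.fixture(scope="session")
def small_test_set():
    return _small_scene_pairs(seeds=(5,), days=(6, 8, 10))


@pytest.fixture(scope="session")
def tiny_model(small_training_set):
    """A quickly trained segmenter for contract/monotonicity tests."""
    frames, masks = small_training_set
    return SubPixelRootSegmenter(
        epochs=4, patches_per_frame=4, random_state=0
    ).fit(frames, masks)


def hair_specimen_params():
    """A single thin root crossing a mm-scale window, densely haired."""
    return RootSystemParams(
        frame_width_mm=10.0, frame_height_mm=10.0, horizon_days=2,
        initial_length_mm=6.0, taproot_rate_mm_per_day=0.5,
        taproot_diameter_mm=0.15, tip_taper=0.9,
        n_lateral1=0, n_lateral2=0, hairs_per_mm=3.0,
        hair_lifespan_mean_days=None,
    )


@pytest.fixture(scope="session")
def hair_specimen():
    """(truth, combined mask, calibration) of a hair-grade specimen scan."""
    truth = grow_root_system(hair_specimen_params(), seed=5)
    cfg = RenderConfig(dpi=4800, seed=5)
    _, mask, hair_mask = render_frame(truth, 2, cfg)
    return truth, mask | hair_mask, calibrate(4800)
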