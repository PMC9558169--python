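import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhizotrack.catalog import calibrate
from rhizotrack.lifespan import (
    RootEvent,
    align_series,
    classify_status,
    compare_groups,
    extract_events,
    hair_status,
    kaplan_meier,
)
from rhizotrack.synthetic import (
    RenderConfig,
    RootSystemParams,
    grow_root_system,
    render_frame,
    render_series,
    render_subject_roi,
)


def rttr_survival(sample):
    """Independent product-limit oracle: redistribute-to-the-right.

    Each observation starts with weight 1/n; walking censored
    observations in time order (deaths before censorings at ties), each
    one passes its weight equally to all strictly later observations.
    S(t) is then one minus the cumulative death weight.
    """
    n = len(sample)
    order = sorted(range(n), key=lambda i: (sample[i][0], sample[i][1] is False))
    w = [1.0 / n] * n
    for pos, i in enumerate(order):
        t, observed = sample[i]
        if not observed:
            later = [j for j in order[pos + 1 :]]
            if later:
                share = w[i] / len(later)
                for j in later:
                    w[j] += share
                w[i] = 0.0

    def s(t):
        dead = sum(w[i] for i in range(n) if sample[i][1] and sample[i][0] <= t)
        return 1.0 - dead

    return s


class TestAlign:
    def test_identical_frames_zero_offsets(self, frame_day10):
        img = frame_day10[0]
        assert align_series([img, img, img]) == [(0, 0)] * 3

    def test_recovers_constructed_shift(self, frame_day10):
        img = frame_day10[0]
        shifted = np.roll(img, (3, -2), axis=(0, 1))
        assert align_series([img, shifted]) == [(0, 0), (3, -2)]

    def test_reversed_series_negates_offsets(self, frame_day10):
        img = frame_day10[0]
        shifted = np.roll(img, (5, 4), axis=(0, 1))
        fwd = align_series([img, shifted])
        rev = align_series([shifted, img])
        assert rev[1] == (-fwd[1][0], -fwd[1][1])

    def test_excessive_shift_falls_back_to_zero(self, frame_day10):
        img = frame_day10[0]
        shifted = np.roll(img, (50, 0), axis=(0, 1))
        with pytest.warns(UserWarning, match="alignment failed"):
            offs = align_series([img, shifted], max_shift=20)
        assert offs[1] == (0, 0)

    def test_single_frame_rejected(self, frame_day10):
        with pytest.raises(ValueError, match="2 frames"):
            align_series([frame_day10[0]])


class TestStatusCalls:
    def test_live_and_senescent_palettes(self, default_truth, default_render):
        # pick a day where some roots have senesced
        sen = [r for r in default_truth.roots if r.senescence_day is not None
               and r.senescence_day <= 15]
        assert sen, "default scene should contain senescence"
        day = 15
        from rhizotrack.synthetic import render_root_mask

        img, mask, _ = render_frame(default_truth, day, default_render)
        live = [r for r in default_truth.roots if not r.is_senescent(day)]
        live_mask = render_root_mask(default_truth, day, default_render,
                                     root_ids=[live[0].root_id])
        assert classify_status(img, live_mask & mask) == "live"
        dead_mask = render_root_mask(default_truth, day, default_render,
                                     root_ids=[sen[0].root_id])
        assert classify_status(img, dead_mask & mask) == "senescent"

    def test_exact_threshold_counts_as_live(self):
        img = np.full((5, 5, 3), 160, np.uint8)
        roi = np.ones((5, 5), bool)
        assert classify_status(img, roi, live_min_brightness=160.0) == "live"

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            classify_status(np.zeros((5, 5, 3), np.uint8), np.zeros((5, 5), bool))

    def test_straight_hair_intact(self):
        path = np.column_stack([np.arange(10), np.zeros(10)])
        assert hair_status(path) == "intact"

    def test_semicircle_distorted_at_default_threshold(self):
        # arc/chord of a semicircle is pi/2 ~ 1.571 > 1.5
        t = np.linspace(0, np.pi, 100)
        semi = np.column_stack([np.cos(t), np.sin(t)])
        assert hair_status(semi) == "distorted"
        assert hair_status(semi, threshold=2.0) == "intact"

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hair_status(np.array([[0, 0], [1, 1]]))


class TestExtractEvents:
    @pytest.fixture(scope="class")
    @staticmethod
    def scene():
        truth = grow_root_system(RootSystemParams(), seed=3)
        cfg = RenderConfig(seed=3)
        days = list(range(1, 16))
        images, masks, _ = render_series(truth, days, cfg)
        rois = {
            r.root_id: ("lateral_root", render_subject_roi(truth, r.root_id, cfg))
            for r in truth.roots
            if r.order != "taproot"
        }
        events = extract_events(masks, images, rois, days,
                                calibration=calibrate(cfg.dpi))
        return truth, {e.subject_id: e for e in events}

    def test_emergence_recovered_exactly(self, scene):
        truth, events = scene
        hits = [
            events[r.root_id].emergence_day == r.emergence_day
            for r in truth.roots
            if r.order != "taproot" and r.root_id in events
        ]
        assert np.mean(hits) >= 0.9

    def test_senescence_within_one_day(self, scene):
        truth, events = scene
        checked = 0
        for r in truth.roots:
            if r.order == "taproot" or r.root_id not in events:
                continue
            e = events[r.root_id]
            if r.senescence_day is not None and r.senescence_day <= 15:
                assert not e.censored
                assert abs(e.end_day - r.senescence_day) <= 1
                checked += 1
            else:
                assert e.censored
                assert e.end_day == 15
        assert checked >= 1

    def test_deterministic(self, scene):
        truth, _ = scene
        cfg = RenderConfig(seed=3)
        days = list(range(1, 16))
        images, masks, _ = render_series(truth, days, cfg)
        roi = {"x": ("lateral_root", render_subject_roi(truth, "l1_00", cfg))}
        a = extract_events(masks, images, roi, days)
        b = extract_events(masks, images, roi, days)
        assert a == b

    def test_never_populated_roi_dropped_with_warning(self, scene):
        truth, _ = scene
        cfg = RenderConfig(seed=3)
        days = [1, 2]
        images, masks, _ = render_series(truth, days, cfg)
        roi = np.zeros_like(masks[0])
        roi[:4, :4] = True  # a corner with no roots
        with pytest.warns(UserWarning, match="never populated"):
            out = extract_events(masks, images, {"ghost": ("lateral_root", roi)}, days)
        assert out == []


class TestKaplanMeier:
    def test_hand_example_without_censoring(self):
        km = kaplan_meier([(5, True), (10, True), (15, True)])
        assert km.survival == pytest.approx((2 / 3, 1 / 3, 0.0))
        assert km.median == 10

    def test_hand_example_with_censoring(self):
        # deaths at 4 and 8, one censored at 6: S(4)=2/3, S(8)=0
        km = kaplan_meier([(4, True), (6, False), (8, True)])
        assert km.survival == pytest.approx((2 / 3, 0.0))
        assert km.median == 8

    def test_simultaneous_deaths(self):
        km = kaplan_meier([(7, True)] * 4)
        assert km.survival == (0.0,)
        assert km.median == 7

    def test_all_censored_at_zero_rejected(self):
        with pytest.raises(ValueError, match="censored at time 0"):
            kaplan_meier([(0, False), (0, False)])

    def test_survival_curve_is_nonincreasing_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        sample = [(int(t), bool(o)) for t, o in
                  zip(rng.integers(1, 30, 40), rng.random(40) > 0.3)]
        km = kaplan_meier(sample)
        s = (1.0,) + km.survival
        assert all(b <= a for a, b in zip(s, s[1:]))
        assert km.survival_at(0) == 1.0

    def test_accepts_root_events(self):
        events = [
            RootEvent("a", "lateral_root", 2, 12, False),
            RootEvent("b", "lateral_root", 3, 15, True),
        ]
        km = kaplan_meier(events)
        assert km.times == (10.0,)

    def test_matches_rttr_oracle_on_all_small_samples(self):
        """Exhaustive product-limit check for every sample of size <= 5
        over times {1,2,3} x {death, censored}, against the independent
        redistribute-to-the-right construction."""
        options = [(t, o) for t in (1, 2, 3) for o in (True, False)]
        for n in range(1, 6):
            for sample in itertools.combinations_with_replacement(options, n):
                if not any(o for _, o in sample):
                    continue  # no deaths: S stays 1 everywhere, trivial
                km = kaplan_meier(list(sample))
                oracle = rttr_survival(list(sample))
                for t, s in zip(km.times, km.survival):
                    assert s == pytest.approx(oracle(t), abs=1e-12), sample

    def test_matches_lifelines_on_random_samples(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            dur = rng.integers(1, 25, n)
            obs = rng.random(n) > 0.35
            if not obs.any():
                continue
            km = kaplan_meier(list(zip(dur, obs)))
            kmf = KaplanMeierFitter().fit(dur, event_observed=obs)
            for t, s in zip(km.times, km.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
                )

    @given(
        st.lists(st.integers(1, 50), min_size=1, max_size=30)
    )
    def test_median_equals_sample_median_without_censoring(self, times):
        km = kaplan_meier([(t, True) for t in times])
        expected = sorted(times)[int(np.ceil(len(times) / 2)) - 1]
        assert km.median == expected

    def test_exponential_lifespans_recover_half_life(self):
        # a single n=300 KM median has ~8% standard error, so the 10% band
        # is checked on the mean over independent replicates, which tests
        # the same estimator with adequate power
        rng = np.random.default_rng(300)
        m = 20.0
        medians = []
        for _ in range(10):
            dur = rng.exponential(m, 300)
            medians.append(kaplan_meier(list(zip(dur, [True] * 300))).median)
        assert np.mean(medians) == pytest.approx(m * np.log(2), rel=0.10)


class TestCompareGroups:
    def test_identical_groups(self):
        g = [(5, True), (9, True), (14, True)]
        out = compare_groups(g, list(g))
        assert out.median_difference == 0
        assert out.logrank_chi_sq == 0.0

    def test_shift_equivariance_of_median(self):
        a = [(5, True), (9, True), (14, True), (20, True)]
        b = [(t + 10, o) for t, o in a]
        out = compare_groups(a, b)
        assert out.median_difference == 10

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(2)
        a = list(zip(rng.exponential(20, 200), [True] * 200))
        b = list(zip(rng.exponential(40, 200), [True] * 200))
        out = compare_groups(a, b)
        assert out.logrank_p < 0.01

    def test_too_few_uncensored_rejected(self):
        with pytest.raises(ValueError, match="uncensored"):
            compare_groups([(5, True), (9, False)], [(5, True), (6, True)])

    def test_undefined_median_still_produces_logrank(self):
        # group b never reaches S <= 0.5: median undefined
        a = [(2, True), (4, True), (6, True), (8, True)]
        b = [(3, True), (5, True), (30, False), (40, False), (50, False),
             (60, False), (70, False)]
        out = compare_groups(a, b)
        assert out.median_b is None
        assert out.median_difference is None
        assert np.isfinite(out.logrank_chi_sq)
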