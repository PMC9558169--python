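import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from rhizotrack.catalog import calibrate
from rhizotrack.segmentation import (
    RootMask,
    SubPixelRootSegmenter,
    compare_trait_agreement,
    evaluate,
    predict_mask,
    threshold_segment,
    train_model,
)


class TestEvaluate:
    def test_identical_nonempty_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:8] = True
        s = evaluate(m, m)
        assert (s.iou, s.dice, s.precision, s.recall) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert evaluate(a, b).iou == 0.0

    def test_half_overlapping_squares(self):
        # two 10x10 squares overlapping on a 5x10 strip: IoU = 50/150
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[:, 0:10] = True
        b[:, 5:15] = True
        s = evaluate(a, b)
        assert s.iou == pytest.approx(50 / 150)
        assert s.dice == pytest.approx(2 * s.iou / (1 + s.iou))

    def test_empty_vs_empty_is_perfect(self):
        z = np.zeros((5, 5), bool)
        s = evaluate(z, z)
        assert s.iou == s.dice == s.precision == s.recall == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    def test_symmetry_and_precision_recall_duality(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.random((20, 20)) > 0.6
            b = rng.random((20, 20)) > 0.6
            ab, ba = evaluate(a, b), evaluate(b, a)
            assert ab.iou == pytest.approx(ba.iou)
            assert ab.dice == pytest.approx(ba.dice)
            assert ab.precision == pytest.approx(ba.recall)


class TestThresholdSegment:
    def test_uniform_gray_gives_empty_mask(self):
        img = np.full((120, 120, 3), 128, np.uint8)
        assert threshold_segment(img).mask.sum() == 0

    def test_frame_without_roots_is_nearly_empty(self):
        from rhizotrack.synthetic import (
            RenderConfig, RootSystemParams, grow_root_system, render_frame,
        )

        p = RootSystemParams(n_lateral1=0, n_lateral2=0)
        truth = grow_root_system(p, seed=3)
        truth.roots[0].emergence_day = 10  # nothing emerged yet at day 2
        img, mask, _ = render_frame(truth, 2, RenderConfig(seed=3))
        assert mask.sum() == 0
        assert threshold_segment(img).density < 0.01

    def test_deterministic(self, frame_day10):
        img = frame_day10[0]
        a = threshold_segment(img).mask
        b = threshold_segment(img).mask
        np.testing.assert_array_equal(a, b)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_segment(np.zeros((0, 0, 3), np.uint8))

    def test_provenance(self, frame_day10):
        assert threshold_segment(frame_day10[0]).provenance == "classical"


class TestSegmenterTraining:
    def test_loss_decreases_over_epochs(self, tiny_model):
        hist = tiny_model.loss_history_
        assert len(hist) == 4
        assert hist[-1] < hist[0]
        assert np.isfinite(hist).all()

    def test_training_is_deterministic(self, small_training_set):
        frames, masks = small_training_set
        kw = dict(epochs=2, patches_per_frame=2, random_state=7)
        a = SubPixelRootSegmenter(**kw).fit(frames[:3], masks[:3])
        b = SubPixelRootSegmenter(**kw).fit(frames[:3], masks[:3])
        assert a.loss_history_ == b.loss_history_

    def test_all_background_labels_yield_empty_predictions(self, small_training_set):
        frames, masks = small_training_set
        zeros = [np.zeros_like(m) for m in masks[:3]]
        model = SubPixelRootSegmenter(
            epochs=3, patches_per_frame=3, random_state=0
        ).fit(frames[:3], zeros)
        assert model.predict(frames[0]).density < 0.01

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SubPixelRootSegmenter().fit([], [])

    def test_shape_mismatch_rejected(self, small_training_set):
        frames, masks = small_training_set
        bad = np.zeros((10, 10), bool)
        with pytest.raises(ValueError, match="mismatch"):
            SubPixelRootSegmenter().fit([frames[0]], [bad])

    def test_invalid_aspp_rates_rejected(self, small_training_set):
        frames, masks = small_training_set
        with pytest.raises(ValueError, match="aspp"):
            SubPixelRootSegmenter(aspp_rates=(1, 2)).fit(frames[:1], masks[:1])
        with pytest.raises(ValueError, match="aspp"):
            SubPixelRootSegmenter(aspp_rates=(2, 2, 4)).fit(frames[:1], masks[:1])

    def test_sklearn_params_roundtrip(self):
        model = SubPixelRootSegmenter(lr=1e-3)
        params = model.get_params()
        assert params["lr"] == 1e-3
        model.set_params(epochs=3)
        assert model.epochs == 3


class TestSegmenterInference:
    def test_untrained_model_rejected(self, frame_day10):
        with pytest.raises(NotFittedError):
            SubPixelRootSegmenter().predict(frame_day10[0])

    def test_output_shape_matches_input(self, tiny_model, small_test_set):
        img = small_test_set[0][0]
        p = tiny_model.predict_proba(img)
        assert p.shape == img.shape[:2]

    def test_density_monotone_in_threshold(self, tiny_model, small_test_set):
        img = small_test_set[0][0]
        dens = [tiny_model.predict(img, threshold=t).density
                for t in (0.0, 0.3, 0.5, 0.8)]
        assert all(b <= a for a, b in zip(dens, dens[1:]))

    def test_threshold_zero_sets_everything_with_positive_probability(
        self, tiny_model, small_test_set
    ):
        img = small_test_set[0][0]
        p = tiny_model.predict_proba(img)
        m = tiny_model.predict(img, threshold=0.0)
        np.testing.assert_array_equal(m.mask, p > 0)

    def test_prediction_deterministic(self, tiny_model, small_test_set):
        img = small_test_set[0][0]
        np.testing.assert_array_equal(
            tiny_model.predict(img).mask, tiny_model.predict(img).mask
        )

    def test_provenance_is_model(self, tiny_model, small_test_set):
        assert tiny_model.predict(small_test_set[0][0]).provenance == "model"

    def test_tiling_agrees_with_whole_frame_on_overlap_seams(
        self, tiny_model, small_test_set
    ):
        # a frame larger than the patch is stitched from tiles; probabilities
        # must remain in [0, 1] and produce a reasonable mask
        img, mask = small_test_set[0][0], small_test_set[0][1]
        p = tiny_model.predict_proba(img)
        assert 0.0 <= p.min() and p.max() <= 1.0

    def test_checkpoint_roundtrip(self, tiny_model, small_test_set, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        back = SubPixelRootSegmenter.load(path)
        img = small_test_set[0][0]
        np.testing.assert_allclose(
            back.predict_proba(img), tiny_model.predict_proba(img)
        )

    def test_wrapper_functions(self, small_training_set):
        frames, masks = small_training_set
        model = train_model(
            frames[:2], masks[:2],
            {"epochs": 1, "patches_per_frame": 2, "random_state": 0},
        )
        out = predict_mask(model, frames[0])
        assert isinstance(out, RootMask)


class TestTraitAgreement:
    def test_identical_masks_give_unit_r2(self, small_test_set):
        masks = small_test_set[1]
        r2 = compare_trait_agreement(masks, masks, calibrate(150))
        assert all(v == 1.0 for v in r2.values())

    def test_perturbation_lowers_r2(self, small_test_set):
        masks = list(small_test_set[1])
        perturbed = [m.copy() for m in masks]
        perturbed[0][:, ::3] = False  # chop one frame's roots
        r2 = compare_trait_agreement(perturbed, masks, calibrate(150))
        assert r2["RL"] < 1.0

    def test_fewer_than_three_pairs_rejected(self, small_test_set):
        masks = small_test_set[1]
        with pytest.raises(ValueError, match=">= 3"):
            compare_trait_agreement(masks[:2], masks[:2], calibrate(150))
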