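"""Perturbation metrics: masking primitives, curve endpoint contracts, a
hand-enumerated AUC oracle, the AD/IC/ADA definitions, macro aggregation
against published per-emotion values, and the full suite's invariants."""

import numpy as np
import pytest

import fedfer as ff
from fedfer.config import MaskSpec
from fedfer.metrics import METRIC_NAMES

from _tables import (
    XAI_MACRO_3LAYER,
    XAI_MACRO_4LAYER,
    XAI_PER_CLASS_3LAYER,
    XAI_PER_CLASS_4LAYER,
)


class MeanIntensityModel:
    """Duck-typed stand-in model: P(class 0) = mean pixel intensity."""

    def predict_proba(self, batch):
        m = np.asarray(batch).mean(axis=(1, 2, 3))
        rest = (1.0 - m) / 3.0
        return np.stack([m, rest, rest, rest], axis=1)

    def predict(self, batch):
        return self.predict_proba(batch).argmax(axis=1)


class TestMaskingPrimitives:
    def test_binarize_zero_map_is_empty(self):
        assert not ff.binarize(np.zeros((48, 48)), 0.5).any()

    def test_binarize_tie_is_salient(self):
        values = np.array([[0.5, 0.499], [0.501, 0.0]])
        mask = ff.binarize(values, 0.5)
        assert mask.tolist() == [[True, False], [True, False]]

    def test_binarize_counts_pixels_at_or_above_threshold(self, rng):
        values = rng.random((48, 48))
        assert ff.binarize(values, 0.3).sum() == (values >= 0.3).sum()

    def test_active_pixel_ratio_extremes(self):
        assert ff.active_pixel_ratio(np.ones((48, 48), bool)) == 1.0
        assert ff.active_pixel_ratio(np.zeros((48, 48), bool)) == 0.0

    def test_empty_mask_occlude_identity_retain_constant(self, rng):
        img = rng.random((48, 48))
        empty = np.zeros((48, 48), bool)
        np.testing.assert_array_equal(ff.occlude_salient(img, empty, 0.0), img)
        assert (ff.retain_salient(img, empty, 0.0) == 0.0).all()

    def test_full_mask_occlude_is_constant_fill(self, rng):
        img = rng.random((48, 48))
        full = np.ones((48, 48), bool)
        assert (ff.occlude_salient(img, full, 0.0) == 0.0).all()

    def test_occlude_plus_retain_reconstructs_image(self, rng):
        img = rng.random((48, 48))
        mask = rng.random((48, 48)) > 0.5
        recon = ff.occlude_salient(img, mask, 0.0) + ff.retain_salient(img, mask, 0.0)
        np.testing.assert_allclose(recon, img)

    def test_inputs_are_not_modified(self, rng):
        img = rng.random((48, 48))
        before = img.copy()
        ff.occlude_salient(img, np.ones((48, 48), bool), 0.0)
        ff.retain_salient(img, np.zeros((48, 48), bool), 0.0)
        np.testing.assert_array_equal(img, before)


class TestCurves:
    def test_deletion_endpoints(self, tiny_arch, rng):
        model = ff.build_network(tiny_arch, seed=1)
        img = rng.random((48, 48)).astype(np.float32)
        saliency = rng.random((48, 48))
        curve = ff.deletion_curve(model, img, saliency, target_class=1, n_steps=10)
        p0 = model.predict_proba(img[None, ..., None])[0, 1]
        p1 = model.predict_proba(np.zeros((1, 48, 48, 1), np.float32))[0, 1]
        assert curve.confidences[0] == pytest.approx(p0, abs=1e-6)
        assert curve.confidences[-1] == pytest.approx(p1, abs=1e-6)

    def test_insertion_endpoint_is_original_confidence(self, tiny_arch, rng):
        model = ff.build_network(tiny_arch, seed=1)
        img = rng.random((48, 48)).astype(np.float32)
        saliency = rng.random((48, 48))
        curve = ff.insertion_curve(model, img, saliency, target_class=2, n_steps=10)
        p_full = model.predict_proba(img[None, ..., None])[0, 2]
        assert curve.confidences[-1] == pytest.approx(p_full, abs=1e-6)

    def test_constant_prediction_model_gives_flat_curves(self, tiny_arch, rng):
        model = ff.build_network(tiny_arch, seed=1)
        weights = model.get_weights()
        weights["output/W"][...] = 0.0
        weights["output/b"][...] = 0.0
        model.set_weights(weights)
        img = rng.random((48, 48)).astype(np.float32)
        saliency = rng.random((48, 48))
        dauc = ff.deletion_curve(model, img, saliency, 0, n_steps=8).auc
        iauc = ff.insertion_curve(model, img, saliency, 0, n_steps=8).auc
        assert dauc == pytest.approx(0.25, abs=1e-6)
        assert iauc == pytest.approx(0.25, abs=1e-6)

    def test_hand_enumerated_two_by_two_deletion(self):
        """Enumerate the 5 deletion steps of a 2x2 image under the
        mean-intensity model and compare the trapezoid AUC."""
        model = MeanIntensityModel()
        img = np.array([[0.8, 0.4], [0.6, 0.2]], dtype=np.float32)
        saliency = np.array([[0.9, 0.3], [0.7, 0.1]])  # rank: 0.8, 0.6, 0.4, 0.2
        curve = ff.deletion_curve(model, img, saliency, target_class=0, n_steps=4)
        # fractions 0, .25, .5, .75, 1 remove the top 0,1,2,3,4 ranked pixels
        means = [
            (0.8 + 0.4 + 0.6 + 0.2) / 4,
            (0.0 + 0.4 + 0.6 + 0.2) / 4,
            (0.0 + 0.4 + 0.0 + 0.2) / 4,
            (0.0 + 0.0 + 0.0 + 0.2) / 4,
            0.0,
        ]
        np.testing.assert_allclose(curve.confidences, means, atol=1e-7)
        expected_auc = np.trapezoid(means, np.linspace(0, 1, 5))
        assert curve.auc == pytest.approx(expected_auc, abs=1e-7)

    def test_saliency_ties_break_row_major(self):
        model = MeanIntensityModel()
        img = np.array([[1.0, 1.0], [1.0, 1.0]], dtype=np.float32)
        saliency = np.full((2, 2), 0.5)
        curve = ff.deletion_curve(model, img, saliency, 0, n_steps=4)
        # all-tied saliency removes pixels in row-major order
        np.testing.assert_allclose(curve.confidences, [1, 0.75, 0.5, 0.25, 0.0])

    def test_unnormalized_map_rejected(self, tiny_arch, rng):
        model = ff.build_network(tiny_arch, seed=1)
        with pytest.raises(ValueError, match="normalized"):
            ff.deletion_curve(model, rng.random((48, 48)), rng.random((48, 48)) * 3)


class TestScalarMetrics:
    def test_average_drop_simple_case(self):
        assert ff.average_drop([(1.0, 0.5)]) == pytest.approx(0.5)

    def test_average_drop_clamps_increases_to_zero(self):
        assert ff.average_drop([(0.4, 0.9), (0.8, 0.8)]) == 0.0

    def test_average_drop_excludes_zero_confidence(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            value = ff.average_drop([(0.0, 0.1), (1.0, 0.5)])
        assert value == pytest.approx(0.5)
        assert "excluded" in caplog.text

    def test_increase_in_confidence_fraction(self):
        pairs = [(0.5, 0.6), (0.5, 0.4), (0.9, 1.0), (0.7, 0.1)]
        assert ff.increase_in_confidence(pairs) == pytest.approx(0.5)

    def test_increase_in_confidence_is_strict(self):
        assert ff.increase_in_confidence([(0.5, 0.5), (0.2, 0.2)]) == 0.0

    def test_ada_complements_masked_accuracy_on_correct_subset(self):
        labels = np.array([0, 1, 2, 3] * 250)
        preds_orig = labels.copy()  # correctly-classified subset
        rng = np.random.default_rng(1)
        preds_occ = np.where(rng.random(1000) < 0.287, labels,
                             (labels + 1) % 4)
        ada, masked = ff.ada_and_masked_accuracy(labels, preds_orig, preds_occ)
        assert ada == pytest.approx(1.0 - masked, abs=1e-12)

    def test_ada_zero_when_accuracy_unchanged(self):
        labels = np.array([0, 1, 2, 3])
        preds = np.array([0, 1, 2, 0])
        ada, masked = ff.ada_and_masked_accuracy(labels, preds, preds)
        assert ada == 0.0
        assert masked == pytest.approx(0.75)


class TestMacroAggregation:
    def test_three_layer_macro_reproduces_published_row(self):
        macro = ff.macro_aggregate(XAI_PER_CLASS_3LAYER)
        for key, expected in XAI_MACRO_3LAYER.items():
            assert round(macro[key], 3) == pytest.approx(expected, abs=1e-12), key

    def test_four_layer_macro_reproduces_published_row(self):
        # the published IC cell is 0.001 below the exact class mean (rounding
        # of the per-class inputs); everything else reproduces exactly
        macro = ff.macro_aggregate(XAI_PER_CLASS_4LAYER)
        for key, expected in XAI_MACRO_4LAYER.items():
            assert abs(round(macro[key], 3) - expected) <= 0.001 + 1e-9, key

    def test_published_ada_masking_pairs_sum_to_one(self):
        for table in (XAI_PER_CLASS_3LAYER, XAI_PER_CLASS_4LAYER):
            for row in table.values():
                assert row["ada"] + row["accuracy_after_masking"] == pytest.approx(
                    1.0, abs=1e-9)


@pytest.fixture(scope="module")
def suite_report(trained_model, synthetic_split):
    _, test = synthetic_split
    subset = test.subset(np.arange(0, len(test), 5))  # 80 samples
    return ff.evaluate_suite([trained_model], subset, n_steps=20)[0]


class TestEvaluateSuite:
    def test_all_metrics_in_unit_interval(self, suite_report):
        for cls, row in suite_report.per_class.items():
            for name in METRIC_NAMES:
                assert 0.0 <= row[name] <= 1.0, (cls, name)

    def test_macro_equals_class_mean(self, suite_report):
        for name in METRIC_NAMES:
            manual = np.mean([row[name] for row in suite_report.per_class.values()])
            assert suite_report.macro[name] == pytest.approx(manual, abs=1e-12)

    def test_ada_identity_on_the_all_correct_subset(self, suite_report):
        # the evaluation subset is correctly classified, so per class
        # ADA + accuracy-after-masking = 1 exactly
        for row in suite_report.per_class.values():
            assert row["ada"] + row["accuracy_after_masking"] == pytest.approx(
                1.0, abs=1e-12)

    def test_perfect_model_keeps_full_test_set(self, trained_model, synthetic_split):
        _, test = synthetic_split
        subset = test.subset(np.arange(40))
        correct = trained_model.predict(subset.images) == subset.labels
        reports = ff.evaluate_suite([trained_model], subset, n_steps=5)
        assert sum(reports[0].n_samples.values()) == int(correct.sum())

    def test_empty_subset_raises_helpful_error(self, tiny_arch, synthetic_split):
        _, test = synthetic_split
        model = ff.build_network(tiny_arch, seed=1)  # untrained
        subset = test.subset(np.arange(8))
        preds = model.predict(subset.images)
        if (preds == subset.labels).any():  # force an all-wrong subset
            subset = subset.subset(np.flatnonzero(preds != subset.labels))
        with pytest.raises(ValueError, match="correctly classified"):
            ff.evaluate_suite([model], subset, n_steps=5)
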