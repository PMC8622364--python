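"""Max-aggregation WSI prediction, heatmaps, and evaluation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histomine.errors import UndefinedMetricError
from histomine.inference import (SlidePrediction, bootstrap_ci,
                                 confusion_at_threshold, log_loss,
                                 predict_wsi, render_heatmap, roc_auc,
                                 specificity_at_full_sensitivity)
from histomine.model import BackboneConfig, build_model
from histomine.slide_io import Slide, SlideRef, TissueMask
from histomine.tiling import TileSpec


def pairwise_auc(labels, scores):
    """Exhaustive pair-counting oracle: concordant + half-credit ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12))
    def test_matches_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid -> ties occur
        assert roc_auc(labels, scores) == pytest.approx(
            pairwise_auc(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        scores = rng.random(30)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, np.exp(3 * scores)), abs=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(4)
        labels = np.array([0, 1] * 10)
        scores = rng.permutation(20) / 20.0  # all distinct
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.5, 0.6])


class TestLogLoss:
    def test_worked_examples(self):
        assert log_loss([1, 0], [0.8, 0.2]) == pytest.approx(-np.log(0.8), abs=1e-5)
        assert log_loss([1, 0], [0.8, 0.2]) == pytest.approx(0.22314, abs=1e-5)
        assert log_loss([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(np.log(2))

    def test_perfect_predictions_clipped(self):
        assert log_loss([1, 0], [1.0, 0.0]) < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            log_loss([], [])


class TestConfusion:
    def test_worked_example(self):
        c = confusion_at_threshold([1, 0], [0.9, 0.1], 0.5)
        assert c == {"tn": 1, "fp": 0, "fn": 0, "tp": 1}

    def test_zero_threshold_all_positive(self):
        c = confusion_at_threshold([1, 0, 0], [0.2, 0.0, 0.9], 0.0)
        assert c["tp"] + c["fp"] == 3

    def test_threshold_comparison_is_geq(self):
        c = confusion_at_threshold([1], [0.5], 0.5)
        assert c["tp"] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        labels, scores = rng.integers(0, 2, 50), rng.random(50)
        c = confusion_at_threshold(labels, scores, 0.3)
        assert sum(c.values()) == 50


class TestSpecificityAtFullSensitivity:
    def test_worked_six_element_example(self):
        thr, spec = specificity_at_full_sensitivity(
            [1, 1, 0, 0, 0, 0], [0.7, 0.4, 0.6, 0.3, 0.2, 0.1])
        assert thr == pytest.approx(0.4)
        assert spec == pytest.approx(0.75)

    def test_perfect_separation_gives_one(self):
        _, spec = specificity_at_full_sensitivity([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert spec == 1.0

    def test_inverted_scores_give_zero(self):
        _, spec = specificity_at_full_sensitivity([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert spec == 0.0


class TestBootstrap:
    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(1)
        labels, scores = rng.integers(0, 2, 60), rng.random(60)
        labels[:2] = [0, 1]
        a = bootstrap_ci("auc", labels, scores, 200, seed=5)
        assert a == bootstrap_ci("auc", labels, scores, 200, seed=5)

    def test_degenerate_constant_scores_zero_width(self):
        labels = np.array([1] * 5 + [0] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        lo, hi = bootstrap_ci("auc", labels, scores, 100, seed=0)
        assert lo == hi == 1.0

    def test_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n = 60
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.clip(rng.normal(0.4 + 0.3 * labels, 0.2), 0, 1)
            for metric, fn in (("auc", roc_auc), ("log_loss", log_loss)):
                lo, hi = bootstrap_ci(metric, labels, scores, 300, seed=trial)
                assert lo - 1e-12 <= fn(labels, scores) <= hi + 1e-12

    def test_separable_n200_high_lower_bound(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 100 + [0] * 100)
        scores = np.concatenate([rng.uniform(0.7, 1.0, 100),
                                 rng.uniform(0.0, 0.3, 100)])
        lo, _ = bootstrap_ci("auc", labels, scores, 1000, seed=0)
        assert lo >= 0.95

    def test_iteration_count_stability(self):
        rng = np.random.default_rng(11)
        labels = np.array([1] * 100 + [0] * 100)
        scores = np.clip(rng.normal(0.35 + 0.3 * labels, 0.15), 0, 1)
        a = bootstrap_ci("auc", labels, scores, 100, seed=1)
        b = bootstrap_ci("auc", labels, scores, 1000, seed=1)
        assert abs(a[0] - b[0]) < 0.02 and abs(a[1] - b[1]) < 0.02


def uniform_slide(value=120, size=512):
    px = np.full((size, size, 3), value, dtype=np.uint8)
    return Slide(SlideRef("u", "mem", size, size), px)


def full_mask(size=512, factor=32):
    n = size // factor
    return TissueMask(np.ones((n, n), dtype=bool), factor, 200)


@pytest.fixture(scope="module")
def model():
    return build_model(BackboneConfig(architecture="tiny_cnn", input_size=32))


class TestPredictWsi:
    def test_wsi_score_is_max_of_tiles(self, model):
        pred = predict_wsi(model, uniform_slide(), 128, 64, full_mask())
        probs = [p for _, p in pred.tile_scores]
        assert pred.wsi_score == pytest.approx(max(probs))

    def test_no_tissue_flagged_undefined(self, model):
        mask = TissueMask(np.zeros((16, 16), dtype=bool), 32, 200)
        with pytest.warns(UserWarning):
            pred = predict_wsi(model, uniform_slide(), 128, 64, mask)
        assert pred.undefined
        assert np.isnan(pred.wsi_score)

    def test_score_invariant_to_added_low_tile(self):
        scores = [(TileSpec("s", 0, 0, 128), 0.1), (TileSpec("s", 64, 0, 128), 0.7),
                  (TileSpec("s", 128, 0, 128), 0.3)]
        assert max(p for _, p in scores) == 0.7
        scores.append((TileSpec("s", 192, 0, 128), 0.2))
        assert max(p for _, p in scores) == 0.7


class TestHeatmap:
    def _pred(self, scores):
        return SlidePrediction("s", scores, max(p for _, p in scores))

    def test_uniform_zero_is_cold(self):
        import matplotlib

        scores = [(TileSpec("s", x, y, 64), 0.0)
                  for x in (0, 64) for y in (0, 64)]
        img = render_heatmap(self._pred(scores), 32)
        cold = (np.array(matplotlib.colormaps["inferno"](0.0)[:3]) * 255).astype(np.uint8)
        assert (img == cold).all()

    def test_single_hot_tile_rectangle(self):
        import matplotlib

        scores = [(TileSpec("s", 0, 0, 64), 0.0), (TileSpec("s", 128, 128, 64), 1.0)]
        img = render_heatmap(self._pred(scores), 64,
                             slide_width=256, slide_height=256)
        cmap = matplotlib.colormaps["inferno"]
        hot = (np.array(cmap(1.0)[:3]) * 255).astype(np.uint8)
        cold = (np.array(cmap(0.0)[:3]) * 255).astype(np.uint8)
        assert np.array_equal(img[2, 2], hot)  # the tile's mapped cell
        assert np.array_equal(img[0, 0], cold)
        assert np.array_equal(img[1, 2], cold)

    def test_overlap_takes_max(self):
        import matplotlib

        scores = [(TileSpec("s", 0, 0, 128), 0.2), (TileSpec("s", 64, 0, 128), 0.9)]
        img = render_heatmap(self._pred(scores), 64,
                             slide_width=192, slide_height=128)
        hot = (np.array(matplotlib.colormaps["inferno"](0.9)[:3]) * 255).astype(np.uint8)
        # overlapped column [64,128) renders at 0.9
        assert np.array_equal(img[0, 1], hot)
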