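"""Learning-rate schedule, hard mining, early stopping, the fit loop."""

import numpy as np
import pytest

from histomine.errors import SamplingError
from histomine.model import BackboneConfig, build_model
from histomine.tiling import LabeledSlide, TileSpec, balanced_slide_queue
from histomine.slide_io import SlideRef
from histomine.training import (EarlyStopTracker, TrainingConfig,
                                hard_mine_select, hard_mining_round, lr_at_epoch)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.001), (1, 0.001), (4, 0.001 * 0.95 ** 2),
    ])
    def test_stepped_decay(self, epoch, expected):
        assert lr_at_epoch(0.001, 0.95, 2, epoch) == pytest.approx(expected)

    def test_decay_one_is_constant(self):
        assert all(lr_at_epoch(0.001, 1.0, 2, e) == 0.001 for e in range(20))


def specs(n):
    return [TileSpec("s", i * 64, 0, 64) for i in range(n)]


class TestHardMineSelect:
    def test_negative_slide_takes_highest(self):
        scored = list(zip(specs(4), [0.9, 0.1, 0.8, 0.5]))
        picked = hard_mine_select(scored, wsi_label=0, k=2)
        assert [t.x for t in picked] == [0, 2 * 64]

    def test_positive_slide_takes_lowest(self):
        scored = list(zip(specs(4), [0.9, 0.1, 0.8, 0.5]))
        picked = hard_mine_select(scored, wsi_label=1, k=2)
        assert [t.x for t in picked] == [1 * 64, 3 * 64]

    def test_fewer_than_k_returns_all(self):
        scored = list(zip(specs(3), [0.2, 0.4, 0.6]))
        assert len(hard_mine_select(scored, 0, k=16)) == 3

    def test_ties_resolve_to_grid_order(self):
        scored = list(zip(specs(5), [0.5, 0.5, 0.9, 0.5, 0.5]))
        picked = hard_mine_select(scored, 0, k=3)
        assert [t.x for t in picked] == [2 * 64, 0, 1 * 64]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            probs = np.round(rng.random(n), 2)  # rounded -> frequent ties
            k = int(rng.integers(1, 20))
            label = int(rng.integers(0, 2))
            scored = list(zip(specs(n), probs))
            picked = hard_mine_select(scored, label, k)
            key = (lambda i: (-probs[i], i)) if label == 0 else \
                (lambda i: (probs[i], i))
            oracle = sorted(range(n), key=key)[:k]
            assert [t.x for t in picked] == [i * 64 for i in oracle]

    def test_empty_scores_raise(self):
        with pytest.raises(SamplingError):
            hard_mine_select([], 0, 4)


class TestEarlyStopTracker:
    def test_stopping_rule_trace(self):
        """Losses 0.50, 0.40 then flat with patience 10: 12 epochs, best = 1."""
        losses = [0.50, 0.40] + [0.41 + 0.01 * i for i in range(30)]
        tracker = EarlyStopTracker(switch_patience=2, stop_patience=10)
        epochs_run = 0
        for epoch, loss in enumerate(losses):
            epochs_run += 1
            _, stop = tracker.update(epoch, loss)
            if stop:
                break
        assert epochs_run == 12
        assert tracker.best_epoch == 1

    def test_phase_switch_after_two_stale_epochs(self):
        tracker = EarlyStopTracker(switch_patience=2, stop_patience=10)
        tracker.update(0, 0.5)
        assert tracker.phase == "random"
        tracker.update(1, 0.6)
        assert tracker.phase == "random"
        tracker.update(2, 0.6)
        assert tracker.phase == "hard_mining"

    def test_improvement_tolerance_is_strict(self):
        tracker = EarlyStopTracker(2, 10)
        assert tracker.update(0, 0.5)[0]
        assert not tracker.update(1, 0.5 - 1e-9)[0]


class FakeStore:
    """Duck-typed SlideStore: fixed candidate tiles, noise pixels."""

    def __init__(self, n_candidates=30, tile=32):
        self.n, self.tile = n_candidates, tile
        self._rng = np.random.default_rng(0)

    def candidates(self, slide):
        return [TileSpec(slide.slide_id, i * self.tile, 0, self.tile)
                for i in range(self.n)]

    def extract(self, tiles, slides_by_id):
        return (self._rng.random((len(tiles), self.tile, self.tile, 3))
                * 255).astype(np.uint8)


def fake_slides(n_pos, n_neg):
    return ([LabeledSlide(SlideRef(f"p{i}", "mem", 4096, 4096), 1, "train")
             for i in range(n_pos)]
            + [LabeledSlide(SlideRef(f"n{i}", "mem", 4096, 4096), 0, "train")
               for i in range(n_neg)])


class TestHardMiningRound:
    def _run(self, k, N, n_candidates=30):
        cfg = TrainingConfig(k=k, N=N, tile_size=32, train_stride=32)
        slides = fake_slides(4, 4)
        queue = balanced_slide_queue(slides, 0)
        model = build_model(BackboneConfig(architecture="tiny_cnn"))
        store = FakeStore(n_candidates=n_candidates)
        return hard_mining_round(model, queue, store, cfg,
                                 {s.slide_id: s for s in slides})

    def test_subset_filled_in_expected_visits(self):
        subset = self._run(k=16, N=256)
        assert len(subset.tiles) == 256
        assert subset.slides_visited == 16  # ceil(256/16)

    def test_k_equals_n_single_visit(self):
        subset = self._run(k=64, N=64, n_candidates=100)
        assert subset.slides_visited == 1

    def test_label_balance_within_k_of_half(self):
        subset = self._run(k=16, N=256)
        n_pos = int(subset.labels.sum())
        assert abs(n_pos - 128) <= 16


@pytest.fixture(scope="module")
def micro_fit(micro_dataset):
    from histomine.tiling import load_labeled_slides
    from histomine.training import SlideStore, fit

    slides = load_labeled_slides(micro_dataset)
    train = [s for s in slides if s.split == "train"]
    val = [s for s in slides if s.split == "val"]
    cfg = TrainingConfig(tile_size=128, train_stride=64, k=8, N=64,
                         switch_patience=1, stop_patience=2, max_epochs=8,
                         seed=11)
    bc = BackboneConfig(architecture="tiny_cnn", input_size=32)
    store = SlideStore(cfg)
    model, hist = fit(train, val, cfg, bc, store=store)
    return model, hist, (train, val, cfg, bc)


class TestFit:
    def test_history_best_epoch_has_minimal_val_loss(self, micro_fit):
        _, hist, _ = micro_fit
        losses = [r["val_loss"] for r in hist.rows]
        assert hist.best_val_loss == pytest.approx(min(losses))
        assert losses[hist.best_epoch] == pytest.approx(min(losses))

    def test_validation_loss_improves_over_initial(self, micro_fit):
        _, hist, _ = micro_fit
        assert hist.best_val_loss < hist.rows[0]["val_loss"]

    def test_learning_rate_follows_schedule(self, micro_fit):
        _, hist, _ = micro_fit
        for r in hist.rows:
            assert r["lr"] == pytest.approx(lr_at_epoch(0.001, 0.95, 2, r["epoch"]))

    def test_same_seed_reproduces_history(self, micro_fit):
        from histomine.training import SlideStore, fit

        _, hist, (train, val, cfg, bc) = micro_fit
        model2, hist2 = fit(train, val, cfg, bc, store=SlideStore(cfg))
        assert hist2.rows == hist.rows

    def test_missing_label_in_split_rejected(self, micro_fit):
        from histomine.errors import ConfigurationError
        from histomine.training import fit

        _, _, (train, val, cfg, bc) = micro_fit
        only_pos = [s for s in train if s.wsi_label == 1]
        with pytest.raises(ConfigurationError):
            fit(only_pos, val, cfg, bc)


class TestTrainingConfig:
    def test_invariants_enforced(self):
        with pytest.raises(Exception):
            TrainingConfig(k=300, N=256)
        with pytest.raises(Exception):
            TrainingConfig(batch_size=33)

    def test_tiles_per_slide_from_batch_and_labels(self):
        assert TrainingConfig().tiles_per_slide == 16  # 32 / 2
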