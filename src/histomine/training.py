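"""Two-phase weakly-supervised training: balanced sampling, then hard mining.

Phase 1 draws random balanced batches — one positive and one negative
slide per batch from an alternating shuffled queue, batch_size /
num_labels tiles from each — and minimises tile-level binary
cross-entropy with Adam under a stepped learning-rate decay.  Once the
validation loss stalls for `switch_patience` epochs, training switches
to phase 2: alternate between scoring slides with a sliding window and
training on the k hardest tiles per slide (highest-probability tiles of
negative slides, lowest of positive slides) collected into subsets of N.
Training stops after `stop_patience` epochs without validation
improvement; the weights at the best validation epoch are kept.

Tiles inherit their parent slide's label.  Annotated (positive) slides
are sampled and mined only inside their annotation polygons, so tissue
outside the marked tumour regions never enters training with a positive
label; unannotated slides use their whole tissue area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from ._nn import bce_loss_and_grad
from .errors import ConfigurationError, SamplingError
from .model import BackboneConfig, Model, build_model, make_optimizer
from .slide_io import Slide, TissueMask, tissue_mask
from .tiling import (DEFAULT_MIN_TISSUE_FRACTION, LabeledSlide, TileSpec,
                     annotation_candidates, balanced_slide_queue,
                     sample_tiles_from_slide, tile_grid, tissue_tiles)

logger = logging.getLogger("histomine.training")

#: "No improvement" means the loss fails to beat the running minimum by this.
IMPROVEMENT_TOL = 1e-6


@dataclass
class TrainingConfig:
    """All training hyperparameters; defaults are the full-scale settings."""

    k: int = 16                 # hard tiles kept per mined slide
    N: int = 256                # hard-mining subset size
    batch_size: int = 32
    num_labels: int = 2
    tile_size: int = 512
    train_stride: int = 256     # sliding-window stride during mining
    lr0: float = 0.001
    lr_decay: float = 0.95
    decay_every: int = 2
    beta1: float = 0.9
    beta2: float = 0.999
    switch_patience: int = 2    # stale epochs before switching to hard mining
    stop_patience: int = 10     # stale epochs before early stop
    seed: int = 0
    max_epochs: int = 200
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION
    mask_downsample: int = 32
    val_tiles_per_slide: int = 64

    def __post_init__(self):
        if self.k > self.N:
            raise ConfigurationError(f"k={self.k} must be <= N={self.N}")
        if self.batch_size % self.num_labels:
            raise ConfigurationError("batch_size must be divisible by num_labels")
        for name in ("k", "N", "batch_size", "num_labels", "tile_size",
                     "train_stride", "decay_every", "switch_patience",
                     "stop_patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def tiles_per_slide(self) -> int:
        return self.batch_size // self.num_labels


@dataclass
class TrainingHistory:
    rows: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def record(self, epoch: int, phase: str, train_loss: float, val_loss: float,
               lr: float) -> None:
        self.rows.append(dict(epoch=epoch, phase=phase, train_loss=train_loss,
                              val_loss=val_loss, lr=lr))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def lr_at_epoch(lr0: float, decay: float, every: int, epoch: int) -> float:
    """Stepped decay: lr0 * decay ** floor(epoch / every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * decay ** (epoch // every)


class EarlyStopTracker:
    """Phase switching and early stopping on the validation loss.

    An epoch "improves" when its loss beats the running minimum by more
    than IMPROVEMENT_TOL.  The phase flips from random sampling to hard
    mining once `switch_patience` consecutive epochs fail to improve;
    training stops after `stop_patience` such epochs.
    """

    def __init__(self, switch_patience: int, stop_patience: int):
        self.switch_patience = switch_patience
        self.stop_patience = stop_patience
        self.best_loss = float("inf")
        self.best_epoch = -1
        self.phase = "random"

    def update(self, epoch: int, val_loss: float) -> tuple[bool, bool]:
        """Returns (improved, stop_now); may flip self.phase as a side effect."""
        improved = val_loss < self.best_loss - IMPROVEMENT_TOL
        if improved:
            self.best_loss = val_loss
            self.best_epoch = epoch
        stale = epoch - self.best_epoch
        if self.phase == "random" and stale >= self.switch_patience:
            self.phase = "hard_mining"
        return improved, stale >= self.stop_patience


def hard_mine_select(scored: list[tuple[TileSpec, float]], wsi_label: int,
                     k: int) -> list[TileSpec]:
    """The k hardest tiles of one scored slide.

    Negative slide: the k highest-probability tiles (false-positive
    candidates); positive slide: the k lowest.  Ties resolve to the
    earlier tile in grid (row-major) order; if fewer than k tiles exist,
    all are returned.
    """
    if not scored:
        raise SamplingError("hard_mine_select on an empty score list")
    probs = np.array([p for _, p in scored])
    key = -probs if wsi_label == 0 else probs
    order = np.argsort(key, kind="stable")[:k]
    return [scored[i][0] for i in order]


@dataclass
class MiningSubset:
    tiles: list[TileSpec]
    labels: np.ndarray  # parent-WSI label per tile
    slides_visited: int


class SlideStore:
    """Caches per-slide pixels, tissue masks, and tile candidate lists.

    Desk-scale slides are held fully in memory; candidate lists (the
    sliding-window tissue grid for unannotated slides, the
    annotation-rule origins for annotated ones) are computed once per
    slide and reused by sampling, mining, validation, and inference.
    """

    def __init__(self, cfg: TrainingConfig):
        self.cfg = cfg
        self._pixels: dict[str, np.ndarray] = {}
        self._masks: dict[str, TissueMask] = {}
        self._tissue: dict[str, list[TileSpec]] = {}
        self._candidates: dict[str, list[TileSpec]] = {}

    def pixels(self, slide: LabeledSlide) -> np.ndarray:
        if slide.slide_id not in self._pixels:
            self._pixels[slide.slide_id] = Slide.open(
                slide.slide.path, slide.slide_id).pixels
        return self._pixels[slide.slide_id]

    def mask(self, slide: LabeledSlide) -> TissueMask:
        if slide.slide_id not in self._masks:
            sl = Slide(slide.slide, self.pixels(slide))
            self._masks[slide.slide_id] = tissue_mask(sl, self.cfg.mask_downsample)
        return self._masks[slide.slide_id]

    def tissue(self, slide: LabeledSlide) -> list[TileSpec]:
        """All tissue tiles on the sliding-window grid (train_stride)."""
        if slide.slide_id not in self._tissue:
            origins = tile_grid(slide.slide.width, slide.slide.height,
                                self.cfg.tile_size, self.cfg.train_stride)
            self._tissue[slide.slide_id] = tissue_tiles(
                origins, self.mask(slide), slide.slide_id, self.cfg.tile_size,
                self.cfg.min_tissue_fraction)
        return self._tissue[slide.slide_id]

    def candidates(self, slide: LabeledSlide) -> list[TileSpec]:
        """Sampling/mining pool: annotation tiles if annotated, else tissue tiles."""
        if slide.slide_id not in self._candidates:
            if slide.is_annotated:
                self._candidates[slide.slide_id] = annotation_candidates(
                    slide, self.cfg.tile_size, self.cfg.train_stride)
            else:
                self._candidates[slide.slide_id] = self.tissue(slide)
        return self._candidates[slide.slide_id]

    def extract(self, tiles: list[TileSpec],
                slides_by_id: dict[str, LabeledSlide]) -> np.ndarray:
        """Stack tile pixel blocks into an (n, size, size, 3) uint8 batch."""
        size = tiles[0].size
        out = np.empty((len(tiles), size, size, 3), dtype=np.uint8)
        for i, t in enumerate(tiles):
            px = self.pixels(slides_by_id[t.slide_id])
            out[i] = px[t.y:t.y + t.size, t.x:t.x + t.size]
        return out


def hard_mining_round(model: Model, queue: Iterator[LabeledSlide],
                      store: SlideStore, cfg: TrainingConfig,
                      slides_by_id: dict[str, LabeledSlide]) -> MiningSubset:
    """Collect a training subset of exactly N hard tiles from the queue.

    Visits slides from the balanced queue, scores each slide's candidate
    tiles with the model in inference mode, keeps the k hardest per
    slide, and stops once >= N tiles are gathered; the subset is then
    truncated to exactly N in insertion order.  Each tile carries its
    parent slide's label.
    """
    tiles: list[TileSpec] = []
    labels: list[int] = []
    visits = 0
    while len(tiles) < cfg.N:
        slide = next(queue)
        visits += 1
        cands = store.candidates(slide)
        if not cands:
            logger.warning("slide %s: no candidate tiles, skipped in mining",
                           slide.slide_id)
            continue
        batch = store.extract(cands, slides_by_id)
        probs = model.predict(batch)
        hard = hard_mine_select(list(zip(cands, probs)), slide.wsi_label, cfg.k)
        tiles.extend(hard)
        labels.extend([slide.wsi_label] * len(hard))
    tiles = tiles[:cfg.N]
    labels = labels[:cfg.N]
    return MiningSubset(tiles=tiles, labels=np.array(labels), slides_visited=visits)


def _validation_sample(val_slides: list[LabeledSlide], store: SlideStore,
                       cfg: TrainingConfig, seed_seq: np.random.SeedSequence
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed seeded tile sample from the validation slides.

    Up to `val_tiles_per_slide` tiles per slide, drawn without
    replacement from each slide's candidate pool (annotation-restricted
    for annotated positives), in sorted slide-id order so the sample is
    reproducible and identical across both training phases.
    """
    ordered = sorted(val_slides, key=lambda s: s.slide_id)
    children = seed_seq.spawn(len(ordered))
    all_tiles: list[TileSpec] = []
    labels: list[int] = []
    by_id = {s.slide_id: s for s in ordered}
    for slide, child in zip(ordered, children):
        rng = np.random.default_rng(child)
        cands = store.candidates(slide)
        if not cands:
            logger.warning("validation slide %s has no candidate tiles", slide.slide_id)
            continue
        n = min(cfg.val_tiles_per_slide, len(cands))
        idx = rng.choice(len(cands), size=n, replace=False)
        all_tiles.extend(cands[i] for i in idx)
        labels.extend([slide.wsi_label] * n)
    if not all_tiles:
        raise ConfigurationError("validation set yields no tiles")
    batch = store.extract(all_tiles, by_id)
    return batch, np.array(labels)


def validation_loss(model: Model, val_batch: np.ndarray,
                    val_labels: np.ndarray) -> float:
    probs = model.predict(val_batch)
    loss, _ = bce_loss_and_grad(probs, val_labels)
    return loss


def _train_step(model: Model, optimizer, batch: np.ndarray, labels: np.ndarray,
                lr: float) -> float:
    x = model.preprocess(batch)
    probs = model.forward(x, train=True)
    loss, dlogit = bce_loss_and_grad(probs, labels)
    optimizer.zero_grad(model.params())
    model.backward_from_logit_grad(dlogit)
    optimizer.step(lr)
    return loss


def fit(train_slides: list[LabeledSlide], val_slides: list[LabeledSlide],
        cfg: TrainingConfig, backbone: BackboneConfig,
        store: SlideStore | None = None,
        progress: Callable[[dict], None] | None = None
        ) -> tuple[Model, TrainingHistory]:
    """Run the full two-phase training and return the best-epoch model."""
    for name, slides in (("train", train_slides), ("val", val_slides)):
        lab = {s.wsi_label for s in slides}
        if lab != {0, 1}:
            raise ConfigurationError(f"{name} split must contain both labels, has {lab}")

    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_queue, s_sample, s_val = ss.spawn(4)
    backbone_seed = int(s_init.generate_state(1)[0] % (2 ** 31))
    backbone = BackboneConfig(**{**asdict(backbone), "seed": backbone_seed})
    model = build_model(backbone)
    frozen_before = {p.name: p.value.copy() for p in model.params() if not p.trainable}
    optimizer = make_optimizer(model, cfg.beta1, cfg.beta2)

    store = store or SlideStore(cfg)
    by_id = {s.slide_id: s for s in train_slides + val_slides}
    queue = balanced_slide_queue(train_slides, int(s_queue.generate_state(1)[0] % (2 ** 31)))
    sample_rng = np.random.default_rng(s_sample)
    val_batch, val_labels = _validation_sample(val_slides, store, cfg, s_val)

    n_pos = sum(s.wsi_label == 1 for s in train_slides)
    n_neg = len(train_slides) - n_pos
    pairs_per_epoch = max(n_pos, n_neg)

    tracker = EarlyStopTracker(cfg.switch_patience, cfg.stop_patience)
    history = TrainingHistory()
    best_state = model.snapshot()

    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(cfg.lr0, cfg.lr_decay, cfg.decay_every, epoch)
        phase = tracker.phase
        batch_losses = []
        if phase == "random":
            for _ in range(pairs_per_epoch):
                pos, neg = next(queue), next(queue)
                tiles, labels = [], []
                for slide in (pos, neg):
                    picks = sample_tiles_from_slide(
                        slide, cfg.tiles_per_slide, cfg.tile_size,
                        store.mask(slide), sample_rng,
                        candidates=store.candidates(slide))
                    tiles.extend(picks)
                    labels.extend([slide.wsi_label] * len(picks))
                batch = store.extract(tiles, by_id)
                batch_losses.append(_train_step(model, optimizer, batch,
                                                np.array(labels), lr))
        else:
            subset = hard_mining_round(model, queue, store, cfg, by_id)
            logger.info("epoch %d mining: %d slides visited, %d/%d positive tiles",
                        epoch, subset.slides_visited, int(subset.labels.sum()), cfg.N)
            for i in range(0, cfg.N, cfg.batch_size):
                chunk = subset.tiles[i:i + cfg.batch_size]
                lab = subset.labels[i:i + cfg.batch_size]
                batch = store.extract(chunk, by_id)
                batch_losses.append(_train_step(model, optimizer, batch, lab, lr))

        vloss = validation_loss(model, val_batch, val_labels)
        tloss = float(np.mean(batch_losses)) if batch_losses else float("nan")
        history.record(epoch, phase, tloss, vloss, lr)
        improved, stop = tracker.update(epoch, vloss)
        if improved:
            best_state = model.snapshot()
        if progress:
            progress(history.rows[-1])
        logger.info("epoch %d [%s] train %.4f val %.4f lr %.6f%s", epoch, phase,
                    tloss, vloss, lr, " *" if improved else "")
        if stop:
            break

    history.best_epoch = tracker.best_epoch
    history.best_val_loss = tracker.best_loss
    model.load_state_arrays(best_state)
    for p in model.params():  # freeze contract: untouched for the whole fit
        if not p.trainable and p.name in frozen_before:
            assert np.array_equal(p.value, frozen_before[p.name])
    return model, history
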