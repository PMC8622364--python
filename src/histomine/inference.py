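"""Whole-slide inference, heatmaps, and WSI-level evaluation statistics.

A slide's score is the maximum of its tile probabilities over a
sliding-window grid restricted to tissue — a single confident tile flags
the slide, the natural aggregation for a "does this biopsy contain
poorly differentiated tumour anywhere" question.  Evaluation reports
ROC AUC and log loss with stratified percentile-bootstrap confidence
intervals, a confusion matrix at a probability threshold, and the
specificity achievable while keeping sensitivity at 100%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import UndefinedMetricError
from .model import Model, ensemble_predict, predict_tiles
from .slide_io import Slide, TissueMask
from .tiling import (DEFAULT_MIN_TISSUE_FRACTION, LabeledSlide, TileSpec,
                     tile_grid, tissue_tiles)

PROB_CLIP = 1e-7


@dataclass
class SlidePrediction:
    """Per-tile probabilities on the inference grid plus the max-aggregated score."""

    slide_id: str
    tile_scores: list[tuple[TileSpec, float]]
    wsi_score: float
    undefined: bool = False  # no tissue tiles: score carries no information


@dataclass
class EvalReport:
    n: int
    roc_auc: float
    auc_ci: tuple[float, float]
    log_loss: float
    log_loss_ci: tuple[float, float]
    threshold: float
    confusion: dict  # tn / fp / fn / tp
    sensitivity: float
    specificity: float
    full_sensitivity_threshold: float
    specificity_at_full_sensitivity: float
    bootstrap_iterations: int

    def to_json(self, **extra) -> str:
        d = {**self.__dict__, **extra}
        return json.dumps(d, indent=2, default=float)


def predict_wsi(model: Model | list[Model], slide: LabeledSlide | Slide,
                tile_size: int, stride: int, mask: TissueMask,
                min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
                pixels: np.ndarray | None = None,
                batch_size: int = 256) -> SlidePrediction:
    """Sliding-window prediction with max aggregation.

    Accepts a single model or a list (ensemble: tile probabilities are
    averaged across members before taking the slide maximum).
    """
    if isinstance(slide, Slide):
        ref, px = slide.ref, slide.pixels
    else:
        ref = slide.slide
        px = pixels if pixels is not None else Slide.open(ref.path, ref.id).pixels
    origins = tile_grid(ref.width, ref.height, tile_size, stride)
    tiles = tissue_tiles(origins, mask, ref.id, tile_size, min_tissue_fraction)
    if not tiles:
        warnings.warn(f"slide {ref.id}: no tissue tiles, WSI score undefined",
                      stacklevel=2)
        return SlidePrediction(slide_id=ref.id, tile_scores=[],
                               wsi_score=float("nan"), undefined=True)
    batch = np.empty((len(tiles), tile_size, tile_size, 3), dtype=np.uint8)
    for i, t in enumerate(tiles):
        batch[i] = px[t.y:t.y + t.size, t.x:t.x + t.size]
    if isinstance(model, list):
        probs = ensemble_predict(model, batch, batch_size=batch_size)
    else:
        probs = predict_tiles(model, batch, batch_size=batch_size)
    scores = list(zip(tiles, (float(p) for p in probs)))
    return SlidePrediction(slide_id=ref.id, tile_scores=scores,
                           wsi_score=float(probs.max()))


def render_heatmap(pred: SlidePrediction, downsample: int,
                   slide_width: int | None = None, slide_height: int | None = None,
                   thumbnail: np.ndarray | None = None,
                   cmap: str = "inferno", overlay_alpha: float = 0.5) -> np.ndarray:
    """Paint tile probabilities onto a downsampled canvas, overlaps by max.

    Returns an RGB uint8 image; if a thumbnail of matching shape is
    given, the heatmap is alpha-blended onto it.
    """
    import matplotlib

    if not pred.tile_scores:
        raise ValueError(f"slide {pred.slide_id}: no tile scores to render")
    if slide_width is None:
        slide_width = max(t.x + t.size for t, _ in pred.tile_scores)
        slide_height = max(t.y + t.size for t, _ in pred.tile_scores)
    h = -(-slide_height // downsample)
    w = -(-slide_width // downsample)
    canvas = np.zeros((h, w), dtype=np.float32)
    for t, p in pred.tile_scores:
        x0, y0 = t.x // downsample, t.y // downsample
        x1 = -(-(t.x + t.size) // downsample)
        y1 = -(-(t.y + t.size) // downsample)
        region = canvas[y0:y1, x0:x1]
        np.maximum(region, p, out=region)
    rgba = matplotlib.colormaps[cmap](canvas)
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    if thumbnail is not None:
        if thumbnail.shape[:2] != rgb.shape[:2]:
            raise ValueError("thumbnail shape does not match heatmap canvas")
        rgb = (overlay_alpha * rgb + (1 - overlay_alpha) * thumbnail).astype(np.uint8)
    return rgb


# ---------------------------------------------------------------------------
# WSI-level statistics

def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metric undefined: only one class present")


def roc_auc(labels, scores) -> float:
    """All-pairs concordance P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def log_loss(labels, scores, clip: float = PROB_CLIP) -> float:
    """Mean binary cross-entropy with probabilities clipped to [clip, 1-clip]."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("log_loss on empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    p = np.clip(scores, clip, 1.0 - clip)
    return float(np.mean(-(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))))


_METRICS = {"auc": roc_auc, "log_loss": log_loss}


def bootstrap_ci(metric: str, labels, scores, iterations: int = 1000,
                 seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Stratified percentile bootstrap CI.

    Resamples with replacement *within each class*, preserving class
    counts, so AUC is defined on every resample; returns the 2.5/97.5
    percentile bounds (for alpha=0.05) over `iterations` seeded resamples.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    fn = _METRICS[metric]
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_two_class(labels)
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    values = np.empty(iterations)
    for i in range(iterations):
        idx = np.concatenate([rng.choice(ci, size=len(ci), replace=True)
                              for ci in class_idx])
        values[i] = fn(labels[idx], scores[idx])
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def confusion_at_threshold(labels, scores, t: float) -> dict:
    """2x2 counts with predicted positive iff score >= t."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= t
    return {
        "tn": int(np.sum((labels == 0) & ~pred)),
        "fp": int(np.sum((labels == 0) & pred)),
        "fn": int(np.sum((labels == 1) & ~pred)),
        "tp": int(np.sum((labels == 1) & pred)),
    }


def specificity_at_full_sensitivity(labels, scores) -> tuple[float, float]:
    """Lowest threshold keeping every positive called, and its specificity.

    The threshold is the minimum score among positives (>= comparison
    keeps all positives); specificity is the fraction of negatives
    scoring strictly below it.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not (labels == 1).any() or not (labels == 0).any():
        raise UndefinedMetricError("need at least one slide of each class")
    threshold = float(scores[labels == 1].min())
    neg = scores[labels == 0]
    return threshold, float(np.mean(neg < threshold))


def evaluate(labels, scores, threshold: float = 0.5, bootstrap_iterations: int = 1000,
             seed: int = 0) -> EvalReport:
    """Full WSI-level evaluation report."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    auc = roc_auc(labels, scores)
    ll = log_loss(labels, scores)
    ss = np.random.SeedSequence(seed)
    s_auc, s_ll = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    auc_ci = bootstrap_ci("auc", labels, scores, bootstrap_iterations, s_auc)
    ll_ci = bootstrap_ci("log_loss", labels, scores, bootstrap_iterations, s_ll)
    conf = confusion_at_threshold(labels, scores, threshold)
    tp, fn = conf["tp"], conf["fn"]
    tn, fp = conf["tn"], conf["fp"]
    fs_thr, fs_spec = specificity_at_full_sensitivity(labels, scores)
    return EvalReport(
        n=len(labels), roc_auc=auc, auc_ci=auc_ci, log_loss=ll, log_loss_ci=ll_ci,
        threshold=threshold, confusion=conf,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        full_sensitivity_threshold=fs_thr,
        specificity_at_full_sensitivity=fs_spec,
        bootstrap_iterations=bootstrap_iterations,
    )
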