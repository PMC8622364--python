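"""Tile-grid enumeration, tissue filtering, balanced sampling.

Training batches are balanced at two levels: a shuffled queue alternates
positive and negative slides (reshuffling an exhausted label pool so the
minority class is oversampled), and each selected slide contributes
batch_size / num_labels tiles.  Annotated (positive) slides are sampled
only inside their annotation polygons; unannotated slides are sampled
uniformly from their tissue tiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, annotation_tile_origins, load_annotations
from .errors import ConfigurationError, GeometryError, SamplingError
from .slide_io import SlideRef, TissueMask

POSITIVE_LABEL = "poorly_adc"
NEGATIVE_LABEL = "other"

#: Minimum fraction of tissue mask pixels for a tile to count as tissue.
DEFAULT_MIN_TISSUE_FRACTION = 0.1


@dataclass
class TileSpec:
    """A square tile: slide, origin (base-magnification px), side length."""

    slide_id: str
    x: int
    y: int
    size: int

    def key(self) -> tuple:
        return (self.slide_id, self.x, self.y, self.size)


@dataclass
class LabeledSlide:
    """A manifest row: slide reference, WSI label, split, optional annotations."""

    slide: SlideRef
    wsi_label: int  # 1 = poorly differentiated ADC, 0 = other
    split: str  # train / val / test
    annotations: AnnotationSet | None = None

    @property
    def slide_id(self) -> str:
        return self.slide.id

    @property
    def is_annotated(self) -> bool:
        return self.annotations is not None and len(self.annotations) > 0


def tile_grid(width: int, height: int, tile_size: int, stride: int) -> list[tuple[int, int]]:
    """Sliding-window origins over a width x height slide.

    Origins at multiples of `stride`; when the last strided tile would
    overrun, a final origin clamped to dim - tile_size is appended so the
    grid always reaches the slide edge.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if tile_size > width or tile_size > height:
        raise GeometryError(
            f"tile_size {tile_size} exceeds slide dimensions {width}x{height}")

    def axis(dim: int) -> list[int]:
        xs = list(range(0, dim - tile_size + 1, stride))
        if xs[-1] != dim - tile_size:
            xs.append(dim - tile_size)
        return xs

    return [(x, y) for y in axis(height) for x in axis(width)]


def tile_tissue_fraction(mask: TissueMask, x: int, y: int, tile_size: int) -> float:
    """Fraction of a tile's footprint covered by tissue, measured on the mask."""
    f = mask.downsample_factor
    x0, y0 = x // f, y // f
    x1, y1 = -(-(x + tile_size) // f), -(-(y + tile_size) // f)
    block = mask.mask[y0:y1, x0:x1]
    return float(block.mean()) if block.size else 0.0


def tissue_tiles(origins: list[tuple[int, int]], mask: TissueMask, slide_id: str,
                 tile_size: int,
                 min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION) -> list[TileSpec]:
    """Keep grid tiles whose tissue fraction reaches the threshold."""
    out = []
    for x, y in origins:
        if tile_tissue_fraction(mask, x, y, tile_size) >= min_tissue_fraction:
            out.append(TileSpec(slide_id=slide_id, x=x, y=y, size=tile_size))
    return out


def balanced_slide_queue(slides: list[LabeledSlide],
                         rng_seed: int) -> Iterator[LabeledSlide]:
    """Infinite queue alternating positive / negative slides.

    Each label pool is independently seeded-shuffled; an exhausted pool
    is reshuffled and reused, oversampling the minority label so batches
    stay balanced however skewed the slide counts are.
    """
    pos = [s for s in slides if s.wsi_label == 1]
    neg = [s for s in slides if s.wsi_label == 0]
    if not pos or not neg:
        raise ConfigurationError(
            f"balanced queue needs both labels: {len(pos)} positive, {len(neg)} negative")
    ss = np.random.SeedSequence(rng_seed)
    rng_pos, rng_neg = (np.random.default_rng(c) for c in ss.spawn(2))

    def pool(items: list[LabeledSlide], rng: np.random.Generator) -> Iterator[LabeledSlide]:
        while True:
            order = rng.permutation(len(items))
            for i in order:
                yield items[i]

    pos_iter, neg_iter = pool(pos, rng_pos), pool(neg, rng_neg)
    while True:
        yield next(pos_iter)
        yield next(neg_iter)


def annotation_candidates(slide: LabeledSlide, tile_size: int,
                          grid_stride: int | None = None) -> list[TileSpec]:
    """Union of annotation-rule tile origins over all annotations of a slide."""
    assert slide.annotations is not None
    seen: set[tuple[int, int]] = set()
    out: list[TileSpec] = []
    for ann in slide.annotations.annotations:
        for ox, oy in annotation_tile_origins(
                ann, tile_size, grid_stride,
                slide_width=slide.slide.width, slide_height=slide.slide.height):
            if (ox, oy) not in seen:
                seen.add((ox, oy))
                out.append(TileSpec(slide_id=slide.slide_id, x=ox, y=oy, size=tile_size))
    return out


def sample_tiles_from_slide(slide: LabeledSlide, n_tiles: int, tile_size: int,
                            mask: TissueMask, rng: np.random.Generator,
                            stride: int | None = None,
                            min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
                            candidates: list[TileSpec] | None = None) -> list[TileSpec]:
    """Draw n_tiles tiles (with replacement) from one slide.

    Annotated slides draw from the union of annotation tile origins;
    unannotated slides draw uniformly from tissue tiles on the stride
    grid.  `candidates` short-circuits recomputation when the caller
    caches per-slide candidate lists.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if candidates is None:
        if slide.is_annotated:
            candidates = annotation_candidates(slide, tile_size, stride)
        else:
            origins = tile_grid(slide.slide.width, slide.slide.height, tile_size,
                                stride or tile_size // 2)
            candidates = tissue_tiles(origins, mask, slide.slide_id, tile_size,
                                      min_tissue_fraction)
    if not candidates:
        kind = "annotation" if slide.is_annotated else "tissue"
        raise SamplingError(f"slide {slide.slide_id}: no valid {kind} tiles to sample")
    idx = rng.integers(0, len(candidates), size=n_tiles)
    return [candidates[i] for i in idx]


# ---------------------------------------------------------------------------
# Manifest I/O

MANIFEST_COLUMNS = ["slide_id", "slide_path", "label", "annotation_path", "split"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the slide manifest CSV."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "annotation_path"]
    if missing:
        raise ConfigurationError(f"manifest {path} missing columns: {missing}")
    if "annotation_path" not in df.columns:
        df["annotation_path"] = ""
    bad = set(df["label"]) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ConfigurationError(f"manifest {path}: unknown labels {sorted(bad)}")
    if df["slide_id"].duplicated().any():
        dupes = df.loc[df["slide_id"].duplicated(), "slide_id"].tolist()
        raise ConfigurationError(f"manifest {path}: duplicate slide ids {dupes}")
    return df


def load_labeled_slides(manifest_path: str | Path,
                        split: str | None = None) -> list[LabeledSlide]:
    """Materialise LabeledSlide records (image headers + annotations) from a manifest.

    Positive training slides must carry annotations; negative slides need none.
    """
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
    base = manifest_path.parent
    out = []
    for row in df.itertuples(index=False):
        spath = Path(row.slide_path)
        if not spath.is_absolute():
            spath = base / spath
        props = iio.improps(spath)
        h, w = props.shape[:2]
        ref = SlideRef(id=row.slide_id, path=spath, width=w, height=h)
        annotations = None
        if row.annotation_path:
            apath = Path(row.annotation_path)
            if not apath.is_absolute():
                apath = base / apath
            annotations = load_annotations(apath, slide_id=row.slide_id)
        label = 1 if row.label == POSITIVE_LABEL else 0
        if label == 1 and row.split == "train" and annotations is None:
            raise ConfigurationError(
                f"positive training slide {row.slide_id} has no annotations")
        out.append(LabeledSlide(slide=ref, wsi_label=label, split=row.split,
                                annotations=annotations))
    return out
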