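"""Synthetic H&E-like slides with ground truth, for end-to-end testing.

Real biopsy WSIs from the source hospitals are private, so the pipeline
is exercised on generated fixtures that reproduce the statistical
structure it relies on: a bright glass background (~245 gray), a handful
of darker pink-tinted tissue fragments (~155 gray) with smooth mottling
and gland-like ring motifs, and — on positive slides only — regions of
densely packed small dark blue-purple nuclei (region mean ~90 gray, the
"diffuse small dark nuclei" texture of poorly differentiated tumour),
each covered by a free-hand-style annotation polygon.  The positive
texture is locally detectable inside a single tile, matching the
weak-label assumption of tile-based training, and every pixel of ground
truth (tissue mask, positive-texture mask, region polygons) is returned
alongside the image.

All randomness flows from SynthConfig.seed through named substreams;
the same seed reproduces byte-identical images and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .annotations import Annotation, AnnotationSet, save_annotations
from .errors import ConfigurationError
from .tiling import NEGATIVE_LABEL, POSITIVE_LABEL

# Appearance constants (8-bit levels).  Tissue ~155 gray, positive
# texture region mean ~90: a >= 30-level separation a single tile can see.
TISSUE_RGB = np.array([200.0, 140.0, 170.0])     # eosin pink, gray ~155
NUCLEUS_RGB = np.array([62.0, 50.0, 112.0])      # hematoxylin purple, gray ~57
RING_DELTA = -30.0                               # gland wall darkening
LUMEN_DELTA = +18.0                              # gland lumen lightening
NUCLEUS_COVERAGE = 0.7                           # Boolean-model target coverage


@dataclass
class SynthConfig:
    n_positive: int = 10
    n_negative: int = 10
    slide_size: int = 2048
    background_gray: int = 245
    n_fragments: tuple[int, int] = (3, 7)          # inclusive range per slide
    positive_region_fraction: tuple[float, float] = (0.1, 0.4)
    noise_sd: float = 8.0
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if self.n_positive + self.n_negative < 2:
            raise ConfigurationError("need at least 2 slides")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


@dataclass
class SlideFixture:
    """A generated slide plus every piece of ground truth about it."""

    slide_id: str
    label: str
    image: np.ndarray                      # HxWx3 uint8
    tissue_mask: np.ndarray                # bool, full resolution
    positive_mask: np.ndarray              # bool; empty on negative slides
    annotations: AnnotationSet | None      # positives only
    region_polygons: list[list[tuple[float, float]]] = field(default_factory=list)


def _ellipse_mask(shape, cy, cx, ry, rx, rotation, rng=None) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape, rotation=rotation)
    m[rr, cc] = True
    return m


def _smooth_field(rng: np.random.Generator, shape, cells: int = 16,
                  amplitude: float = 10.0) -> np.ndarray:
    """Low-frequency mottling: a coarse random grid upsampled by np.kron."""
    h, w = shape
    coarse = rng.normal(0.0, amplitude, size=(cells, cells))
    fh, fw = -(-h // cells), -(-w // cells)
    return np.kron(coarse, np.ones((fh, fw)))[:h, :w]


def _ellipse_polygon(cy: float, cx: float, ry: float, rx: float, rotation: float,
                     n_vertices: int = 32, inflate: float = 1.03,
                     pad: float = 3.0) -> list[tuple[float, float]]:
    """Vertex ring circumscribing the (inflated) ellipse, as (x, y) pairs."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    ey = (ry * inflate + pad) * np.sin(theta)
    ex = (rx * inflate + pad) * np.cos(theta)
    c, s = math.cos(rotation), math.sin(rotation)
    xs = cx + ex * c - ey * s
    ys = cy + ex * s + ey * c
    return [(float(x), float(y)) for x, y in zip(xs, ys)]


def generate_slide(kind: str, cfg: SynthConfig, rng: np.random.Generator,
                   slide_id: str = "slide") -> SlideFixture:
    """Render one synthetic slide with ground-truth masks and annotations."""
    if kind not in ("positive", "negative"):
        raise ValueError(f"kind must be positive/negative, got {kind!r}")
    n = cfg.slide_size
    shape = (n, n)

    # glass background with sensor noise
    img = np.full((n, n, 3), float(cfg.background_gray))
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)

    # tissue fragments: unions of overlapping rotated ellipses
    tissue = np.zeros(shape, dtype=bool)
    n_frag = int(rng.integers(cfg.n_fragments[0], cfg.n_fragments[1] + 1))
    frag_params = []
    for _ in range(n_frag):
        cy, cx = rng.uniform(0.18 * n, 0.82 * n, size=2)
        ry = rng.uniform(0.08 * n, 0.18 * n)
        rx = rng.uniform(0.08 * n, 0.18 * n)
        rot = rng.uniform(0.0, math.pi)
        frag_params.append((cy, cx, ry, rx, rot))
        for _ in range(int(rng.integers(2, 4))):
            dy, dx = rng.normal(0.0, 0.25, size=2) * min(ry, rx)
            tissue |= _ellipse_mask(shape, cy + dy, cx + dx,
                                    ry * rng.uniform(0.6, 1.0),
                                    rx * rng.uniform(0.6, 1.0),
                                    rng.uniform(0.0, math.pi))

    # pink tissue with per-channel mottling
    mottle = _smooth_field(rng, shape, cells=16, amplitude=6.0)
    for c in range(3):
        chan = img[..., c]
        chan[tissue] = (TISSUE_RGB[c] + mottle[tissue]
                        + rng.normal(0.0, cfg.noise_sd, size=int(tissue.sum())))

    # gland-like ring motifs (negative texture) scattered over the tissue
    ys, xs = np.nonzero(tissue)
    n_rings = max(1, int(tissue.sum() / 60000))
    for _ in range(n_rings):
        j = rng.integers(0, len(ys))
        cy, cx = float(ys[j]), float(xs[j])
        r_out = rng.uniform(0.008 * n, 0.018 * n)
        r_in = r_out - rng.uniform(2.5, 5.0)
        outer = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((cy, cx), r_out, shape=shape)
        outer[rr, cc] = True
        inner = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((cy, cx), max(1.0, r_in), shape=shape)
        inner[rr, cc] = True
        wall = outer & ~inner & tissue
        lumen = inner & tissue
        img[wall] += RING_DELTA
        img[lumen] += LUMEN_DELTA

    positive = np.zeros(shape, dtype=bool)
    annotations = None
    region_polys: list[list[tuple[float, float]]] = []

    if kind == "positive":
        target_frac = rng.uniform(*cfg.positive_region_fraction)
        n_regions = int(rng.integers(1, 4))
        tissue_area = float(tissue.sum())
        area_per_region = target_frac * tissue_area / n_regions
        ann_list = []
        for _ in range(n_regions):
            fcy, fcx, fry, frx, frot = frag_params[rng.integers(0, n_frag)]
            # region ellipse centred inside the fragment with the target area
            aspect = rng.uniform(0.6, 1.4)
            ry = math.sqrt(area_per_region * aspect / math.pi)
            rx = area_per_region / (math.pi * ry)
            if min(rx, ry) < 8.0:
                raise ConfigurationError(
                    "positive_region_fraction too small: region thinner than 8 px, "
                    "no tile could sample it")
            cy = fcy + rng.normal(0.0, 0.15) * fry
            cx = fcx + rng.normal(0.0, 0.15) * frx
            rot = rng.uniform(0.0, math.pi)
            poly = _ellipse_polygon(cy, cx, ry, rx, rot)
            poly = [(min(max(x, 0.0), n - 1.0), min(max(y, 0.0), n - 1.0))
                    for x, y in poly]
            # nuclei are confined to ellipse ∩ tissue ∩ rasterized polygon, so
            # the annotation covers the positive texture by construction
            poly_mask = np.zeros(shape, dtype=bool)
            rr, cc = draw_polygon([p[1] for p in poly], [p[0] for p in poly], shape=shape)
            poly_mask[rr, cc] = True
            region = _ellipse_mask(shape, cy, cx, ry, rx, rot) & tissue & poly_mask
            if not region.any():
                continue
            # dense small dark nuclei confined to the region (Boolean model:
            # coverage 1 - exp(-lambda pi r^2) ~= NUCLEUS_COVERAGE)
            r_mean = 3.5
            lam = -math.log(1.0 - NUCLEUS_COVERAGE) / (math.pi * r_mean ** 2)
            n_nuclei = int(lam * math.pi * ry * rx)
            rys, rxs = np.nonzero(region)
            centers = rng.integers(0, len(rys), size=n_nuclei)
            drawn = np.zeros(shape, dtype=bool)
            for j in centers:
                r = rng.uniform(2.2, 4.8)
                rr, cc = draw_disk((float(rys[j]), float(rxs[j])), r, shape=shape)
                drawn[rr, cc] = True
            drawn &= region
            for c in range(3):
                chan = img[..., c]
                chan[drawn] = NUCLEUS_RGB[c] + rng.normal(
                    0.0, cfg.noise_sd, size=int(drawn.sum()))
            positive |= drawn
            region_polys.append(poly)
            ann_list.append(Annotation(polygon=poly, label="poorly_diff_adc"))
        if not ann_list:
            raise ConfigurationError(
                f"slide {slide_id}: no positive region could be placed")
        annotations = AnnotationSet(slide_id=slide_id, annotations=ann_list)

    image = np.clip(img, 0, 255).astype(np.uint8)
    return SlideFixture(slide_id=slide_id,
                        label=POSITIVE_LABEL if kind == "positive" else NEGATIVE_LABEL,
                        image=image, tissue_mask=tissue, positive_mask=positive,
                        annotations=annotations, region_polygons=region_polys)


def _split_assignment(n: int, fractions, rng: np.random.Generator) -> list[str]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n - 2)) if n >= 3 else n_train
    n_val = max(1, min(n_val, n - n_train - 1)) if n - n_train >= 2 else n_val
    splits = (["train"] * n_train + ["val"] * n_val
              + ["test"] * (n - n_train - n_val))
    perm = rng.permutation(n)
    out = [""] * n
    for i, s in zip(perm, splits):
        out[i] = s
    return out


def generate_dataset(cfg: SynthConfig, out_dir: str | Path,
                     split_counts: dict[str, tuple[int, int]] | None = None) -> Path:
    """Write slides, annotations, and a stratified manifest; returns its path.

    `split_counts` optionally pins exact per-label (train, val) counts
    (the remainder goes to test) instead of the fractional split.
    """
    out_dir = Path(out_dir)
    (out_dir / "slides").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    s_slides, s_split = ss.spawn(2)
    slide_streams = s_slides.spawn(cfg.n_positive + cfg.n_negative)
    split_rng = np.random.default_rng(s_split)

    rows = []
    kinds = ([("positive", i) for i in range(cfg.n_positive)]
             + [("negative", i) for i in range(cfg.n_negative)])
    for (kind, i), stream in zip(kinds, slide_streams):
        slide_id = f"{'pos' if kind == 'positive' else 'neg'}_{i:03d}"
        fx = generate_slide(kind, cfg, np.random.default_rng(stream), slide_id)
        img_path = out_dir / "slides" / f"{slide_id}.png"
        iio.imwrite(img_path, fx.image)
        ann_path = ""
        if fx.annotations is not None:
            ann_file = out_dir / "annotations" / f"{slide_id}.geojson"
            save_annotations(fx.annotations, ann_file)
            ann_path = str(ann_file.relative_to(out_dir))
        rows.append(dict(slide_id=slide_id,
                         slide_path=str(img_path.relative_to(out_dir)),
                         label=fx.label, annotation_path=ann_path))

    df = pd.DataFrame(rows)
    df["split"] = ""
    for label in (POSITIVE_LABEL, NEGATIVE_LABEL):
        idx = df.index[df["label"] == label].to_numpy()
        if split_counts is not None:
            n_train, n_val = split_counts[label]
            splits = (["train"] * n_train + ["val"] * n_val
                      + ["test"] * (len(idx) - n_train - n_val))
            perm = split_rng.permutation(len(idx))
            for i, s in zip(perm, splits):
                df.loc[idx[i], "split"] = s
        else:
            assignment = _split_assignment(len(idx), cfg.split_fractions, split_rng)
            for i, s in zip(idx, assignment):
                df.loc[i, "split"] = s

    manifest = out_dir / "manifest.csv"
    df.to_csv(manifest, index=False)
    return manifest


def baseline_darkness_wsi_score(image: np.ndarray, tissue_tile_origins,
                                tile_size: int) -> float:
    """Mean-darkness straw-man classifier: max over tiles of 1 - gray/255.

    Exists to certify the learning task is solvable from single-tile
    statistics; a trained model failing where this succeeds indicates a
    pipeline bug, not impossible data.
    """
    from .slide_io import to_grayscale

    gray = to_grayscale(image)
    best = 0.0
    for x, y in tissue_tile_origins:
        m = float(gray[y:y + tile_size, x:x + tile_size].mean())
        best = max(best, 1.0 - m / 255.0)
    return best
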