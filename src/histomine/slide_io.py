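"""Slide reading, grayscale conversion, Otsu thresholding, tissue masks.

Slides are plain RGB raster images (PNG/TIFF); pyramidal containers are
read at their base level through tifffile where possible.  All
coordinates are 0-based pixels at base magnification with half-open
intervals [x, x+w), the convention shared by every module downstream.
Tissue is taken to be *darker* than the near-white glass background, so
a mask pixel is tissue where the downsampled grayscale falls strictly
below the Otsu level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateHistogramError, SlideBoundsError, SlideIOError

#: ITU-R 709 luminosity weights for RGB -> gray.
GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

#: Default mask downsample: one mask pixel summarises 32x32 base pixels.
DEFAULT_MASK_DOWNSAMPLE = 32


@dataclass
class SlideRef:
    """A slide on disk plus its base-magnification dimensions."""

    id: str
    path: Path
    width: int
    height: int
    magnification_tag: str = "x20"

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"slide {self.id}: non-positive dimensions")


@dataclass
class TissueMask:
    """Low-resolution binary tissue mask; True = tissue."""

    mask: np.ndarray  # 2-D bool, shape (ceil(h/f), ceil(w/f))
    downsample_factor: int
    otsu_level: int
    degenerate: bool = False  # blank slide: all-False mask, warning issued

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


def _load_pixels(path: Path) -> np.ndarray:
    """Read a slide image as HxWx3 uint8."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise SlideIOError(f"cannot read slide image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


class Slide:
    """An opened slide: SlideRef plus cached pixel data.

    Desk-scale slides fit in memory, so the full base-level raster is
    held and region reads are array slices.
    """

    def __init__(self, ref: SlideRef, pixels: np.ndarray):
        self.ref = ref
        self.pixels = pixels

    @classmethod
    def open(cls, path: str | Path, slide_id: str | None = None,
             magnification_tag: str = "x20") -> "Slide":
        path = Path(path)
        pixels = _load_pixels(path)
        h, w = pixels.shape[:2]
        ref = SlideRef(id=slide_id or path.stem, path=path, width=w, height=h,
                       magnification_tag=magnification_tag)
        return cls(ref, pixels)


def read_region(slide: Slide, x: int, y: int, w: int, h: int) -> np.ndarray:
    """Return the w x h x 3 uint8 block at half-open [x, x+w) x [y, y+h)."""
    ref = slide.ref
    if x < 0 or y < 0 or x + w > ref.width or y + h > ref.height:
        raise SlideBoundsError(
            f"slide {ref.id}: region ({x},{y},{w},{h}) outside "
            f"{ref.width}x{ref.height}")
    return slide.pixels[y:y + h, x:x + w].copy()


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """8-bit luminosity grayscale: round(0.2125 R + 0.7154 G + 0.0721 B)."""
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 RGB, got shape {rgb.shape}")
    gray = rgb.astype(np.float64) @ GRAY_WEIGHTS
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def otsu_level(histogram: np.ndarray) -> int:
    """Otsu threshold on a 256-bin grayscale histogram.

    Returns the level L in [1, 255] maximising the between-class variance
    of the split {gray < L} vs {gray >= L}; ties broken by the lowest L.
    Pixels below the level are the dark (tissue) class.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0) or hist.sum() <= 0:
        raise ValueError("histogram must be nonnegative with positive total")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "single populated gray level: Otsu split undefined")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative mass/mean of the class {gray < L} for L = 1..255
    w0 = np.cumsum(hist)[:-1] / total               # weight below each candidate
    mu0_num = np.cumsum(hist * levels)[:-1] / total
    mu_total = float((hist * levels).sum() / total)
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, mu0_num / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - mu0_num) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(between)) + 1  # +1: index i is the split L = i+1


def _downsample_gray(gray: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample, padding the ragged edge with the edge values."""
    h, w = gray.shape
    oh, ow = -(-h // factor), -(-w // factor)
    ph, pw = oh * factor - h, ow * factor - w
    g = np.pad(gray.astype(np.float64), ((0, ph), (0, pw)), mode="edge")
    return g.reshape(oh, factor, ow, factor).mean(axis=(1, 3))


def tissue_mask(slide: Slide, downsample_factor: int = DEFAULT_MASK_DOWNSAMPLE) -> TissueMask:
    """Binary tissue mask on a downsampled grid via Otsu thresholding.

    The Otsu level is computed from the full-resolution grayscale
    histogram; a mask pixel is tissue where its block-mean gray value is
    strictly below that level.  A blank slide (degenerate histogram)
    yields an all-False mask with a warning rather than an error.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    gray = to_grayscale(slide.pixels)
    hist = np.bincount(gray.ravel(), minlength=256)
    small = _downsample_gray(gray, downsample_factor)
    try:
        level = otsu_level(hist)
    except DegenerateHistogramError:
        warnings.warn(f"slide {slide.ref.id}: degenerate histogram, empty tissue mask",
                      stacklevel=2)
        return TissueMask(mask=np.zeros(small.shape, dtype=bool),
                          downsample_factor=downsample_factor, otsu_level=0,
                          degenerate=True)
    return TissueMask(mask=small < level, downsample_factor=downsample_factor,
                      otsu_level=level)


def save_mask(mask: TissueMask, png_path: str | Path) -> None:
    """Write the mask as a single-channel PNG plus a JSON sidecar."""
    png_path = Path(png_path)
    iio.imwrite(png_path, (mask.mask.astype(np.uint8) * 255))
    sidecar = png_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "downsample_factor": mask.downsample_factor,
        "otsu_level": mask.otsu_level,
        "degenerate": mask.degenerate,
    }, indent=2))


def load_mask(png_path: str | Path) -> TissueMask:
    png_path = Path(png_path)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    arr = iio.imread(png_path)
    return TissueMask(mask=arr > 127, downsample_factor=int(meta["downsample_factor"]),
                      otsu_level=int(meta["otsu_level"]),
                      degenerate=bool(meta.get("degenerate", False)))
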