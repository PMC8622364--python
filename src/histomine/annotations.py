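"""Free-hand polygon annotations and annotation-driven tile placement.

Positive regions are marked by pathologist-style free-hand polygons in
base-magnification pixel coordinates, stored as GeoJSON Polygon features
with a ``label`` property (QuPath-compatible).  Tile placement follows
two rules: an annotation smaller than the tile gets one tile centred on
it; a larger annotation is covered by an overlapping grid over its
bounding box, keeping every tile that intersects the polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from shapely.geometry import Polygon, box

from .errors import AnnotationFormatError, GeometryError


@dataclass
class Annotation:
    """One free-hand polygon (>= 3 vertices, implicitly closed)."""

    polygon: list[tuple[float, float]]
    label: str = "poorly_diff_adc"

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class AnnotationSet:
    slide_id: str
    annotations: list[Annotation]

    def __len__(self) -> int:
        return len(self.annotations)


def load_annotations(path: str | Path, slide_id: str | None = None) -> AnnotationSet:
    """Parse a GeoJSON FeatureCollection of labelled Polygon features."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationFormatError(f"cannot parse {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise AnnotationFormatError(f"{path}: expected a FeatureCollection")
    annotations = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise AnnotationFormatError(
                f"{path}: feature {i} has geometry {geom.get('type')!r}, "
                "only Polygon is supported")
        props = feat.get("properties") or {}
        if "label" not in props:
            raise AnnotationFormatError(f"{path}: feature {i} missing 'label' property")
        ring = geom["coordinates"][0]
        verts = [(float(x), float(y)) for x, y in ring]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]  # drop the explicit closure; polygons close implicitly
        annotations.append(Annotation(polygon=verts, label=str(props["label"])))
    return AnnotationSet(slide_id=slide_id or doc.get("slide_id", path.stem),
                         annotations=annotations)


def save_annotations(aset: AnnotationSet, path: str | Path) -> None:
    """Write GeoJSON with explicitly closed rings (round-trips exactly)."""
    features = []
    for ann in aset.annotations:
        ring = [list(v) for v in ann.polygon] + [list(ann.polygon[0])]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"label": ann.label},
        })
    doc = {"type": "FeatureCollection", "slide_id": aset.slide_id, "features": features}
    Path(path).write_text(json.dumps(doc))


def _axis_origins(start: float, stop: float, tile_size: int, stride: int) -> list[int]:
    """Grid origins from `start`, clamped so the last tile ends at `stop`."""
    origins = []
    pos = start
    while pos + tile_size <= stop + 1e-9:
        origins.append(int(round(pos)))
        pos += stride
    last = int(round(stop)) - tile_size
    if last >= int(round(start)) and (not origins or origins[-1] != last):
        origins.append(last)
    return origins


def annotation_tile_origins(annotation: Annotation, tile_size: int,
                            grid_stride: int | None = None,
                            slide_width: int | None = None,
                            slide_height: int | None = None) -> list[tuple[int, int]]:
    """Tile origins sampling one annotation.

    Small annotation (bbox width and height both <= tile_size): one tile
    centred on the bbox centroid, clamped into the slide.  Larger
    annotation: overlapping grid over the bbox (default stride
    tile_size/2), last row/column clamped to the bbox edge, keeping only
    tiles that intersect the polygon.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    stride = grid_stride if grid_stride is not None else tile_size // 2
    if not (0 < stride <= tile_size):
        raise ValueError("grid_stride must be in (0, tile_size]")
    poly = annotation.shapely()
    x0, y0, x1, y1 = poly.bounds
    bw, bh = x1 - x0, y1 - y0
    if bw <= 0 or bh <= 0:
        raise GeometryError("degenerate annotation: zero-area bounding box")

    def clamp(v: int, upper: int | None) -> int:
        v = max(0, v)
        if upper is not None:
            v = min(v, upper - tile_size)
        return v

    if bw <= tile_size and bh <= tile_size:
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        ox = clamp(int(round(cx - tile_size / 2.0)), slide_width)
        oy = clamp(int(round(cy - tile_size / 2.0)), slide_height)
        return [(ox, oy)]

    xs = _axis_origins(x0, x1, tile_size, stride) if bw > tile_size else \
        [clamp(int(round((x0 + x1) / 2.0 - tile_size / 2.0)), slide_width)]
    ys = _axis_origins(y0, y1, tile_size, stride) if bh > tile_size else \
        [clamp(int(round((y0 + y1) / 2.0 - tile_size / 2.0)), slide_height)]
    out = []
    for oy in ys:
        for ox in xs:
            if box(ox, oy, ox + tile_size, oy + tile_size).intersects(poly):
                out.append((ox, oy))
    return out
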