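"""Background correction and TM-domain masking for flat-mount images.

A flat-mounted anterior segment is imaged in two tracer channels (red and
blue) plus an optional brightfield channel.  Analysis is restricted to the
trabecular meshwork (TM), delineated by user-drawn polygons; everything
outside the polygons is treated as not-part-of-the-tissue and becomes NaN
downstream.  Background fluorescence is estimated from three 200 x 200 px
regions of interest (one in the central cornea, two in the sclera) and
subtracted as a per-channel scalar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import LinearRing

__all__ = [
    "FlatMountImage",
    "BackgroundROIs",
    "PolygonROI",
    "background_correct",
    "build_tm_mask",
    "load_annotations",
    "save_annotations",
]


@dataclass
class FlatMountImage:
    """Two registered tracer channels of one flat-mounted eye.

    Intensities are arbitrary fluorescence units.  ``red`` and ``blue`` must
    have identical shapes; coordinates are (row, col) with x = col, y = row.
    """

    red: np.ndarray
    blue: np.ndarray
    pixel_size_um: float
    brightfield: Optional[np.ndarray] = None
    eye_id: str = ""
    side: str = "OD"
    puncture_px: Optional[tuple[float, float]] = None  # (x, y)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        if self.red.shape != self.blue.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape} vs blue {self.blue.shape}"
            )
        if not (np.all(np.isfinite(self.red)) and np.all(np.isfinite(self.blue))):
            raise ValueError("channel intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.side not in ("OD", "OS"):
            raise ValueError(f"side must be 'OD' or 'OS', got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"red": self.red, "blue": self.blue}


@dataclass(frozen=True)
class BackgroundROIs:
    """Three square background regions: one central cornea, two sclera.

    ``corners`` are (x, y) pixel coordinates of the top-left corner of each
    square; all three squares must lie fully inside the image and must not
    overlap the TM polygons.
    """

    corners: tuple[tuple[int, int], ...]
    size_px: int = 200

    def __post_init__(self) -> None:
        if len(self.corners) != 3:
            raise ValueError(f"exactly three background ROIs required, got {len(self.corners)}")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for (x, y) in self.corners:
            if x < 0 or y < 0 or x + self.size_px > w or y + self.size_px > h:
                raise ValueError(f"background ROI at ({x}, {y}) extends outside the image")

    def extract(self, channel: np.ndarray) -> list[np.ndarray]:
        self.validate_within(channel.shape)
        s = self.size_px
        return [channel[y : y + s, x : x + s] for (x, y) in self.corners]


@dataclass(frozen=True)
class PolygonROI:
    """Simple closed polygon delineating one TM region, vertices in (x, y) px."""

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if not LinearRing(v).is_simple:
            raise ValueError(f"polygon {self.label!r} is self-intersecting")

    @property
    def area(self) -> float:
        """Shoelace area in px^2."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def background_correct(
    image: FlatMountImage,
    rois: BackgroundROIs,
    per_channel: bool = True,
) -> FlatMountImage:
    """Subtract the mean background level from each tracer channel.

    The correction for a channel is the mean of the three ROI means measured
    on that channel (``per_channel=True``, default) or the mean pooled across
    both channels (``per_channel=False``).  Values are *not* clipped at zero:
    slightly negative pixels after subtraction are legitimate noise
    excursions, and clipping them would bias the per-bin means and hence the
    channel correlation.  The applied corrections are recorded in
    ``metadata['background_red' / 'background_blue']``.
    """
    means = {
        name: float(np.mean([np.mean(r) for r in rois.extract(chan)]))
        for name, chan in image.channels.items()
    }
    if not per_channel:
        pooled = 0.5 * (means["red"] + means["blue"])
        means = {"red": pooled, "blue": pooled}
    meta = dict(image.metadata)
    meta["background_red"] = means["red"]
    meta["background_blue"] = means["blue"]
    return replace(
        image,
        red=image.red - means["red"],
        blue=image.blue - means["blue"],
        metadata=meta,
    )


def build_tm_mask(
    polygons: Sequence[PolygonROI], image_shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise the union of TM polygons into a boolean in-domain mask.

    A pixel belongs to the TM domain iff its centre — taken at the integer
    (col, row) coordinate — lies inside any polygon under the even-odd fill
    rule.  Self-intersecting polygons are rejected at construction time by
    :class:`PolygonROI`.
    """
    if len(polygons) == 0:
        raise ValueError("at least one polygon required")
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    for poly in polygons:
        v = poly.vertices
        if v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5 or v[:, 0].max() > w - 0.5 or v[:, 1].max() > h - 0.5:
            raise ValueError(f"polygon {poly.label!r} extends outside the image")
        # restrict the point-in-polygon test to the bounding box
        x0, x1 = int(np.floor(v[:, 0].min())), int(np.ceil(v[:, 0].max()))
        y0, y1 = int(np.floor(v[:, 1].min())), int(np.ceil(v[:, 1].max()))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w - 1), min(y1, h - 1)
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        path = MplPath(np.vstack([v, v[:1]]), closed=True)
        inside = path.contains_points(pts).reshape(ys.shape)
        mask[y0 : y1 + 1, x0 : x1 + 1] |= inside
    return mask


# ---------------------------------------------------------------------------
# Annotation I/O: polygons, polylines and background ROIs travel together in
# one JSON sidecar per eye.
# ---------------------------------------------------------------------------

def save_annotations(
    path: FilePath | str,
    polygons: Sequence[PolygonROI],
    polylines: Sequence,
    background: BackgroundROIs,
) -> None:
    payload = {
        "polygons": [
            {"label": p.label, "vertices": np.asarray(p.vertices).tolist()} for p in polygons
        ],
        "polylines": [
            {"label": l.label, "vertices": np.asarray(l.vertices).tolist()} for l in polylines
        ],
        "background_rois": {
            "corners": [list(c) for c in background.corners],
            "size_px": background.size_px,
        },
    }
    FilePath(path).write_text(json.dumps(payload, indent=1))


def load_annotations(path: FilePath | str):
    """Read (polygons, polylines, background ROIs) from a JSON sidecar."""
    from .straighten import Polyline  # local import avoids a cycle

    payload = json.loads(FilePath(path).read_text())
    polygons = [
        PolygonROI(vertices=np.asarray(p["vertices"]), label=p.get("label", ""))
        for p in payload["polygons"]
    ]
    polylines = [
        Polyline(vertices=np.asarray(l["vertices"]), label=l.get("label", ""))
        for l in payload["polylines"]
    ]
    b = payload["background_rois"]
    background = BackgroundROIs(
        corners=tuple(tuple(int(v) for v in c) for c in b["corners"]),
        size_px=int(b["size_px"]),
    )
    return polygons, polylines, background
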