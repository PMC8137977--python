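"""Image and lesion-mask I/O with the shared coordinate and unit conventions.

Conventions used throughout the package:

* arrays are row-major with 0-based indices ``(row, col)``;
* pixel ``(r, c)`` covers the unit square ``[c, c+1) x [r, r+1)`` in continuous
  ``(x, y)`` coordinates, so its center sits at ``(c + 0.5, r + 0.5)``;
* physical units come from a single isotropic scale ``pixel_scale_mm`` (mm per
  pixel); a 3 x 3 mm scan on a 304 x 304 grid gives ``3/304`` mm (~9.87 um).

Intensities are min-max normalized to ``[0, 1]`` on load so every downstream
parameter (Frangi scales, threshold offsets) lives on a fixed scale.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

DEFAULT_PIXEL_SCALE_MM = 3.0 / 304.0


@dataclass(frozen=True)
class EnFaceImage:
    """A 2D grayscale en face angiogram with a physical pixel scale."""

    pixels: np.ndarray
    pixel_scale_mm: float = DEFAULT_PIXEL_SCALE_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("en face image must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("en face image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]; use normalize()")
        if self.pixel_scale_mm <= 0:
            raise ValueError("pixel_scale_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LesionMask:
    """Rasterized manual lesion contour delimiting the mCNV region of interest."""

    mask: np.ndarray
    source_contour: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("lesion mask must be a non-empty 2D boolean array")
        object.__setattr__(self, "mask", m)
        if self.source_contour is not None:
            object.__setattr__(
                self, "source_contour", np.asarray(self.source_contour, dtype=float)
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    px = np.asarray(pixels, dtype=float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def load_enface_image(
    path: str | Path, pixel_scale_mm: float = DEFAULT_PIXEL_SCALE_MM
) -> EnFaceImage:
    """Load a PNG/TIFF angiogram, collapsing RGB to luminance, normalized to [0, 1].

    Parameters
    ----------
    path
        Single-channel or RGB(A) raster file.
    pixel_scale_mm
        Physical size of one pixel in mm (isotropic); defaults to the
        3 mm / 304 px convention of a 3 x 3 mm scan.
    """
    try:
        raw = iio.imread(path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:
        if raw.shape[2] >= 3:
            # ITU-R 601 luminance, as used by skimage.color.rgb2gray
            raw = raw[..., 0] * 0.2125 + raw[..., 1] * 0.7154 + raw[..., 2] * 0.0721
        else:
            raw = raw[..., 0]
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError(f"image {path!r} is not a non-empty 2D raster")
    return EnFaceImage(normalize(raw), pixel_scale_mm=pixel_scale_mm)


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float or boolean image as an 8-bit grayscale PNG/TIFF."""
    px = np.asarray(pixels)
    if px.dtype == bool:
        out = np.where(px, 255, 0).astype(np.uint8)
    else:
        out = np.clip(np.asarray(px, dtype=float), 0.0, 1.0)
        out = np.round(out * 255).astype(np.uint8)
    iio.imwrite(path, out)


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points."""
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (ys >= min(y1, y2)) & (ys < max(y1, y2))
        x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < x_at)
    return inside


def rasterize_contour(
    vertices: Sequence[Sequence[float]], shape: tuple[int, int]
) -> LesionMask:
    """Rasterize a manual lesion contour into a boolean mask.

    A pixel is foreground iff its center ``(c + 0.5, r + 0.5)`` falls inside the
    polygon under the even-odd fill rule.  Vertices are in ``(x, y)`` pixel
    coordinates and are clipped to the image bounds.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("contour needs at least 3 (x, y) vertices")
    h, w = shape
    verts = np.column_stack(
        [np.clip(verts[:, 0], 0, w), np.clip(verts[:, 1], 0, h)]
    )
    # shoelace area; ~0 means collinear/degenerate
    x, y = verts[:, 0], verts[:, 1]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 < 1e-9:
        raise ValueError("degenerate (collinear) contour encloses no area")
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    mask = _points_in_polygon(cols + 0.5, rows + 0.5, verts)
    if not mask.any():
        raise ValueError("contour rasterizes to an empty mask")
    return LesionMask(mask, source_contour=verts)


def load_contour(path: str | Path) -> np.ndarray:
    """Read polygon vertices from CSV (columns x,y) or GeoJSON-style JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        geo = json.loads(path.read_text())
        coords = geo["coordinates"] if "coordinates" in geo else geo
        ring = np.asarray(coords[0] if np.asarray(coords).ndim == 3 else coords, float)
        # drop a closing vertex that repeats the first
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        return ring
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row]
    if rows and not _is_number(rows[0][0]):
        header = [h.strip().lower() for h in rows[0]]
        xi, yi = header.index("x"), header.index("y")
        rows = rows[1:]
    else:
        xi, yi = 0, 1
    return np.asarray([[float(r[xi]), float(r[yi])] for r in rows], dtype=float)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
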