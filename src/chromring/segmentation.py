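"""Nucleus segmentation: thresholding, masking, and boundary extraction.

The segmentation channel (the DNA stain, by convention) yields one closed
boundary polygon per z-slice; that boundary is then applied synchronously to
every channel downstream, so DNA and marker are always measured over the same
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
import shapely
from skimage import measure
from skimage.filters import threshold_otsu

from .image_io import MultiChannelImage, rasterize_polygon

__all__ = [
    "ThresholdSpec",
    "BinaryMask",
    "PolygonROI",
    "NucleusBoundary",
    "FilterCriteria",
    "compute_threshold",
    "threshold_foreground",
    "make_mask",
    "extract_contour",
    "segment_nucleus",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize a plane.

    ``default_isodata`` is the iterative Ridler–Calvard scheme most imaging
    software ships as its default automatic threshold; it iterates
    ``t <- (mean(I < t) + mean(I >= t)) / 2`` to a fixed point.  ``manual``
    selects the closed intensity window ``[manual_min, manual_max]``.
    """

    method: str = "default_isodata"
    manual_min: float | None = None
    manual_max: float | None = None

    _METHODS = ("default_isodata", "otsu", "mean", "manual")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "manual":
            if self.manual_min is None or self.manual_max is None:
                raise ValueError("manual thresholding needs manual_min and manual_max")
            if not (self.manual_min < self.manual_max):
                raise ValueError("manual_min must be < manual_max")


@dataclass
class BinaryMask:
    mask: np.ndarray  # boolean (H, W)
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


class PolygonROI:
    """A simple closed polygon in pixel coordinates, vertices as (x, y)."""

    def __init__(self, vertices: np.ndarray):
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs an (N>=3, 2) vertex array")
        # drop an explicitly repeated closing vertex
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if verts.shape[0] < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        geom = shapely.polygons(verts)
        if not geom.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if geom.area <= 0:
            raise ValueError("polygon has zero area")
        self.vertices = verts
        self._geom = geom

    @property
    def geometry(self) -> shapely.Polygon:
        return self._geom

    @property
    def area(self) -> float:
        return self._geom.area

    def rasterize(self, height: int, width: int) -> np.ndarray:
        return rasterize_polygon(self.vertices, height, width)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PolygonROI({len(self.vertices)} vertices, area={self.area:.1f})"


@dataclass
class NucleusBoundary:
    """Per-slice boundary polygons for one nucleus."""

    per_slice: dict[int, PolygonROI]
    channel_used: str

    def __post_init__(self) -> None:
        if not self.per_slice:
            raise ValueError("boundary must cover at least one slice")
        idx = sorted(self.per_slice)
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"slice indices must be contiguous, got {idx}")

    @property
    def slice_indices(self) -> list[int]:
        return sorted(self.per_slice)


@dataclass(frozen=True)
class FilterCriteria:
    """Optional per-slice acceptance windows on area (µm²) and mean intensity."""

    min_area: float | None = None
    max_area: float | None = None
    min_mean_intensity: float | None = None
    max_mean_intensity: float | None = None

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.min_area, self.max_area, "area"),
            (self.min_mean_intensity, self.max_mean_intensity, "mean intensity"),
        ):
            if lo is not None and hi is not None and not (lo < hi):
                raise ValueError(f"{what} window is empty: [{lo}, {hi}]")

    def accepts(self, area_um2: float, mean_intensity: float) -> bool:
        if self.min_area is not None and area_um2 < self.min_area:
            return False
        if self.max_area is not None and area_um2 > self.max_area:
            return False
        if self.min_mean_intensity is not None and mean_intensity < self.min_mean_intensity:
            return False
        if self.max_mean_intensity is not None and mean_intensity > self.max_mean_intensity:
            return False
        return True


def compute_threshold(plane: np.ndarray, spec: ThresholdSpec) -> float:
    """Scalar threshold for ``plane``; foreground is ``plane >= t``.

    The IsoData iteration runs on the raw pixel values rather than a binned
    histogram, so translating every intensity by a constant translates the
    threshold by exactly that constant.
    """
    values = np.asarray(plane, dtype=np.float64).ravel()
    if spec.method == "manual":
        return float(spec.manual_min)
    if values.size == 0:
        raise ValueError("empty plane")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError(f"constant plane (value {vmin}); automatic threshold undefined")
    if spec.method == "mean":
        return float(values.mean())
    if spec.method == "otsu":
        return float(threshold_otsu(values))
    # default_isodata: Ridler–Calvard fixed point
    t = float(values.mean())
    for _ in range(500):
        below = values[values < t]
        above = values[values >= t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < 1e-12 * max(1.0, abs(t)):
            t = t_new
            break
        t = t_new
    return float(t)


def threshold_foreground(plane: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    if spec.method == "manual":
        return (plane >= spec.manual_min) & (plane <= spec.manual_max)
    t = compute_threshold(plane, spec)
    return plane >= t


def make_mask(
    plane: np.ndarray,
    spec: ThresholdSpec,
    seed: tuple[int, int] | None = None,
    slice_index: int = 0,
    threshold_value: float | None = None,
) -> BinaryMask:
    """Binarize, fill interior holes, and keep one 8-connected component.

    The component containing ``seed`` (given as ``(x, y)``) is kept; without a
    seed the largest component wins.  ``threshold_value`` overrides the
    per-plane automatic threshold (used to apply one stack-wide threshold).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if threshold_value is not None and spec.method != "manual":
        fg = plane >= threshold_value
    else:
        fg = threshold_foreground(plane, spec)
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg, connectivity=2)
    if seed is not None:
        x, y = int(seed[0]), int(seed[1])
        if not (0 <= y < fg.shape[0] and 0 <= x < fg.shape[1]):
            raise ValueError(f"seed {seed} outside the image")
        lbl = labels[y, x]
        if lbl == 0:
            raise ValueError(f"seed {seed} is not on a foreground component")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lbl = int(counts.argmax())
    return BinaryMask(labels == lbl, slice_index=slice_index)


def _simplify_collinear(verts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop vertices lying on the segment joining their neighbours."""
    n = len(verts)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        p, q, r = verts[i - 1], verts[i], verts[(i + 1) % n]
        cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        if abs(cross) < tol:
            keep[i] = False
    out = verts[keep]
    return out if len(out) >= 3 else verts


def extract_contour(mask: BinaryMask | np.ndarray) -> PolygonROI:
    """Closed outer contour of a single-component mask via marching squares.

    The contour is traced at level 0.5 on the zero-padded binary mask and
    expressed in pixel-centre coordinates, so a mask of N pixels yields a
    polygon of area close to N (corner cells are bevelled by the marching
    squares convention).
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    n_comp = measure.label(m, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask must have exactly one connected component, got {n_comp}")
    padded = np.pad(m.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=len)
    # (row, col) in padded index space -> (x, y) pixel-centre coordinates
    xy = np.column_stack([outer[:, 1] - 1 + 0.5, outer[:, 0] - 1 + 0.5])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return PolygonROI(_simplify_collinear(xy))


def segment_nucleus(
    image: MultiChannelImage,
    channel: str = "dna",
    spec: ThresholdSpec | None = None,
    seed: tuple[int, int] | None = None,
    criteria: FilterCriteria | None = None,
    per_slice_threshold: bool = False,
) -> NucleusBoundary:
    """Segment the nucleus on ``channel`` and return its per-slice boundary.

    By default one threshold is computed on the maximum-intensity projection
    and applied to every slice, which keeps region boundaries stable along z;
    ``per_slice_threshold=True`` re-thresholds each slice independently.
    Slices with empty masks or failing ``criteria`` are dropped, and the
    longest contiguous run of valid slices is kept.
    """
    spec = spec or ThresholdSpec()
    criteria = criteria or FilterCriteria()
    stack = image.channel(channel)
    shared_t: Optional[float] = None
    if not per_slice_threshold and spec.method != "manual":
        shared_t = compute_threshold(stack.max(axis=0), spec)

    valid: dict[int, PolygonROI] = {}
    for z in range(image.n_slices):
        plane = stack[z]
        try:
            bm = make_mask(plane, spec, seed=seed, slice_index=z, threshold_value=shared_t)
            poly = extract_contour(bm)
        except ValueError:
            continue
        area_um2 = bm.count * image.calibration.pixel_area
        mean_int = float(plane[bm.mask].mean())
        if criteria.accepts(area_um2, mean_int):
            valid[z] = poly

    if not valid:
        raise ValueError(f"no slice yields a valid nucleus boundary on channel {channel!r}")
    run = _longest_contiguous_run(sorted(valid))
    return NucleusBoundary({z: valid[z] for z in run}, channel_used=channel)


def _longest_contiguous_run(indices: list[int]) -> list[int]:
    best, current = [], []
    for z in indices:
        if current and z == current[-1] + 1:
            current.append(z)
        else:
            current = [z]
        if len(current) > len(best):
            best = current
    return best
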