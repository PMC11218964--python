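"""Calibrated multichannel image I/O, ROI persistence and the clear-outside step.

Coordinate convention used throughout the package: 0-based pixel indices with
``x`` the column and ``y`` the row; the centre of pixel ``(x, y)`` sits at
continuous coordinates ``(x + 0.5, y + 0.5)``.  A pixel belongs to a polygon
iff its centre is inside the polygon or on its boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "MultiChannelImage",
    "RectROI",
    "read_image",
    "write_image",
    "clear_outside",
    "rasterize_polygon",
    "save_roi",
    "load_roi",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class Calibration:
    """Physical pixel/voxel size. ``voxel_depth`` is ignored for 2D images."""

    pixel_width: float = 1.0  # µm / px
    pixel_height: float = 1.0  # µm / px
    voxel_depth: float = 1.0  # µm / z-slice

    def __post_init__(self) -> None:
        for name in ("pixel_width", "pixel_height", "voxel_depth"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_width * self.pixel_height


@dataclass
class MultiChannelImage:
    """A calibrated 2D plane or 3D z-stack with named channels.

    Every channel is stored as a ``(n_slices, height, width)`` float array;
    2D images have ``n_slices == 1``.  Dimensionality is derived from the
    slice count: a one-slice stack *is* a 2D image.
    """

    channels: dict[str, np.ndarray]
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must have at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        normalized = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim == 2:
                a = a[None, :, :]
            if a.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2D or 3D, got shape {shapes[name]}")
            if np.any(a < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            normalized[name] = a
        ref = next(iter(normalized.values())).shape
        for name, a in normalized.items():
            if a.shape != ref:
                raise ValueError(f"channel shapes differ: {name!r} {a.shape} vs {ref}")
        self.channels = normalized

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    @property
    def is_3d(self) -> bool:
        return self.n_slices > 1

    @property
    def dimensionality(self) -> str:
        return "3D" if self.is_3d else "2D"

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}") from None

    def copy(self) -> "MultiChannelImage":
        return MultiChannelImage(
            {k: v.copy() for k, v in self.channels.items()}, self.calibration
        )


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle in pixel indices, half-open on the max side."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate rectangle {self}")

    def validate_bounds(self, height: int, width: int) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.x1 > width or self.y1 > height:
            raise ValueError(
                f"ROI {self} outside image bounds (height={height}, width={width})"
            )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)


def read_image(
    path: str | Path,
    channel_map: Mapping[str, int],
    calibration: Calibration | None = None,
) -> MultiChannelImage:
    """Read a single- or multi-page TIFF into named channels.

    Accepted array layouts: ``(H, W)`` single-channel plane, ``(C, H, W)``
    multichannel plane (when the map names more than one channel) or
    single-channel stack (one-entry map), and ``(Z, C, H, W)`` multichannel
    stack.  Calibration is taken from the argument; TIFF resolution tags are
    deliberately not trusted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not channel_map:
        raise ValueError("channel_map must name at least one channel")
    data = np.asarray(tifffile.imread(path))
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"non-numeric pixel data of dtype {data.dtype}")

    if data.ndim == 2:
        data = data[None, None, :, :]  # (Z=1, C=1, H, W)
    elif data.ndim == 3:
        if len(channel_map) > 1:
            data = data[None, :, :, :]  # (Z=1, C, H, W)
        else:
            data = data[:, None, :, :]  # (Z, C=1, H, W)
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}")

    n_channels = data.shape[1]
    channels = {}
    for name, idx in channel_map.items():
        if not (0 <= idx < n_channels):
            raise IndexError(
                f"channel index {idx} for {name!r} out of range (file has {n_channels})"
            )
        channels[name] = data[:, idx, :, :]
    return MultiChannelImage(channels, calibration or Calibration())


def write_image(path: str | Path, image: MultiChannelImage) -> None:
    """Write as a ``(Z, C, H, W)`` float32 TIFF, channel order sorted by name."""
    names = sorted(image.channels)
    stack = np.stack([image.channels[n] for n in names], axis=1).astype(np.float32)
    tifffile.imwrite(path, stack)


def rasterize_polygon(
    vertices: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside or on the polygon."""
    import shapely

    verts = np.asarray(vertices, dtype=float)
    if verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = shapely.polygons(verts)
    if poly.area <= 0:
        raise ValueError("degenerate polygon with zero area")
    minx, miny, maxx, maxy = shapely.bounds(poly)
    x_lo = max(int(np.floor(minx - 0.5)), 0)
    x_hi = min(int(np.ceil(maxx + 0.5)), width)
    y_lo = max(int(np.floor(miny - 0.5)), 0)
    y_hi = min(int(np.ceil(maxy + 0.5)), height)
    mask = np.zeros((height, width), dtype=bool)
    if x_lo >= x_hi or y_lo >= y_hi:
        return mask
    xs = np.arange(x_lo, x_hi) + 0.5
    ys = np.arange(y_lo, y_hi) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel())
    mask[y_lo:y_hi, x_lo:x_hi] = inside.reshape(y_hi - y_lo, x_hi - x_lo)
    return mask


def clear_outside(
    image: MultiChannelImage,
    roi,
    slice_index: int | str = "all",
) -> MultiChannelImage:
    """Zero every pixel whose centre lies outside the polygon, on all channels.

    ``roi`` is a :class:`~chromring.segmentation.PolygonROI` or an ``(N, 2)``
    vertex array.  ``slice_index`` restricts the operation to one z-slice;
    ``"all"`` (default) applies it to the whole stack.
    """
    vertices = np.asarray(getattr(roi, "vertices", roi), dtype=float)
    n_slices, h, w = image.shape
    keep = rasterize_polygon(vertices, h, w)
    out = image.copy()
    if slice_index == "all":
        sel = range(n_slices)
    else:
        if not (0 <= int(slice_index) < n_slices):
            raise IndexError(f"slice {slice_index} out of range for {n_slices} slices")
        sel = [int(slice_index)]
    for arr in out.channels.values():
        for z in sel:
            arr[z][~keep] = 0.0
    return out


# --- ROI persistence (documented JSON schema; ImageJ .roi binaries are not parsed) ---

def save_roi(path: str | Path, roi) -> None:
    """Persist a rectangle or polygon ROI as JSON.

    Schema: ``{"type": "rect", "bounds": [x0, y0, x1, y1]}`` or
    ``{"type": "polygon", "vertices": [[x, y], ...]}``.
    """
    if isinstance(roi, RectROI):
        obj = {"type": "rect", "bounds": [roi.x0, roi.y0, roi.x1, roi.y1]}
    else:
        verts = np.asarray(getattr(roi, "vertices", roi), dtype=float)
        obj = {"type": "polygon", "vertices": verts.tolist()}
    Path(path).write_text(json.dumps(obj))


def load_roi(path: str | Path):
    from .segmentation import PolygonROI

    obj = json.loads(Path(path).read_text())
    kind = obj.get("type")
    if kind == "rect":
        return RectROI(*(int(v) for v in obj["bounds"]))
    if kind == "polygon":
        return PolygonROI(np.asarray(obj["vertices"], dtype=float))
    raise ValueError(f"unknown ROI type {kind!r} in {path}")


def write_results(records: Sequence[Mapping], path: str | Path) -> pd.DataFrame:
    """Write per-nucleus result records (see :mod:`chromring.pipeline`) to CSV."""
    if len(records) == 0:
        raise ValueError("empty result collection")
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
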