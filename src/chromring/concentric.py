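"""Concentric region construction by centroid-anchored polygon shrinking.

Each inner region is the nucleus boundary polygon scaled toward its own area
centroid: ``v_new = centroid + s * (v - centroid)``.  With a reduction
fraction ``r`` the scale is ``s = sqrt(1 - r)`` in ``area`` mode — so the
shrunken region keeps exactly ``(1 - r)`` of the full area and the bands
between successive regions are iso-area — or ``s = 1 - r`` in ``linear``
mode, where the *coordinates* shrink by ``r``.  The classic trisection uses
reductions ``[0.3333, 0.6666]``: an intermediate region holding 66.66% of the
full area and a central region holding 33.33%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .segmentation import NucleusBoundary, PolygonROI

__all__ = [
    "ShrinkSpec",
    "Centroid",
    "RegionSet",
    "polygon_centroid",
    "shrink_polygon",
    "build_region_set",
    "DEFAULT_REDUCTIONS",
]

DEFAULT_REDUCTIONS = (0.3333, 0.6666)

#: fewest pixels a rasterized region may hold and still be measurable
MIN_REGION_PIXELS = 10


@dataclass(frozen=True)
class ShrinkSpec:
    reductions: tuple[float, ...] = DEFAULT_REDUCTIONS
    mode: str = "area"

    def __post_init__(self) -> None:
        object.__setattr__(self, "reductions", tuple(float(r) for r in self.reductions))
        if self.mode not in ("area", "linear"):
            raise ValueError(f"mode must be 'area' or 'linear', got {self.mode!r}")
        for r in self.reductions:
            if not (0.0 < r < 1.0):
                raise ValueError(f"reduction {r} outside (0, 1)")
        if any(b <= a for a, b in zip(self.reductions, self.reductions[1:])):
            raise ValueError(f"reductions must be strictly increasing: {self.reductions}")

    def scale(self, reduction: float) -> float:
        return float(np.sqrt(1.0 - reduction)) if self.mode == "area" else 1.0 - reduction

    @property
    def labels(self) -> list[str]:
        n = len(self.reductions)
        if n == 0:
            return ["full"]
        if n == 2:
            return ["full", "intermediate", "center"]
        return ["full"] + [f"region_{i}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class Centroid:
    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class RegionSet:
    """Nested raster masks per slice, outermost first.

    ``per_slice[z]`` is a list of boolean masks ordered ``[full, ...inner]``;
    on every slice each mask is a subset of its parent and pixel counts are
    strictly decreasing.
    """

    per_slice: dict[int, list[np.ndarray]]
    labels: list[str]
    spec: ShrinkSpec = field(default_factory=ShrinkSpec)

    def __post_init__(self) -> None:
        for z, masks in self.per_slice.items():
            if len(masks) != len(self.labels):
                raise ValueError(f"slice {z}: {len(masks)} masks for {len(self.labels)} labels")
            for outer, inner in zip(masks, masks[1:]):
                if np.any(inner & ~outer):
                    raise ValueError(f"slice {z}: regions are not nested")
                if inner.sum() >= outer.sum():
                    raise ValueError(f"slice {z}: region pixel counts not strictly decreasing")

    @property
    def slice_indices(self) -> list[int]:
        return sorted(self.per_slice)

    def counts(self, label: str) -> int:
        i = self.labels.index(label)
        return int(sum(masks[i].sum() for masks in self.per_slice.values()))

    def label_image(self, z: int, shape: tuple[int, int]) -> np.ndarray:
        """QC image: 0 = background, 1 = outermost band, ..., K = innermost region."""
        out = np.zeros(shape, dtype=np.uint8)
        for level, mask in enumerate(self.per_slice[z], start=1):
            out[mask] = level
        return out


def polygon_centroid(poly: PolygonROI) -> Centroid:
    """Uniform-density area centroid (the shoelace first-moment formula)."""
    c = poly.geometry.centroid
    return Centroid(float(c.x), float(c.y))


def shrink_polygon(
    poly: PolygonROI,
    centroid: Centroid | None = None,
    reduction: float = 0.3333,
    mode: str = "area",
) -> PolygonROI:
    """Scale the polygon about the centroid by the reduction's similarity factor.

    The output area is exactly ``s**2`` times the input area, with
    ``s = sqrt(1 - reduction)`` (area mode) or ``1 - reduction`` (linear mode).
    """
    if not (0.0 < reduction < 1.0):
        raise ValueError(f"reduction {reduction} outside (0, 1)")
    if mode not in ("area", "linear"):
        raise ValueError(f"mode must be 'area' or 'linear', got {mode!r}")
    c = (centroid or polygon_centroid(poly)).as_array()
    s = float(np.sqrt(1.0 - reduction)) if mode == "area" else 1.0 - reduction
    return PolygonROI(c + s * (poly.vertices - c))


def build_region_set(boundary: NucleusBoundary, spec: ShrinkSpec | None = None,
                     shape: tuple[int, int] | None = None) -> RegionSet:
    """Rasterize the full boundary and its shrunken copies on every slice.

    Shrinking is per-slice about each slice's own centroid.  Nesting is
    enforced by intersecting each raster mask with its parent, which guards
    against pathological non-star-shaped boundaries; for convex or
    star-shaped nuclei the intersection is a no-op.
    """
    spec = spec or ShrinkSpec()
    if shape is None:
        # tight frame covering every polygon
        maxx = max(p.vertices[:, 0].max() for p in boundary.per_slice.values())
        maxy = max(p.vertices[:, 1].max() for p in boundary.per_slice.values())
        shape = (int(np.ceil(maxy)) + 2, int(np.ceil(maxx)) + 2)
    h, w = shape

    per_slice: dict[int, list[np.ndarray]] = {}
    for z, poly in boundary.per_slice.items():
        centroid = polygon_centroid(poly)
        masks = [poly.rasterize(h, w)]
        for r in spec.reductions:
            inner_poly = shrink_polygon(poly, centroid, r, spec.mode)
            inner = inner_poly.rasterize(h, w) & masks[-1]
            if inner.sum() < MIN_REGION_PIXELS:
                raise ValueError(
                    f"slice {z}: region at reduction {r} rasterizes to "
                    f"{int(inner.sum())} px (< {MIN_REGION_PIXELS}); too small to measure"
                )
            masks.append(inner)
        per_slice[z] = masks
    return RegionSet(per_slice, spec.labels, spec)
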