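"""Background normalization, integrated densities, and the ten concentric ratios.

The background level is estimated from a user-supplied rectangle in a
nucleus-free area.  Its per-slice mean intensities give the normalization
factor

    NF = (sum of per-slice background means / n_slices) * voxel_depth   (3D)
    NF =  background mean                                               (2D)

and each region's integrated density (sum of intensities, times voxel depth
in 3D) is corrected by the background expected over the same number of
pixels/voxels:

    normalized = IntDen - NF * count.

Concentric *bands* telescope out of the nested regions —
peripheral = full - intermediate, intermediate band = intermediate - center,
central = center — and the ten ratios (A/B, A1/B, A2/B, A3/B, A1/A, A2/A,
A3/A, B1/B, B2/B, B3/B) compare marker (A) and DNA (B) signal across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concentric import RegionSet
from .image_io import Calibration, MultiChannelImage, RectROI

__all__ = [
    "BackgroundEstimate",
    "RegionMeasurement",
    "RatioTable",
    "estimate_background",
    "measure_regions",
    "band_decompose",
    "compute_ratios",
]


@dataclass(frozen=True)
class BackgroundEstimate:
    per_slice_mean: tuple[float, ...]
    nf: float  # intensity units; carries the voxel-depth factor in 3D

    @property
    def n_slices(self) -> int:
        return len(self.per_slice_mean)


@dataclass(frozen=True)
class RegionMeasurement:
    label: str
    channel: str
    count: int  # pixels (2D) or voxels (3D)
    intden: float  # sum of intensities, x voxel_depth in 3D
    normalized: float  # intden - nf * count

    @property
    def below_background(self) -> bool:
        """Region dimmer than the background estimate (negative after correction)."""
        return self.normalized < 0


_RATIO_FIELDS = (
    "a_over_b",
    "a1_over_b",
    "a2_over_b",
    "a3_over_b",
    "a1_over_a",
    "a2_over_a",
    "a3_over_a",
    "b1_over_b",
    "b2_over_b",
    "b3_over_b",
)


@dataclass(frozen=True)
class RatioTable:
    """The ten concentric ratios as raw fractions; ``percent()`` gives x100 views."""

    a_over_b: float
    a1_over_b: float
    a2_over_b: float
    a3_over_b: float
    a1_over_a: float
    a2_over_a: float
    a3_over_a: float
    b1_over_b: float
    b2_over_b: float
    b3_over_b: float
    negative_bands: tuple[str, ...] = field(default=(), compare=False)

    names = _RATIO_FIELDS

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _RATIO_FIELDS}

    def percent(self) -> dict[str, float]:
        return {f"{name}_pct": 100.0 * getattr(self, name) for name in _RATIO_FIELDS}


def estimate_background(
    image: MultiChannelImage, channel: str, bg_roi: RectROI
) -> BackgroundEstimate:
    """Mean background intensity per slice and the channel's normalization factor."""
    stack = image.channel(channel)
    n_slices, h, w = stack.shape
    bg_roi.validate_bounds(h, w)
    ys, xs = bg_roi.slices()
    means = tuple(float(stack[z, ys, xs].mean()) for z in range(n_slices))
    nf = float(np.sum(means)) / n_slices
    if image.is_3d:
        nf *= image.calibration.voxel_depth
    return BackgroundEstimate(means, nf)


def measure_regions(
    image: MultiChannelImage,
    channel: str,
    regions: RegionSet,
    background: BackgroundEstimate | None = None,
) -> dict[str, RegionMeasurement]:
    """Integrated density and background-corrected intensity per concentric region.

    Sums run over every slice the region set covers; in 3D the integrated
    density carries the voxel-depth factor, matching the depth factor inside
    the normalization factor so the correction stays per-voxel exact.
    """
    stack = image.channel(channel)
    nf = background.nf if background is not None else 0.0
    depth = image.calibration.voxel_depth if image.is_3d else 1.0
    out: dict[str, RegionMeasurement] = {}
    for i, label in enumerate(regions.labels):
        count = 0
        raw_sum = 0.0
        for z, masks in regions.per_slice.items():
            m = masks[i]
            count += int(m.sum())
            raw_sum += float(stack[z][m].sum())
        if count == 0:
            raise ValueError(f"region {label!r} is empty")
        intden = raw_sum * depth
        out[label] = RegionMeasurement(
            label=label,
            channel=channel,
            count=count,
            intden=intden,
            normalized=intden - nf * count,
        )
    return out


def band_decompose(
    full: RegionMeasurement,
    intermediate: RegionMeasurement,
    center: RegionMeasurement,
) -> tuple[float, float, float]:
    """Telescope nested-region values into (peripheral, intermediate, central) bands.

    x1 = full - intermediate, x2 = intermediate - center, x3 = center;
    the bands sum back to the full value exactly.
    """
    if not (full.channel == intermediate.channel == center.channel):
        raise ValueError("band decomposition mixes channels")
    x1 = full.normalized - intermediate.normalized
    x2 = intermediate.normalized - center.normalized
    x3 = center.normalized
    return (x1, x2, x3)


def compute_ratios(
    bands_a: tuple[float, float, float],
    total_a: float,
    bands_b: tuple[float, float, float],
    total_b: float,
) -> RatioTable:
    """The ten concentric ratios from per-channel band values and totals."""
    if not (total_a > 0):
        raise ValueError(f"non-positive total for marker channel A: {total_a}")
    if not (total_b > 0):
        raise ValueError(f"non-positive total for DNA channel B: {total_b}")
    a1, a2, a3 = bands_a
    b1, b2, b3 = bands_b
    flagged = tuple(
        name
        for name, v in zip(("a1", "a2", "a3", "b1", "b2", "b3"), (a1, a2, a3, b1, b2, b3))
        if v < 0
    )
    return RatioTable(
        a_over_b=total_a / total_b,
        a1_over_b=a1 / total_b,
        a2_over_b=a2 / total_b,
        a3_over_b=a3 / total_b,
        a1_over_a=a1 / total_a,
        a2_over_a=a2 / total_a,
        a3_over_a=a3 / total_a,
        b1_over_b=b1 / total_b,
        b2_over_b=b2 / total_b,
        b3_over_b=b3 / total_b,
        negative_bands=flagged,
    )
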