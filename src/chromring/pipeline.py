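"""End-to-end per-nucleus analysis: segment -> concentric regions -> ratios."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .concentric import RegionSet, ShrinkSpec, build_region_set
from .image_io import MultiChannelImage, RectROI
from .quantify import (
    BackgroundEstimate,
    RatioTable,
    RegionMeasurement,
    compute_ratios,
    estimate_background,
    measure_regions,
)
from .segmentation import (
    FilterCriteria,
    NucleusBoundary,
    ThresholdSpec,
    compute_threshold,
    segment_nucleus,
)

__all__ = ["AnalysisResult", "analyze_image"]


@dataclass
class AnalysisResult:
    """Everything measured for one nucleus, ready to flatten into a CSV row."""

    ratios: Optional[RatioTable]
    bands: dict[str, tuple[float, ...]]  # channel -> telescoped band values
    totals: dict[str, float]  # channel -> normalized full-region value
    measurements: dict[str, dict[str, RegionMeasurement]]  # channel -> label -> m
    backgrounds: dict[str, Optional[BackgroundEstimate]]
    boundary: NucleusBoundary
    regions: RegionSet
    threshold_method: str
    threshold_value: Optional[float]
    normalized: bool
    metadata: dict = field(default_factory=dict)

    def to_record(self, image_name: str = "", nucleus_id: int = 0) -> dict:
        spec = self.regions.spec
        rec: dict = {
            "image": image_name,
            "nucleus": nucleus_id,
            "mode": "3D" if len(self.regions.per_slice) > 1 else "2D",
            "n_slices": len(self.regions.per_slice),
            "shrink_mode": spec.mode,
            "reductions": ";".join(f"{r:g}" for r in spec.reductions),
            "threshold_method": self.threshold_method,
            "threshold_value": self.threshold_value,
            "normalized": self.normalized,
        }
        for ch, bg in self.backgrounds.items():
            rec[f"nf_{ch}"] = bg.nf if bg is not None else 0.0
        first = next(iter(self.measurements.values()))
        for label in self.regions.labels:
            rec[f"count_{label}"] = first[label].count
        for ch, ms in self.measurements.items():
            for label, m in ms.items():
                rec[f"intden_{ch}_{label}"] = m.intden
                rec[f"norm_{ch}_{label}"] = m.normalized
        if self.ratios is not None:
            rec.update(self.ratios.as_dict())
            rec.update(self.ratios.percent())
            rec["negative_bands"] = ";".join(self.ratios.negative_bands)
        else:
            for ch in self.bands:
                for i, v in enumerate(self.bands[ch], start=1):
                    rec[f"band{i}_{ch}"] = v
                    rec[f"band{i}_over_total_{ch}"] = v / self.totals[ch]
        return rec


def analyze_image(
    image: MultiChannelImage,
    dna: str = "dna",
    marker: str = "marker",
    threshold: ThresholdSpec | None = None,
    shrink: ShrinkSpec | None = None,
    bg_roi: RectROI | None = None,
    normalize: bool = True,
    seed_point: tuple[int, int] | None = None,
    criteria: FilterCriteria | None = None,
    per_slice_threshold: bool = False,
    segmentation_channel: str | None = None,
) -> AnalysisResult:
    """Run the full concentric analysis on one nucleus.

    Segmentation runs on the DNA channel by default and the boundary is
    applied to both channels.  With ``normalize=True`` a background rectangle
    is mandatory; pass ``normalize=False`` to work with raw integrated
    densities (sensitivity checks only).
    """
    threshold = threshold or ThresholdSpec()
    shrink = shrink or ShrinkSpec()
    if normalize and bg_roi is None:
        raise ValueError(
            "normalization requires a background ROI; supply bg_roi or pass normalize=False"
        )
    seg_channel = segmentation_channel or dna
    boundary = segment_nucleus(
        image,
        channel=seg_channel,
        spec=threshold,
        seed=seed_point,
        criteria=criteria,
        per_slice_threshold=per_slice_threshold,
    )
    h, w = image.shape[1:]
    regions = build_region_set(boundary, shrink, shape=(h, w))

    t_value: Optional[float] = None
    if threshold.method != "manual":
        stack = image.channel(seg_channel)
        t_value = compute_threshold(
            stack.max(axis=0) if not per_slice_threshold else stack[boundary.slice_indices[0]],
            threshold,
        )

    backgrounds: dict[str, Optional[BackgroundEstimate]] = {}
    measurements: dict[str, dict[str, RegionMeasurement]] = {}
    bands: dict[str, tuple[float, ...]] = {}
    totals: dict[str, float] = {}
    for ch in (dna, marker):
        bg = estimate_background(image, ch, bg_roi) if normalize else None
        backgrounds[ch] = bg
        ms = measure_regions(image, ch, regions, background=bg)
        measurements[ch] = ms
        ordered = [ms[label].normalized for label in regions.labels]
        # telescoping bands: outer minus next-inner, innermost region as-is
        bands[ch] = tuple(
            outer - inner for outer, inner in zip(ordered, ordered[1:])
        ) + (ordered[-1],)
        totals[ch] = ordered[0]

    ratios: Optional[RatioTable] = None
    if len(regions.labels) == 3:
        ratios = compute_ratios(bands[marker], totals[marker], bands[dna], totals[dna])

    return AnalysisResult(
        ratios=ratios,
        bands=bands,
        totals=totals,
        measurements=measurements,
        backgrounds=backgrounds,
        boundary=boundary,
        regions=regions,
        threshold_method=threshold.method,
        threshold_value=t_value,
        normalized=normalize,
    )
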