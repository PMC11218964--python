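import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromring as cr
from chromring.concentric import ShrinkSpec, build_region_set
from chromring.segmentation import NucleusBoundary, PolygonROI

from conftest import random_convex_polygon


def shoelace_centroid(verts):
    """Closed-form area centroid of a simple polygon (independent oracle)."""
    v = np.asarray(verts, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return cx, cy


class TestPolygonCentroid:
    @pytest.mark.parametrize(
        "verts, expected",
        [
            ([(0, 0), (4, 0), (4, 4), (0, 4)], (2, 2)),
            ([(0, 0), (3, 0), (0, 3)], (1, 1)),
            # L-shaped hexagon: two unit squares, area-weighted mean of centroids
            ([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)], (5 / 6, 5 / 6)),
        ],
    )
    def test_known_shapes(self, verts, expected):
        c = cr.polygon_centroid(PolygonROI(verts))
        assert (c.x, c.y) == pytest.approx(expected, abs=1e-12)
        assert shoelace_centroid(verts) == pytest.approx(expected, abs=1e-12)

    def test_matches_shoelace_on_random_polygon(self):
        poly = random_convex_polygon(np.random.default_rng(1))
        c = cr.polygon_centroid(poly)
        assert (c.x, c.y) == pytest.approx(shoelace_centroid(poly.vertices), abs=1e-9)


class TestShrinkPolygon:
    def test_linear_halving(self):
        sq = PolygonROI([(0, 0), (1, 0), (1, 1), (0, 1)])
        out = cr.shrink_polygon(sq, reduction=0.5, mode="linear")
        np.testing.assert_allclose(
            out.vertices, [(0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75)]
        )
        assert out.area == pytest.approx(0.25 * sq.area, abs=1e-12)

    def test_area_mode_exact_fraction(self):
        poly = random_convex_polygon(np.random.default_rng(2))
        out = cr.shrink_polygon(poly, reduction=0.3333, mode="area")
        assert out.area / poly.area == pytest.approx(1 - 0.3333, abs=1e-12)

    def test_area_mode_hand_example(self):
        sq = PolygonROI([(0, 0), (2, 0), (2, 2), (0, 2)])
        out = cr.shrink_polygon(sq, reduction=0.75, mode="area")  # s = 0.5
        np.testing.assert_allclose(
            out.vertices, [(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)], atol=1e-12
        )
        assert out.area == pytest.approx(1.0, abs=1e-12)

    def test_reduction_bounds(self):
        sq = PolygonROI([(0, 0), (2, 0), (2, 2), (0, 2)])
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                cr.shrink_polygon(sq, reduction=bad)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 1000),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        angle=st.floats(0, 2 * np.pi),
        reduction=st.floats(0.05, 0.95),
    )
    def test_commutes_with_rigid_motion(self, seed, dx, dy, angle, reduction):
        """Shrinking is a similarity: it commutes with translation and rotation."""
        poly = random_convex_polygon(np.random.default_rng(seed))
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])

        def transform(verts):
            return verts @ rot.T + (dx, dy)

        a = cr.shrink_polygon(PolygonROI(transform(poly.vertices)), reduction=reduction)
        b = transform(cr.shrink_polygon(poly, reduction=reduction).vertices)
        np.testing.assert_allclose(a.vertices, b, atol=1e-8)


class TestShrinkSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ShrinkSpec(reductions=(0.6, 0.3))
        with pytest.raises(ValueError):
            ShrinkSpec(reductions=(0.5,), mode="radial")
        with pytest.raises(ValueError):
            ShrinkSpec(reductions=(0.0, 0.5))

    def test_labels(self):
        assert ShrinkSpec(()).labels == ["full"]
        assert ShrinkSpec().labels == ["full", "intermediate", "center"]
        assert ShrinkSpec((0.25, 0.5, 0.75)).labels == [
            "full", "region_1", "region_2", "region_3",
        ]


def _disk_boundary(radius, frame):
    spec = cr.SyntheticSpec(radius_px=radius, frame=frame)
    image, *_ = cr.generate_nucleus(spec)
    return cr.segment_nucleus(image), image.shape[1:]


class TestBuildRegionSet:
    def test_equal_area_fractions_disk(self):
        boundary, shape = _disk_boundary(150, 384)
        regions = build_region_set(boundary, ShrinkSpec(), shape=shape)
        full = regions.counts("full")
        assert regions.counts("intermediate") / full == pytest.approx(0.6667, abs=0.005)
        assert regions.counts("center") / full == pytest.approx(0.3333, abs=0.005)

    def test_no_reductions_identity(self, uniform_disk):
        *_, result = uniform_disk
        regions = build_region_set(result.boundary, ShrinkSpec(()))
        assert regions.labels == ["full"]

    def test_nesting_and_monotone_counts(self, spheroid_stack):
        *_, result = spheroid_stack
        for masks in result.regions.per_slice.values():
            for outer, inner in zip(masks, masks[1:]):
                assert not np.any(inner & ~outer)
                assert inner.sum() < outer.sum()

    def test_spheroid_per_slice_and_voxel_fractions(self, spheroid_stack):
        *_, result = spheroid_stack
        regions = result.regions
        i_mid = regions.labels.index("intermediate")
        i_cen = regions.labels.index("center")
        for masks in regions.per_slice.values():
            full = masks[0].sum()
            assert masks[i_mid].sum() / full == pytest.approx(2 / 3, abs=0.01)
            assert masks[i_cen].sum() / full == pytest.approx(1 / 3, abs=0.01)
        total_full = regions.counts("full")
        assert regions.counts("center") / total_full == pytest.approx(1 / 3, abs=0.01)

    def test_rasterization_error_shrinks_with_resolution(self):
        errors = []
        for radius, frame in ((50, 160), (100, 256), (200, 448)):
            boundary, shape = _disk_boundary(radius, frame)
            regions = build_region_set(boundary, ShrinkSpec(), shape=shape)
            frac = regions.counts("center") / regions.counts("full")
            errors.append(abs(frac - 1 / 3))
        assert errors[-1] < 0.004
        assert errors[-1] <= errors[0] + 1e-4

    def test_too_small_region_rejected(self):
        tiny = PolygonROI([(0, 0), (6, 0), (6, 6), (0, 6)])
        boundary = NucleusBoundary({0: tiny}, channel_used="dna")
        with pytest.raises(ValueError, match="too small"):
            build_region_set(boundary, ShrinkSpec((0.3333, 0.9999)), shape=(8, 8))

    def test_four_region_generalization(self):
        boundary, shape = _disk_boundary(100, 256)
        regions = build_region_set(boundary, ShrinkSpec((0.25, 0.5, 0.75)), shape=shape)
        full = regions.counts("full")
        fracs = [regions.counts(l) / full for l in regions.labels[1:]]
        assert fracs == pytest.approx([0.75, 0.5, 0.25], abs=0.01)
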