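"""Depth frames, kernel profiles, ellipse fitting and arc projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medconn.layers import (
    LOBULA_FRAME,
    MEDULLA_FRAME,
    EllipseFitError,
    EllipseModel,
    LayerFrame,
    PlanarDepthAxis,
    arc_position,
    depth_fraction,
    fit_ellipse_lsq,
    layer_of,
    smoothed_profile,
)
from medconn.io import Point3


def slab(thickness=40.0):
    return PlanarDepthAxis(
        origin_nm=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), thickness_um=thickness
    )


class TestDepthAxis:
    def test_surface_midpoint_and_extrapolation(self):
        axis = slab(40.0)
        assert depth_fraction(Point3(0, 0, 0), axis) == 0.0
        assert depth_fraction(Point3(5, 5, 20_000), axis) == 50.0
        assert depth_fraction(Point3(0, 0, -4_000), axis) == -10.0

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            slab(0.0)
        with pytest.raises(ValueError):
            PlanarDepthAxis(np.zeros(3), np.zeros(3), 40.0)

    def test_fraction_linear_along_axis(self):
        axis = slab(40.0)
        zs = np.linspace(-5000, 45000, 11)
        pts = np.column_stack([np.zeros(11), np.zeros(11), zs])
        fr = axis.depth_fraction(pts)
        assert np.allclose(np.diff(fr), np.diff(fr)[0])


class TestLayerLookup:
    @pytest.mark.parametrize(
        "fraction, frame, expected",
        [
            (50.0, MEDULLA_FRAME, "M5"),
            (8.2, MEDULLA_FRAME, "M2"),  # boundary belongs to the deeper layer
            (0.0, MEDULLA_FRAME, "M1"),
            (100.0, MEDULLA_FRAME, "M10"),
            (-5.0, MEDULLA_FRAME, "outside"),
            (105.0, MEDULLA_FRAME, "outside"),
            (30.0, MEDULLA_FRAME, "M3"),
            (60.0, MEDULLA_FRAME, "M6"),
            (3.0, LOBULA_FRAME, "Lo1"),
            (70.0, LOBULA_FRAME, "Lo6"),
        ],
    )
    def test_lookup(self, fraction, frame, expected):
        assert layer_of(fraction, frame) == expected

    def test_bands_partition_the_depth_range(self):
        for frac in np.linspace(0, 100, 1001):
            assert layer_of(float(frac), MEDULLA_FRAME) != "outside"

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            LayerFrame("x", (0.0, 50.0, 40.0, 100.0), ("a", "b", "c"))
        with pytest.raises(ValueError):
            LayerFrame("x", (0.0, 100.0), ("a", "b"))


class TestSmoothedProfile:
    def test_single_point_peak_is_gaussian_maximum(self):
        series = smoothed_profile([0.0], sigma=0.4)
        peak = 1.0 / (0.4 * math.sqrt(2.0 * math.pi))
        assert series.density.max() == pytest.approx(peak, rel=1e-4)
        assert abs(series.positions[np.argmax(series.density)]) < 0.05

    def test_empty_input_gives_zero_profile(self):
        series = smoothed_profile([], sigma=0.4)
        assert series.total_count == 0 and not series.density.any()

    def test_uniform_sample_density_matches_analytic(self):
        rng = np.random.default_rng(5)
        series = smoothed_profile(rng.uniform(0, 10, 1000), sigma=0.6)
        assert series.integral == pytest.approx(1000, rel=0.01)
        interior = (series.positions > 3) & (series.positions < 7)
        assert np.all(np.abs(series.density[interior] - 100.0) < 15.0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            smoothed_profile([1.0], sigma=0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(-50, 50, allow_nan=False, allow_infinity=False), max_size=150
        ),
        sigma=st.sampled_from([0.4, 0.6]),
    )
    def test_mass_conservation_property(self, values, sigma):
        series = smoothed_profile(values, sigma=sigma)
        if values:
            assert series.integral == pytest.approx(len(values), rel=0.01)


def rotate(points, theta, shift):
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T + np.asarray(shift)


class TestEllipseFit:
    def test_exact_circle_recovered(self):
        t = np.linspace(0, 2 * np.pi, 13)[:-1]
        pts = np.column_stack([10 * np.cos(t) + 3, 10 * np.sin(t) - 2])
        e = fit_ellipse_lsq(pts)
        assert e.a == pytest.approx(10, abs=1e-6)
        assert e.b == pytest.approx(10, abs=1e-6)
        assert e.center == pytest.approx((3, -2), abs=1e-6)

    def test_noisy_ellipse_parameters_within_two_percent(self):
        rng = np.random.default_rng(11)
        a, b, theta = 30.0, 12.0, 0.4
        t = rng.uniform(0, 2 * np.pi, 50)
        pts = rotate(
            np.column_stack([a * np.cos(t), b * np.sin(t)]), theta, (5.0, -7.0)
        ) + rng.normal(0, 0.2, (50, 2))
        e = fit_ellipse_lsq(pts)
        assert e.a == pytest.approx(a, rel=0.02)
        assert e.b == pytest.approx(b, rel=0.02)
        assert e.theta == pytest.approx(theta, abs=0.02)

    def test_equivariance_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 2 * np.pi, 40)
        pts = np.column_stack([20 * np.cos(t), 8 * np.sin(t)])
        base = fit_ellipse_lsq(pts)
        moved = fit_ellipse_lsq(rotate(pts, 0.7, (12.0, -4.0)))
        assert moved.a == pytest.approx(base.a, rel=1e-6)
        assert moved.b == pytest.approx(base.b, rel=1e-6)
        assert moved.theta == pytest.approx((base.theta + 0.7) % math.pi, abs=1e-6)
        assert moved.center == pytest.approx((12.0, -4.0), abs=1e-6)

    def test_matches_independent_library_fit(self):
        # Cross-check the in-package algebraic fit against an independently
        # maintained implementation of the same estimator.
        from skimage.measure import EllipseModel as SkimageEllipse

        rng = np.random.default_rng(21)
        t = rng.uniform(0, 2 * np.pi, 60)
        pts = rotate(
            np.column_stack([25 * np.cos(t), 9 * np.sin(t)]), 1.1, (-3.0, 6.0)
        ) + rng.normal(0, 0.3, (60, 2))
        ours = fit_ellipse_lsq(pts)
        theirs = SkimageEllipse.from_estimate(pts)
        xc, yc = theirs.center
        ta, tb = sorted(theirs.axis_lengths, reverse=True)
        assert ours.center == pytest.approx((xc, yc), abs=1e-6)
        assert (ours.a, ours.b) == pytest.approx((ta, tb), rel=1e-6)

    @pytest.mark.parametrize(
        "pts",
        [
            np.column_stack([np.arange(10.0), 2 * np.arange(10.0)]),  # collinear
            np.zeros((4, 2)),  # too few points
        ],
    )
    def test_degenerate_configurations_rejected(self, pts):
        with pytest.raises((EllipseFitError, ValueError)):
            fit_ellipse_lsq(pts)


class TestArcPosition:
    def test_point_beyond_major_vertex(self):
        e = EllipseModel(center=(0, 0), a=10, b=4, theta=0.0)
        arc, normal = arc_position((15.0, 0.0), e)
        assert arc == pytest.approx(0.0, abs=1e-6)
        assert normal == pytest.approx(5.0, abs=1e-6)

    def test_circle_arc_is_radius_times_angle(self):
        r = 7.0
        e = EllipseModel(center=(1, 1), a=r, b=r, theta=0.0)
        for theta in (0.3, 1.2, 2.9):
            pt = (1 + 9 * math.cos(theta), 1 + 9 * math.sin(theta))
            arc, normal = arc_position(pt, e)
            assert arc == pytest.approx(r * theta, abs=1e-6)
            assert normal == pytest.approx(2.0, abs=1e-6)

    def test_interior_point_has_negative_normal(self):
        # on the minor axis the foot is the co-vertex, so the distance is exact
        e = EllipseModel(center=(0, 0), a=10, b=4, theta=0.0)
        _, normal = arc_position((0.0, 2.0), e)
        assert normal == pytest.approx(-2.0, abs=1e-6)

    def test_center_point_rejected(self):
        e = EllipseModel(center=(2, 3), a=5, b=4, theta=0.1)
        with pytest.raises(ValueError, match="ambiguous"):
            arc_position((2.0, 3.0), e)

    def test_arc_monotone_in_parametric_angle(self):
        e = EllipseModel(center=(0, 0), a=12, b=5, theta=0.2)
        ts = np.linspace(0.05, 2 * math.pi - 0.05, 25)
        arcs = [arc_position(1.3 * (e.point_at(t) - e.center) + e.center, e)[0] for t in ts]
        assert all(a < b for a, b in zip(arcs, arcs[1:]))

    def test_agrees_with_dense_sampling_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a = rng.uniform(5, 40)
            e = EllipseModel(
                center=(rng.uniform(-10, 10), rng.uniform(-10, 10)),
                a=a,
                b=rng.uniform(2, a),
                theta=rng.uniform(0, math.pi),
            )
            pt = np.array(e.center) + rng.uniform(-1.5 * a, 1.5 * a, 2)
            if np.hypot(*(pt - np.array(e.center))) < 1e-3:
                continue
            arc, normal = arc_position(pt, e)
            dense = e.point_at(np.linspace(0, 2 * np.pi, 100_001))
            dist = np.linalg.norm(dense - pt, axis=1)
            j = int(np.argmin(dist))
            oracle_arc = np.linalg.norm(np.diff(dense[: j + 1], axis=0), axis=1).sum()
            assert abs(abs(normal) - dist[j]) < 1e-3
            assert abs(arc - oracle_arc) < 1e-2


class TestRimLinearization:
    def test_profile_peak_and_width_recover_arbor_geometry(self):
        """Full dorsal-rim pipeline: columns on an elliptical arc, synapses
        around an arbor centroid, arc-length linearization, 0.6-um kernel.
        The profile peak must land within one column pitch of the true
        centroid and the 90% mass width must match the true span +/-20%."""
        rng = np.random.default_rng(23)
        e_true = EllipseModel(center=(0, 0), a=120.0, b=80.0, theta=0.3)
        ts = np.linspace(0.2, 1.4, 24)  # rim arc of column centers
        centers = e_true.point_at(ts)
        fit = fit_ellipse_lsq(centers)
        # synapses on 10 consecutive rim columns (pitch ~5 um), strongest
        # input in the center of the arbor
        arbor = centers[7:17]
        counts = np.array([12, 16, 22, 30, 40, 40, 30, 22, 16, 12])
        syn = np.repeat(arbor, counts, axis=0) + rng.normal(
            0, 1.0, (int(counts.sum()), 2)
        )
        arcs = np.array([arc_position(p, fit)[0] for p in syn])
        series = smoothed_profile(arcs, sigma=0.6)
        true_center_arc = arc_position(arbor.mean(axis=0), fit)[0]
        peak_arc = series.positions[np.argmax(series.density)]
        pitch = np.linalg.norm(np.diff(centers, axis=0), axis=1).mean()
        assert abs(peak_arc - true_center_arc) < pitch
        cdf = np.cumsum(series.density)
        cdf /= cdf[-1]
        lo = series.positions[np.searchsorted(cdf, 0.05)]
        hi = series.positions[np.searchsorted(cdf, 0.95)]
        true_span = (
            arc_position(arbor[-1], fit)[0] - arc_position(arbor[0], fit)[0]
        )
        assert (hi - lo) == pytest.approx(true_span, rel=0.2)
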