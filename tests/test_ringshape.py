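"""Outline tracing, elliptic Fourier smoothing, circularity and contour length."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from afmring import ringshape, synthgen
from afmring.imgproc import HeightMap
from afmring.ringshape import (
    FrameFlagged,
    Outline,
    binarize_outline,
    circularity,
    classify_and_tally,
    contour_length,
    efd_fit,
    efd_reconstruct,
    otsu_threshold,
    smooth_outline,
)
from conftest import make_annulus, make_disk


def ellipse_outline(a, b, n=200, angle=0.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ca, sa = math.cos(angle), math.sin(angle)
    return Outline(np.column_stack([center[0] + ca * x - sa * y,
                                    center[1] + sa * x + ca * y]))


def ellipse_circularity_oracle(a, b):
    """4*pi*S/L^2 with the perimeter from numerical quadrature."""
    L = 4 * a * quad(lambda t: math.sqrt(1 - (1 - (b / a) ** 2) * math.sin(t) ** 2),
                     0, math.pi / 2)[0]
    return 4 * math.pi * (math.pi * a * b) / L**2


class TestBinarizeOutline:
    def test_disk_outline_radius_within_one_pixel(self):
        hm = make_disk(radius_nm=5.0, pixel_nm=0.25)
        out = binarize_outline(hm)
        r = np.hypot(*(out.points - out.centroid()).T)
        assert np.all(np.abs(r - 5.0) < 2 * hm.pixel_nm)

    def test_largest_of_two_blobs_selected(self):
        hm = make_disk(radius_nm=6.0, pixel_nm=0.25, size_px=128)
        small = make_disk(radius_nm=2.0, pixel_nm=0.25, size_px=128)
        h = hm.heights.copy()
        h[:, :] += np.roll(small.heights, 45, axis=1)
        out = binarize_outline(HeightMap(h, 0.25))
        r = np.hypot(*(out.points - out.centroid()).T)
        assert np.median(r) == pytest.approx(6.0, abs=0.5)

    def test_otsu_maximizes_between_class_variance(self):
        # oracle: exhaustive scan over candidate thresholds; the chosen
        # threshold must achieve the maximal between-class variance
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0.2, 0.1, 4000),
                               rng.normal(5.0, 0.5, 2000)])

        def between_class_variance(thr):
            lo, hi = vals[vals <= thr], vals[vals > thr]
            if lo.size == 0 or hi.size == 0:
                return 0.0
            return lo.size * hi.size * (lo.mean() - hi.mean()) ** 2 / vals.size**2

        thr = otsu_threshold(vals)
        candidates = np.linspace(vals.min(), vals.max(), 256)
        best = max(between_class_variance(t) for t in candidates)
        assert between_class_variance(thr) >= 0.999 * best

    def test_empty_and_border_touching_flagged(self):
        with pytest.raises(FrameFlagged, match="foreground"):
            binarize_outline(HeightMap(np.zeros((32, 32)), 0.5))
        hm = make_disk(radius_nm=8.0, pixel_nm=0.5, size_px=32)  # hits border
        with pytest.raises(FrameFlagged, match="border"):
            binarize_outline(hm)


class TestEFD:
    def test_order1_coefficients_match_dense_first_harmonic_oracle(self):
        # oracle: first Fourier harmonic of the arc-length parameterized
        # ellipse from dense quadrature (the order-1 fit IS that harmonic)
        a, b = 6.0, 3.0
        t = np.linspace(0, 2 * np.pi, 100000, endpoint=False)
        x, y = a * np.cos(t), b * np.sin(t)
        ds = np.hypot(np.gradient(x, t), np.gradient(y, t)) * (t[1] - t[0])
        s = np.cumsum(ds) - ds
        T = s[-1] + ds[-1]
        phi = 2 * np.pi * s / T
        a1 = 2 / T * np.sum(x * np.cos(phi) * ds)
        d1 = 2 / T * np.sum(y * np.sin(phi) * ds)
        desc = efd_fit(ellipse_outline(a, b, n=400), order=1)
        assert desc.coeffs[0, 0] == pytest.approx(a1, rel=1e-3)
        assert desc.coeffs[0, 3] == pytest.approx(d1, rel=1e-3)

    def test_near_circular_ellipse_reproduced_by_first_harmonic(self):
        a, b = 5.0, 4.9
        rec = efd_reconstruct(efd_fit(ellipse_outline(a, b, n=400), order=1), 800)
        rel = rec.points - rec.points.mean(axis=0)
        d = np.hypot(*rel.T)
        assert d.max() == pytest.approx(a, rel=0.005)
        assert d.min() == pytest.approx(b, rel=0.005)

    def test_high_order_reconstruction_converges_to_polygon(self):
        rng = np.random.default_rng(5)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
        pts = np.column_stack([5 * np.cos(angles), 5 * np.sin(angles)])
        out = Outline(pts)
        rec = efd_reconstruct(efd_fit(out, order=64), 2000)
        # every vertex is approached within a pixel-scale distance
        dmax = max(np.min(np.hypot(*(rec.points - p).T)) for p in pts)
        assert dmax < 0.5

    def test_unit_square_order8_area(self):
        # oracle: dense numerical Fourier series of the square contour
        n_side = 64
        s = np.linspace(0, 1, n_side, endpoint=False)
        square = np.vstack([
            np.column_stack([s, np.zeros(n_side)]),
            np.column_stack([np.ones(n_side), s]),
            np.column_stack([1 - s, np.ones(n_side)]),
            np.column_stack([np.zeros(n_side), 1 - s]),
        ])
        rec = smooth_outline(Outline(square), order=8, n_points=1024)
        assert rec.area() == pytest.approx(1.0, rel=0.02)
        # corners are rounded: max |x|,|y| pulled inside the square
        assert rec.points.min() > -0.05
        assert rec.points.max() < 1.05

    def test_open_sequence_rejected(self):
        out = Outline(np.array([[0, 0], [1.0, 0], [1.0, 1.0], [0, 1.0]]))
        out.closed = False
        with pytest.raises(ValueError, match="closed"):
            efd_fit(out)


class TestCircularity:
    def test_circle_is_one(self):
        m = circularity(smooth_outline(ellipse_outline(5.0, 5.0)))
        assert m.circularity >= 0.999
        assert m.circularity <= 1.0 + 1e-6

    def test_two_to_one_ellipse_matches_quadrature_oracle(self):
        m = circularity(smooth_outline(ellipse_outline(8.0, 4.0, angle=0.3)))
        oracle = ellipse_circularity_oracle(8.0, 4.0)
        assert oracle == pytest.approx(0.84, abs=0.005)
        assert m.circularity == pytest.approx(oracle, rel=0.01)

    def test_generated_open_form_below_threshold(self):
        hm = synthgen.render_heightmap(synthgen.make_ring_model("open"),
                                       noise_sd=0.0, seed=0)
        m = circularity(smooth_outline(binarize_outline(hm)))
        assert m.circularity < 0.68

    def test_self_intersecting_profile_flagged_invalid(self):
        bow = Outline(np.array([[0, 0], [2.0, 2.0], [2.0, 0], [0, 2.0]]))
        m = circularity(bow)
        assert not m.valid

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), angle=st.floats(0.0, 2 * math.pi))
    def test_scale_and_rotation_invariance(self, scale, angle):
        base = smooth_outline(ellipse_outline(7.0, 4.0))
        c0 = circularity(base).circularity
        ca, sa = math.cos(angle), math.sin(angle)
        rot = np.array([[ca, -sa], [sa, ca]])
        moved = Outline(scale * base.points @ rot.T)
        assert circularity(moved).circularity == pytest.approx(c0, abs=1e-6)

    def test_smoothing_never_increases_perimeter_of_convex_outline(self):
        for a, b in [(5, 5), (8, 3), (6, 4)]:
            raw = ellipse_outline(a, b, n=128)
            sm = smooth_outline(raw, order=8)
            assert sm.perimeter() <= raw.perimeter() * (1 + 1e-9)


class TestContourLength:
    def test_circular_ridge_circumference(self):
        hm = make_annulus(r_mid_nm=5.6)
        out = smooth_outline(binarize_outline(hm))
        assert contour_length(hm, out) == pytest.approx(2 * math.pi * 5.6, rel=0.02)

    def test_wobbled_ridge_matches_arclength_integration(self):
        # ridge radius r(theta) = R + A sin(3 theta); oracle = fine-grid arc length
        R, A = 5.6, 0.5
        hm_size, px = 128, 0.5
        idx = np.arange(hm_size, dtype=float)
        c = (hm_size - 1) / 2.0
        x = (idx[None, :] - c) * px
        y = (idx[:, None] - c) * px
        r = np.hypot(x, y)
        th = np.arctan2(y, x)
        ridge_r = R + A * np.sin(3 * th)
        hm = HeightMap(8.0 * np.exp(-((r - ridge_r) ** 2) / (2 * 1.8**2)), px)
        out = smooth_outline(binarize_outline(hm))
        got = contour_length(hm, out)
        tt = np.linspace(0, 2 * np.pi, 20000)
        rr = R + A * np.sin(3 * tt)
        drr = 3 * A * np.cos(3 * tt)
        oracle = np.trapezoid(np.sqrt(rr**2 + drr**2), tt)
        assert got == pytest.approx(oracle, rel=0.02)

    def test_open_ring_refused(self):
        hm = synthgen.render_heightmap(synthgen.make_ring_model("open"),
                                       noise_sd=0.0, seed=0)
        out = smooth_outline(binarize_outline(hm))
        with pytest.raises(FrameFlagged, match="closed"):
            contour_length(hm, out)


class TestClassifyAndTally:
    def test_all_circles_closed(self):
        metrics = [circularity(smooth_outline(ellipse_outline(5, 5)))
                   for _ in range(10)]
        tally = classify_and_tally(metrics)
        assert tally["pct_closed"] == 100.0
        assert all(m.ring_class == "closed" for m in metrics)

    def test_tie_at_threshold_classifies_closed(self):
        m = ringshape.ShapeMetrics(perimeter_L=1, area_S=1, circularity=0.68)
        tally = classify_and_tally([m])
        assert m.ring_class == "closed"
        assert tally["pct_closed"] == 100.0

    def test_mixed_generated_set_recovers_composition(self):
        # generator labels are the oracle; default noise level
        metrics, labels = [], []
        for i in range(50):
            for form, label in (("round", "closed"), ("open", "open")):
                hm = synthgen.render_heightmap(synthgen.make_ring_model(form),
                                               noise_sd=0.1, seed=1000 + 2 * i)
                m = circularity(smooth_outline(binarize_outline(hm)))
                metrics.append(m)
                labels.append(label)
        tally = classify_and_tally(metrics)
        correct = np.mean([m.ring_class == lab for m, lab in zip(metrics, labels)])
        assert correct >= 0.95
        assert tally["pct_closed"] == pytest.approx(50.0, abs=5.0)
        assert tally["histogram"]["count"].sum() == 100

    def test_empty_input_empty_report(self):
        tally = classify_and_tally([])
        assert tally["n"] == 0
        assert tally["histogram"].empty
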