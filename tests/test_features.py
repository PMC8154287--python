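"""Characteristic features: extremes, orientation, EI, Hu-moment PS, divider SC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from busfeat import (CharacteristicFeatures, PhantomSpec, characteristic_features,
                     contour_extremes, divider_counts, ei_patch, ei_score,
                     ei_score_patch, generate_phantom, hu_ps_score,
                     orientation_score, ps_region, sc_score)
from busfeat.features import DividerTrace, EIPatch, region_moments


def square_contour(side=40.0, center=(100.0, 100.0), n_per_side=50):
    c = np.array(center)
    h = side / 2
    corners = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
    pts = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        t = np.linspace(0, 1, n_per_side, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts) + c


# ------------------------------------------------------------------ extremes

class TestExtremes:
    def test_ellipse_analytic(self, ellipse_contour):
        e = contour_extremes(ellipse_contour)
        assert e.top == pytest.approx((100, 80), abs=0.1)
        assert e.bottom == pytest.approx((100, 120), abs=0.1)
        assert e.leftmost == pytest.approx((60, 100), abs=0.1)
        assert e.rightmost == pytest.approx((140, 100), abs=0.1)

    def test_square_tie_break_is_side_midpoint(self):
        e = contour_extremes(square_contour())
        assert e.top == pytest.approx((100, 80), abs=1.0)
        assert e.bottom == pytest.approx((100, 120), abs=1.0)
        assert e.leftmost == pytest.approx((80, 100), abs=1.0)
        assert e.rightmost == pytest.approx((120, 100), abs=1.0)

    def test_extremes_lie_on_contour(self, circle_contour):
        e = contour_extremes(circle_contour)
        for pt in (e.top, e.bottom, e.leftmost, e.rightmost):
            d = np.linalg.norm(circle_contour - np.asarray(pt), axis=1).min()
            assert d < 0.5

    def test_degenerate_rejected(self):
        flat = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        with pytest.raises(ValueError):
            contour_extremes(flat)


class TestOrientation:
    def test_circle_is_one(self, circle_contour):
        assert orientation_score(contour_extremes(circle_contour)) == pytest.approx(1.0, abs=1e-6)

    def test_ellipse_half(self, ellipse_contour):
        assert orientation_score(contour_extremes(ellipse_contour)) == pytest.approx(0.5, abs=1e-6)

    def test_invariant_to_scale_and_translation(self, ellipse_contour):
        base = orientation_score(contour_extremes(ellipse_contour))
        moved = ellipse_contour * 3.7 + np.array([13.0, -5.0])
        assert orientation_score(contour_extremes(moved)) == pytest.approx(base, rel=1e-9)


# ------------------------------------------------------------------ EI score

class TestEIScore:
    def test_constant_patch_scores_zero(self):
        patch = EIPatch(values=np.full((21, 15), 0.3), provenance="top")
        assert ei_score_patch(patch) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        patch = EIPatch(values=np.array([[0.0, 0.0], [1.0, 1.0]]), provenance="top")
        assert ei_score_patch(patch) == pytest.approx(0.5)

    def test_intensity_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(21, 15))
        s1 = ei_score_patch(EIPatch(values=v, provenance="top"))
        s2 = ei_score_patch(EIPatch(values=3.0 * v, provenance="top"))
        assert s2 == pytest.approx(3.0 * s1, rel=1e-12)
        assert s1 >= 0

    def test_average_of_two_patches(self, disc_phantom):
        _, image, _, contour = disc_phantom
        e = contour_extremes(contour)
        up = ei_score_patch(ei_patch(image, e.top, 21, 15))
        down = ei_score_patch(ei_patch(image, e.bottom, 21, 15))
        assert ei_score(image, e) == pytest.approx((up + down) / 2)

    def test_patch_out_of_bounds_names_side(self):
        image = np.zeros((40, 40))
        with pytest.raises(ValueError, match="top"):
            ei_patch(image, (20, 3), m=21, n=15)
        with pytest.raises(ValueError, match="right"):
            ei_patch(image, (38, 20), m=21, n=15)

    def test_patch_exact_shape(self):
        image = np.zeros((64, 64))
        patch = ei_patch(image, (30, 30), m=21, n=15)
        assert patch.values.shape == (21, 15)

    def test_decreases_with_edge_blur(self):
        scores = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            spec = PhantomSpec(seed=11, edge_blur_sigma=sigma, speckle_looks=4.0)
            image, _, contour = generate_phantom(spec)
            scores.append(ei_score(image, contour_extremes(contour)))
        assert all(a > b for a, b in zip(scores, scores[1:]))


# ------------------------------------------------------------------ PS score

class TestPSScore:
    def test_hand_computed_checkerboard(self):
        region = np.array([[1.0, 0.0], [0.0, 1.0]])
        mom = region_moments(region)
        assert mom.m00 == 2.0
        assert mom.centroid == pytest.approx((1.5, 1.5))
        assert mom.mu20 == pytest.approx(0.5)
        assert mom.eta20 == pytest.approx(0.125)
        assert hu_ps_score(region) == pytest.approx(-math.log10(0.25), abs=1e-9)

    def test_translation_invariance_of_eta(self):
        rng = np.random.default_rng(1)
        block = rng.uniform(size=(6, 7))
        big1 = np.zeros((30, 30)); big1[2:8, 3:10] = block
        big2 = np.zeros((30, 30)); big2[15:21, 12:19] = block
        m1, m2 = region_moments(big1), region_moments(big2)
        assert m1.eta20 + m1.eta02 == pytest.approx(m2.eta20 + m2.eta02, rel=1e-9)

    def test_eta_stable_under_upsampling(self):
        rng = np.random.default_rng(2)
        region = rng.uniform(0.1, 0.9, size=(20, 24))
        up = np.kron(region, np.ones((2, 2)))  # 2x nearest-neighbor
        s1 = region_moments(region)
        s2 = region_moments(up)
        v1 = s1.eta20 + s1.eta02
        v2 = s2.eta20 + s2.eta02
        assert v2 == pytest.approx(v1, rel=0.02)

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError, match="m00"):
            hu_ps_score(np.zeros((5, 5)))

    def test_single_pixel_eta_zero_errors(self):
        region = np.zeros((3, 3)); region[1, 1] = 1.0
        with pytest.raises(ValueError):
            hu_ps_score(region)

    def test_region_geometry(self, disc_phantom):
        _, image, _, contour = disc_phantom
        e = contour_extremes(contour)
        region = ps_region(image, e, depth="auto")
        height = e.bottom[1] - e.top[1]
        assert region.shape[0] == pytest.approx(height, abs=2)
        assert region.shape[1] == pytest.approx(e.rightmost[0] - e.leftmost[0], abs=2)

    def test_lesion_at_bottom_errors(self):
        image = np.ones((50, 50)) * 0.5
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        contour = np.column_stack([25 + 10 * np.cos(theta), 39.5 + 10 * np.sin(theta)])
        with pytest.raises(ValueError, match="posterior"):
            ps_region(image, contour_extremes(contour))

    def test_phantom_scores_in_clinical_range(self):
        """Typical phantom PS scores bracket the clinical reference span 1.98-2.75."""
        scores = []
        for seed in range(4):
            spec = PhantomSpec(seed=seed, speckle_looks=4.0, shadow_enabled=True,
                               shadow_strength=0.3)
            image, _, contour = generate_phantom(spec)
            scores.append(hu_ps_score(ps_region(image, contour_extremes(contour))))
        assert all(1.5 <= s <= 3.5 for s in scores)


# ------------------------------------------------------------------ SC score

class TestDivider:
    def test_circle_matches_chord_angle_closed_form(self, circle_contour):
        trace = divider_counts(circle_contour, radii=range(4, 12))
        for r, n in zip(trace.radii, trace.counts):
            expected = math.ceil(2 * np.pi / (2 * math.asin(r / 100.0)))
            assert abs(n - expected) <= 1

    def test_counts_non_increasing(self, circle_contour):
        trace = divider_counts(circle_contour, radii=range(4, 12))
        assert all(a >= b for a, b in zip(trace.counts, trace.counts[1:]))

    def test_radius_too_large_errors(self, circle_contour):
        with pytest.raises(ValueError, match="extent"):
            divider_counts(circle_contour, radii=[4, 200])

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValueError):
            DividerTrace(radii=(5, 4), counts=(10, 12))
        with pytest.raises(ValueError):
            DividerTrace(radii=(4, 5), counts=(0, 3))


def ols_slope_oracle(radii, counts):
    """Closed-form simple-regression slope on (log10 R, log10 N)."""
    x = np.log10(np.asarray(radii, float))
    y = np.log10(np.asarray(counts, float))
    return float(((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum())


class TestSCScore:
    def test_exact_power_law(self):
        radii = (2.0, 4.0, 5.0, 10.0)
        counts = (50, 25, 20, 10)  # N = 100 / R exactly
        fit = sc_score(DividerTrace(radii=radii, counts=counts))
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_reference_trace_slope(self):
        radii = (4, 5, 6, 7, 8, 9, 10, 11)
        counts = (109, 85, 72, 61, 53, 46, 43, 37)
        fit = sc_score(DividerTrace(radii=radii, counts=counts))
        assert fit.slope == pytest.approx(-1.045, abs=0.005)
        assert fit.slope == pytest.approx(ols_slope_oracle(radii, counts), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 500), min_size=3, max_size=10, unique=True))
    def test_matches_closed_form_oracle(self, counts):
        counts = tuple(sorted(counts, reverse=True))
        radii = tuple(float(4 + i) for i in range(len(counts)))
        fit = sc_score(DividerTrace(radii=radii, counts=counts))
        assert fit.slope == pytest.approx(ols_slope_oracle(radii, counts), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sc_score(DividerTrace(radii=(4.0, 5.0), counts=(10, 9)))

    def test_smooth_phantom_near_minus_one(self):
        _, _, contour = generate_phantom(PhantomSpec(seed=8))
        fit = sc_score(divider_counts(contour))
        assert fit.slope == pytest.approx(-1.0, abs=0.05)

    def test_more_negative_with_irregularity(self):
        slopes = []
        for amp in (0.0, 0.1, 0.2, 0.3):
            _, _, contour = generate_phantom(PhantomSpec(seed=11, irregularity_amp=amp))
            slopes.append(sc_score(divider_counts(contour)).slope)
        assert all(a > b for a, b in zip(slopes, slopes[1:]))


# ------------------------------------------------------------------ assembly

class TestCharacteristicFeatures:
    def test_length_and_determinism(self, disc_phantom):
        _, image, _, contour = disc_phantom
        cf1 = characteristic_features(image, contour)
        cf2 = characteristic_features(image, contour)
        assert cf1.as_array().shape == (4,)
        assert np.array_equal(cf1.as_array(), cf2.as_array())

    def test_benign_vs_malignant_contrast(self):
        benign = PhantomSpec(seed=21, aspect=0.55, irregularity_amp=0.03,
                             speckle_looks=4.0)
        malignant = PhantomSpec(seed=22, aspect=0.95, irregularity_amp=0.25,
                                speckle_looks=4.0, base_radius=20.0)
        cfs = {}
        for name, spec in (("b", benign), ("m", malignant)):
            image, _, contour = generate_phantom(spec)
            cfs[name] = characteristic_features(image, contour)
        assert cfs["m"].orientation > cfs["b"].orientation
        assert abs(cfs["m"].sc_score) > abs(cfs["b"].sc_score)
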