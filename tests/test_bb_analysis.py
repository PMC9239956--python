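"""Profile extraction, background subtraction, FWHM localisation and
gantry-angle reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlqa.bb_analysis import (
    AmbiguousPeakError,
    Profile,
    TruncatedPeakError,
    extract_profile,
    fwhm_center,
    gantry_reproducibility,
    locate_bb,
    peripheral_peaks,
    subtract_background,
)
from mrlqa.geometry import GantryAngle, MachineGeometry, PortalImage
from mrlqa.phantom_sim import PhantomSpec, WobbleModel, render_mvi


def make_profile(samples, dx=0.25, x0=0.0):
    samples = np.asarray(samples, dtype=float)
    return Profile(samples, x0 + dx * np.arange(len(samples)))


def synthetic_image(pixels):
    pixels = np.asarray(pixels)
    nv, nu = pixels.shape
    return PortalImage(pixels=pixels, angle=GantryAngle(0.0),
                       geometry=MachineGeometry(),
                       central_pixel_uv=((nu - 1) / 2.0, (nv - 1) / 2.0))


class TestExtractProfile:
    def test_constant_image_gives_flat_profile(self):
        img = synthetic_image(np.full((11, 15), 400, dtype=np.uint16))
        p = extract_profile(img, "horizontal", 5)
        assert np.all(p.samples == 0.0)
        assert len(p) == 15

    def test_profile_through_bb_has_single_dominant_peak(self, quiet_image):
        img, _ = quiet_image
        cu, cv = img.central_pixel_uv
        p = extract_profile(img, "horizontal", int(round(cv)))
        c, w = fwhm_center(p)
        assert c == pytest.approx(0.0, abs=0.1)

    def test_single_pixel_span_allowed(self):
        img = synthetic_image(np.arange(20, dtype=np.uint16).reshape(4, 5))
        p = extract_profile(img, "horizontal", 1, span=(2, 3))
        assert len(p) == 1

    def test_out_of_image_span_rejected(self):
        img = synthetic_image(np.zeros((4, 5), dtype=np.uint16))
        with pytest.raises(IndexError):
            extract_profile(img, "horizontal", 1, span=(0, 99))
        with pytest.raises(IndexError):
            extract_profile(img, "vertical", 17)


class TestSubtractBackground:
    def test_affine_background_cancels_exactly(self):
        """Rows at +-d of an affine field average to the central row, so
        the residual is the pure peak."""
        x = np.arange(40) * 0.5
        peak = 100.0 * np.exp(-((x - 10.0) ** 2) / 4.0)

        def bg(row):  # affine in (x, row)
            return 3.0 + 1.7 * x + 2.5 * row

        bb = make_profile(bg(5) + peak, dx=0.5)
        above = make_profile(bg(3), dx=0.5)
        below = make_profile(bg(7), dx=0.5)
        out = subtract_background(bb, above, below)
        np.testing.assert_allclose(out.samples, peak, atol=1e-9)

    def test_identical_profiles_give_zero(self):
        p = make_profile(np.random.default_rng(0).uniform(0, 10, 30))
        out = subtract_background(p, p, p)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_mismatched_coordinates_rejected(self):
        a = make_profile(np.zeros(10), dx=0.25)
        b = make_profile(np.zeros(10), dx=0.30)
        with pytest.raises(ValueError):
            subtract_background(a, b, a)

    def test_couch_ramp_residual_small(self, spec, geom):
        """After subtraction the baseline of a couch-edge-distorted profile
        is flat to < 1% of the peak height."""
        from mrlqa.phantom_sim import CouchEdge

        wob = WobbleModel(couch_edges=(CouchEdge(u_mm=-10.0, amplitude=2500.0,
                                                 ramp_mm=30.0,
                                                 slope_per_mm=-50.0),))
        img, _ = render_mvi(spec, 90.0, wob, field_cm=(5.0, 5.7), geom=geom)
        loc = locate_bb(img, background_subtraction=True)
        cu, cv = img.central_pixel_uv
        row = int(round(loc.v_px))
        off = 60
        bb = extract_profile(img, "horizontal", row)
        above = extract_profile(img, "horizontal", row - off)
        below = extract_profile(img, "horizontal", row + off)
        corrected = subtract_background(bb, above, below)
        n = len(corrected)
        edges = np.concatenate([corrected.samples[: n // 5],
                                corrected.samples[-n // 5:]])
        assert abs(float(edges.mean())) < 0.01 * corrected.samples.max()


class TestFwhmCenter:
    def test_symmetric_triangle_exact(self):
        x = np.arange(81) * 1.25  # peak at coordinate 50.0
        y = np.maximum(0.0, 20.0 - np.abs(x - 50.0))
        c, w = fwhm_center(Profile(y, x))
        assert c == pytest.approx(50.0, abs=1e-12)
        assert w == pytest.approx(20.0, abs=1e-9)

    def test_gaussian_width_matches_closed_form(self):
        sigma = 2.0
        x = np.arange(-12, 12.01, 0.25)
        y = np.exp(-x ** 2 / (2 * sigma ** 2))
        c, w = fwhm_center(make_profile(y, dx=0.25, x0=-12.0))
        expected = sigma * 2 * np.sqrt(2 * np.log(2))  # 4.71 mm
        assert w == pytest.approx(expected, rel=0.02)
        assert c == pytest.approx(0.0, abs=0.01)

    def test_plateau_midpoint_convention(self):
        x = np.arange(0, 20.0, 0.5)
        y = np.where((x >= 6.0) & (x <= 12.0), 10.0, 0.0)
        c, w = fwhm_center(Profile(y, x))
        assert c == pytest.approx(9.0, abs=0.3)

    def test_truncated_peak_rejected(self):
        y = np.linspace(0, 10, 30)  # monotone: no crossing on the right
        with pytest.raises(TruncatedPeakError):
            fwhm_center(make_profile(y))

    def test_two_peaks_ambiguous(self):
        x = np.arange(0, 30.0, 0.5)
        y = (np.exp(-((x - 8) ** 2) / 2.0) + np.exp(-((x - 22) ** 2) / 2.0))
        with pytest.raises(AmbiguousPeakError):
            fwhm_center(Profile(y, x))

    @given(st.floats(-40, 40))
    @settings(max_examples=40, deadline=None)
    def test_translation_equivariance(self, delta):
        sigma = 1.5
        x = np.arange(-10, 10.01, 0.25)
        y = np.exp(-x ** 2 / (2 * sigma ** 2))
        c0, w0 = fwhm_center(Profile(y, x))
        c1, w1 = fwhm_center(Profile(y, x + delta))
        assert c1 - c0 == pytest.approx(delta, abs=1e-9)
        assert w1 == pytest.approx(w0, abs=1e-12)


class TestLocateBB:
    def test_perfect_alignment(self, quiet_image, geom):
        img, _ = quiet_image
        loc = locate_bb(img)
        assert abs(loc.u_mm) / geom.magnification < 0.05
        assert abs(loc.v_mm) / geom.magnification < 0.05
        assert loc.fwhm_u_mm > 0

    def test_offset_grid_localization_error(self, spec, geom):
        """Known offsets over +-2 mm recovered with mean absolute error
        < 0.1 mm despite pixel noise at ~1% of the contrast."""
        errors = []
        for i, off in enumerate(np.linspace(-2.0, 2.0, 9)):
            wob = WobbleModel(fixed_offset_mm=(off, 0.0), noise_sd=300.0,
                              seed=100 + i)
            img, truth = render_mvi(spec, 0.0, wob, field_cm=(5.0, 5.7),
                                    geom=geom)
            loc = locate_bb(img)
            errors.append(abs(loc.u_mm / geom.magnification
                              - truth.axis_offsets_mm[0]))
        assert float(np.mean(errors)) < 0.1

    def test_affine_background_invariance(self, spec, geom):
        """Localisation with background subtraction is unaffected by an
        added affine background."""
        img0, _ = render_mvi(spec, 0.0, WobbleModel(fixed_offset_mm=(0.7, 0.0)),
                             field_cm=(5.0, 5.7), geom=geom)
        wob = WobbleModel(fixed_offset_mm=(0.7, 0.0),
                          background_affine=(500.0, 25.0, 10.0))
        img1, _ = render_mvi(spec, 0.0, wob, field_cm=(5.0, 5.7), geom=geom)
        u0 = locate_bb(img0, background_subtraction=True).u_mm
        u1 = locate_bb(img1, background_subtraction=True).u_mm
        assert u1 == pytest.approx(u0, abs=0.05)

    def test_two_bbs_in_roi_ambiguous(self, spec, geom):
        img, _ = render_mvi(spec, 0.0, WobbleModel(), field_cm=(16.0, 4.0),
                            geom=geom, phantom_y_offset_cm=3.5)
        # wide ROI spanning several ring ballbearings
        with pytest.raises(AmbiguousPeakError):
            locate_bb(img, roi_half_width_mm=80.0)


class TestGantryReproducibility:
    def test_self_comparison_is_null(self, gantry_images):
        m = gantry_reproducibility(gantry_images[0.0], gantry_images[0.0])
        assert m["rms_profile_diff"] == 0.0
        assert all(d == 0.0 for d in m["peripheral_separation_diffs"])
        assert m["eclipse_score"] == 1.0

    def test_metrics_monotonic_in_angle_error(self, gantry_images):
        base = gantry_images[0.0]
        m01 = gantry_reproducibility(gantry_images[0.1], base)
        m03 = gantry_reproducibility(gantry_images[0.3], base)
        assert m03["rms_profile_diff"] > m01["rms_profile_diff"] > 0.0
        assert (1 - m03["eclipse_score"]) > (1 - m01["eclipse_score"]) >= 0.0

    def test_large_offset_resolves_doublets(self, gantry_images):
        """At a 1.0 deg offset the eclipsed/mirrored ballbearing pairs pull
        apart into resolved doublets (more peaks than the baseline)."""
        from mrlqa.bb_analysis import _central_row_profile

        n_base = len(peripheral_peaks(_central_row_profile(gantry_images[0.0])))
        n_off = len(peripheral_peaks(_central_row_profile(gantry_images[1.0])))
        assert n_off > n_base

    def test_metric_nonnegativity(self, gantry_images):
        base = gantry_images[0.0]
        for err in (0.1, 0.3):
            m = gantry_reproducibility(gantry_images[err], base)
            assert m["rms_profile_diff"] >= 0.0
            assert 0.0 <= m["eclipse_score"] <= 1.0
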