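"""Isocentre fitting: back-projection, minimax circle, full image pipeline."""

import numpy as np
import pytest

from mrlqa.geometry import MachineGeometry
from mrlqa.isocentre import (
    BeamAxisLine,
    InsufficientCoverageError,
    displacement_to_axis_line,
    fit_isocentre,
    in_distortion_arc,
    run_isocentre_analysis,
)
from mrlqa.phantom_sim import CouchEdge, PhantomSpec, WobbleModel, \
    render_projection_series
from mrlqa.bb_analysis import locate_bb

from conftest import grid_search_minimax


def lines_at(angle_offsets):
    """Axis lines from (angle_deg, perpendicular_offset_mm) pairs."""
    g = MachineGeometry()
    return [displacement_to_axis_line(w * g.magnification, a, g)
            for a, w in angle_offsets]


class TestBackProjection:
    def test_zero_displacement_through_origin(self):
        g = MachineGeometry()
        line = displacement_to_axis_line(0.0, 123.0, g)
        assert line.distance_to((0.0, 0.0)) == pytest.approx(0.0)

    def test_magnification_division(self):
        g = MachineGeometry(sad_cm=100.0, sid_cm=150.0)  # M = 1.5
        line = displacement_to_axis_line(1.5, 0.0, g)
        # vertical line at x = 1.0 mm
        assert line.distance_to((1.0, 5.0)) == pytest.approx(0.0, abs=1e-12)
        assert line.distance_to((0.0, 0.0)) == pytest.approx(1.0)

    def test_simulator_truth_round_trip(self, wobble_series, geom):
        """Lines rebuilt from the rendered (perspective-projected)
        ballbearing positions pass within 0.01 mm of the true axis foot."""
        series, truth = wobble_series
        for (img, _), w in zip(series, truth.axis_offsets_mm):
            u_rendered = img.metadata["bb_truth"][0]["u_mm"]
            line = displacement_to_axis_line(u_rendered, img.angle, geom)
            true_foot = w * np.array(line.normal)
            assert line.distance_to(true_foot) < 0.01


class TestMinimaxFit:
    def test_tangent_lines_to_circle(self):
        """Beams at the cardinals each offset by r bound a circle of
        radius r: centre at origin, diameter 2r."""
        r = 0.35
        res = fit_isocentre(lines_at([(0, r), (90, r), (180, r), (270, r)]))
        np.testing.assert_allclose(res.center, [0, 0], atol=1e-9)
        assert res.diameter == pytest.approx(2 * r, abs=1e-9)

    def test_concurrent_lines_zero_diameter(self):
        g = MachineGeometry()
        p = np.array([0.4, -0.2])
        lines = []
        for a in (0, 40, 95, 170, 260):
            from mrlqa.geometry import panel_u_direction
            w = float(p @ panel_u_direction(a))
            lines.append(displacement_to_axis_line(w * g.magnification, a, g))
        res = fit_isocentre(lines)
        np.testing.assert_allclose(res.center, p, atol=1e-9)
        assert res.diameter <= 1e-9

    def test_too_few_or_parallel_lines_rejected(self):
        with pytest.raises(InsufficientCoverageError):
            fit_isocentre(lines_at([(0, 0.1), (90, 0.1)]))
        with pytest.raises(InsufficientCoverageError):
            fit_isocentre(lines_at([(0, 0.1), (180, 0.2), (0, -0.1)]))

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(4, 12)
            angles = rng.uniform(0, 360, n)
            offsets = rng.normal(0, 0.3, n)
            lines = lines_at(list(zip(angles, offsets)))
            res = fit_isocentre(lines)
            c0, d0 = grid_search_minimax(lines, half_width_mm=1.5,
                                         resolution_mm=0.01,
                                         center0=tuple(res.center))
            assert abs(res.diameter - d0) <= 0.03  # grid resolution limited

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(0, 360, 8)
        offsets = rng.normal(0, 0.3, 8)
        lines = lines_at(list(zip(angles, offsets)))
        res0 = fit_isocentre(lines)
        t = np.array([0.7, -1.3])
        shifted = [BeamAxisLine(ln.angle, ln.point + t, ln.direction)
                   for ln in lines]
        res1 = fit_isocentre(shifted)
        np.testing.assert_allclose(res1.center, res0.center + t, atol=1e-7)
        assert res1.diameter == pytest.approx(res0.diameter, abs=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(8)
        angles = rng.uniform(0, 360, 8)
        offsets = rng.normal(0, 0.3, 8)
        res0 = fit_isocentre(lines_at(list(zip(angles, offsets))))
        phi = 33.0
        res1 = fit_isocentre(lines_at(list(zip(angles + phi, offsets))))
        t = np.deg2rad(phi)
        # panel-u frame rotates with the gantry: rotating every beam by phi
        # rotates the fitted centre by -phi about the origin
        rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        np.testing.assert_allclose(res1.center, rot @ res0.center, atol=1e-7)
        assert res1.diameter == pytest.approx(res0.diameter, abs=1e-9)

    def test_adding_line_never_shrinks_radius(self):
        rng = np.random.default_rng(9)
        angles = rng.uniform(0, 360, 10)
        offsets = rng.normal(0, 0.3, 10)
        pairs = list(zip(angles, offsets))
        prev = fit_isocentre(lines_at(pairs[:4])).diameter
        for k in range(5, 11):
            cur = fit_isocentre(lines_at(pairs[:k])).diameter
            assert cur >= prev - 1e-12
            prev = cur


class TestImagePipeline:
    def test_distortion_arc_membership(self):
        # the lateral arcs around 90 and 270 deg suffer couch-edge overlap
        for a in (50.0, 90.0, 130.0, 230.0, 270.0, 310.0):
            assert in_distortion_arc(a)
        for a in (0.0, 40.0, 140.0, 180.0, 220.0, 320.0):
            assert not in_distortion_arc(a)

    def test_excluded_angles_dropped(self, spec, geom):
        series, _ = render_projection_series(
            spec, wobble=WobbleModel(), geom=geom,
            angles=[0, 10, 20, 40, 60, 90, 180, 270, 300])
        res = run_isocentre_analysis([im for im, _ in series])
        assert set(res.excluded_angles) == {10.0, 20.0, 60.0, 300.0}
        assert res.n_projections == 5

    def test_default_series_avoids_excluded_angles(self, zero_wobble_series):
        series, _ = zero_wobble_series
        angles = [im.angle.degrees for im, _ in series]
        for a in (10.0, 20.0, 60.0, 300.0):
            assert a not in angles

    def test_zero_wobble_diameter_negligible(self, zero_wobble_series):
        series, truth = zero_wobble_series
        res = run_isocentre_analysis([im for im, _ in series])
        assert truth.diameter_mm == pytest.approx(0.0, abs=1e-9)
        assert res.diameter < 0.02

    def test_pure_translation_recovers_centre(self, spec, geom):
        series, truth = render_projection_series(
            spec, wobble=WobbleModel(fixed_offset_mm=(0.2, 0.0)), geom=geom)
        assert truth.diameter_mm == pytest.approx(0.0, abs=1e-6)
        res = run_isocentre_analysis([im for im, _ in series])
        np.testing.assert_allclose(res.center, [0.2, 0.0], atol=0.08)
        assert res.diameter < 0.1

    def test_known_diameter_recovered(self, wobble_series):
        series, truth = wobble_series
        res = run_isocentre_analysis([im for im, _ in series])
        assert truth.diameter_mm == pytest.approx(0.4, abs=1e-6)
        assert res.diameter == pytest.approx(truth.diameter_mm, abs=0.1)
        assert res.within_tolerance(1.00)

    def test_background_subtraction_improves_localization(self, spec, geom):
        """With a couch-edge artifact crossing the image, background
        subtraction reduces the median localisation error."""
        wob = WobbleModel(
            fixed_offset_mm=(0.5, 0.0),
            couch_edges=(CouchEdge(u_mm=-6.0, amplitude=2500.0, ramp_mm=25.0,
                                   slope_per_mm=-60.0),),
            background_affine=(0.0, 40.0, 0.0),
            noise_sd=20.0, seed=3)
        series, _ = render_projection_series(spec, wobble=wob, geom=geom,
                                             angles=[0, 30, 90, 150, 210, 330])
        errs = {True: [], False: []}
        for img, truth in series:
            true_u = truth.axis_offsets_mm[0] * geom.magnification
            for sub in (True, False):
                loc = locate_bb(img, background_subtraction=sub)
                errs[sub].append(abs(loc.u_mm - true_u))
        assert np.median(errs[True]) < np.median(errs[False])
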