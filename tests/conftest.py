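"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force (dense grid
search, exhaustive gamma minimisation) so that the package's fast
implementations are checked against an independent code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mrlqa.gamma import DoseGrid, GammaCriteria

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mrlqa.geometry import MachineGeometry
from mrlqa.phantom_sim import PhantomSpec, WobbleModel, render_mvi, \
    render_projection_series


@pytest.fixture(scope="session")
def geom() -> MachineGeometry:
    return MachineGeometry()


@pytest.fixture(scope="session")
def spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def quiet_image(spec, geom):
    """Perfectly aligned, noise-free image of the central ballbearing."""
    img, truth = render_mvi(spec, 0.0, WobbleModel(), field_cm=(5.0, 5.7),
                            geom=geom)
    return img, truth


@pytest.fixture(scope="session")
def zero_wobble_series(spec, geom):
    return render_projection_series(spec, wobble=WobbleModel(), geom=geom)


@pytest.fixture(scope="session")
def wobble_series(spec, geom):
    """Series with a constant 0.2 mm perpendicular axis offset (true
    minimax diameter exactly 0.4 mm) plus realistic pixel noise."""
    wob = WobbleModel(harmonics=((0.0, 0.2, 0.0),), noise_sd=30.0, seed=11)
    return render_projection_series(spec, wobble=wob, geom=geom)


@pytest.fixture(scope="session")
def gantry_images(spec, geom):
    """Ring-at-isocentre images at a range of deliberate gantry-angle
    errors, used by the reproducibility tests."""
    out = {}
    for err in (0.0, 0.1, 0.3, 1.0):
        wob = WobbleModel(gantry_angle_error_deg=err, noise_sd=30.0, seed=5)
        img, _ = render_mvi(spec, 0.0, wob, field_cm=(16.0, 4.0), geom=geom,
                            phantom_y_offset_cm=3.5)
        out[err] = img
    return out


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def grid_search_minimax(lines, half_width_mm: float = 1.5,
                        resolution_mm: float = 0.005,
                        center0=(0.0, 0.0)) -> tuple[np.ndarray, float]:
    """Dense 2-D grid search for the minimax centre of a set of axis lines.

    Returns (centre, diameter).  Exhaustive: evaluates the maximum
    point-to-line distance at every grid node and takes the minimum.
    """
    xs = center0[0] + np.arange(-half_width_mm, half_width_mm + resolution_mm / 2,
                                resolution_mm)
    zs = center0[1] + np.arange(-half_width_mm, half_width_mm + resolution_mm / 2,
                                resolution_mm)
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    worst = np.zeros_like(xx)
    for ln in lines:
        n = ln.normal
        b = float(n @ ln.point)
        d = np.abs(n[0] * xx + n[1] * zz - b)
        np.maximum(worst, d, out=worst)
    i, j = np.unravel_index(int(np.argmin(worst)), worst.shape)
    return np.array([xs[i], zs[j]]), 2.0 * float(worst[i, j])


def brute_force_gamma(ref: DoseGrid, evl: DoseGrid,
                      crit: GammaCriteria, fine_step_factor: float = 0.1
                      ) -> np.ndarray:
    """Exhaustive gamma map with its own bilinear interpolation, searching
    every offset on a lattice of step ``fine_step_factor`` x the
    implementation's interpolation step.  Independent of
    :func:`mrlqa.gamma.gamma_map`."""
    step = crit.interpolation_step * crit.dta_mm * fine_step_factor
    radius = crit.search_radius_factor * crit.dta_mm
    n_off = int(np.floor(radius / step))
    offs = np.arange(-n_off, n_off + 1) * step  # exact zero at the centre
    ref_max = ref.values.max()

    ex, ey = evl.x_mm, evl.y_mm
    tol = 1e-9

    def interp(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        fx = np.clip((x - ex[0]) / (ex[1] - ex[0]), 0, len(ex) - 1 - 1e-12)
        fy = np.clip((y - ey[0]) / (ey[1] - ey[0]), 0, len(ey) - 1 - 1e-12)
        inside = ((x >= ex[0] - tol) & (x <= ex[-1] + tol)
                  & (y >= ey[0] - tol) & (y <= ey[-1] + tol))
        i, j = fy.astype(int), fx.astype(int)
        ty, tx = fy - i, fx - j
        v = (evl.values[i, j] * (1 - ty) * (1 - tx)
             + evl.values[i + 1, j] * ty * (1 - tx)
             + evl.values[i, j + 1] * (1 - ty) * tx
             + evl.values[i + 1, j + 1] * ty * tx)
        return np.where(inside, v, np.nan)

    ox, oy = np.meshgrid(offs, offs)
    keep = ox ** 2 + oy ** 2 <= radius ** 2 + 1e-12
    ox, oy = ox[keep], oy[keep]
    dist2 = (ox ** 2 + oy ** 2) / crit.dta_mm ** 2

    gam = np.full(ref.values.shape, np.nan)
    for i, y0 in enumerate(ref.y_mm):
        for j, x0 in enumerate(ref.x_mm):
            dr = ref.values[i, j]
            if dr < crit.suppression_pct / 100.0 * ref_max:
                continue
            if crit.normalization == "global":
                denom = crit.dose_diff_pct / 100.0 * ref_max
            else:
                denom = crit.dose_diff_pct / 100.0 * dr
            de = interp(x0 + ox, y0 + oy)
            g2 = (de - dr) ** 2 / denom ** 2 + dist2
            val = np.nanmin(g2)
            if np.isfinite(val):
                gam[i, j] = np.sqrt(val)
    return gam
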