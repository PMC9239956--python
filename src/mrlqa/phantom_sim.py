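"""Synthetic-fixture generator for every analysis in this package.

Renders megavoltage portal images of a cylindrical ballbearing alignment
phantom (a central 10.0 mm ballbearing plus two rings of twelve 4.0 mm
ballbearings at 30.0 deg spacing, offset +-3.5 cm longitudinally) with a
known, configurable ground truth: per-angle isocentre wobble, gantry-angle
error, additive noise and couch-edge background artifacts.  Also produces
paired 2-D dose maps with exactly known perturbations for gamma testing,
and ionisation-chamber reading series with known beam-quality / output
truth for the dosimetry chain.

Ballbearings are rendered as transmission dips: the in-field fluence is
attenuated by ``1 - exp(-mu * chord)`` where ``chord`` is the path length
through the sphere at each pixel.  The default attenuation coefficient
renders the spheres near-opaque, so the integrated deficit of a ballbearing
tracks its projected area (diameter squared).  A Gaussian blur emulates the
finite source size / detector response, and all randomness is driven by a
single seed so every output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .gamma import DoseGrid
from .geometry import (
    GantryAngle,
    MachineGeometry,
    PortalImage,
    beam_direction,
    panel_u_direction,
)
from .isocentre import (
    DEFAULT_EXCLUDED_ANGLES,
    BeamAxisLine,
    displacement_to_axis_line,
    fit_isocentre,
)

__all__ = [
    "PhantomSpec",
    "WobbleModel",
    "CouchEdge",
    "GroundTruth",
    "render_mvi",
    "render_projection_series",
    "default_isocentre_angles",
    "make_dose_pair",
    "simulate_chamber_series",
    "ChamberSeriesSim",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the MV alignment phantom.

    The ring radius is not a published phantom constant; the default
    (6.5 cm) simply fits the 22.0 cm-wide imaged field and none of the
    analyses depend on its absolute value.
    """

    central_bb_diameter_mm: float = 10.0
    ring_bb_diameter_mm: float = 4.0
    ring_count: int = 12
    ring_angular_spacing_deg: float = 30.0
    ring_longitudinal_offset_cm: float = 3.5
    ring_radius_cm: float = 6.5

    def __post_init__(self) -> None:
        if self.central_bb_diameter_mm <= 0 or self.ring_bb_diameter_mm <= 0:
            raise ValueError("ballbearing diameters must be > 0")
        if not math.isclose(self.ring_count * self.ring_angular_spacing_deg,
                            360.0, abs_tol=1e-9):
            raise ValueError("ring_count * ring_angular_spacing must equal 360")


@dataclass(frozen=True)
class CouchEdge:
    """Additive step + ramp band crossing the image (couch-edge artifact).

    The band raises the background by ``amplitude`` for panel-u beyond
    ``u_mm`` with a linear ramp of width ``ramp_mm`` across the edge, and a
    mild slope beyond it — the kind of structured background the
    background-subtraction step is designed to remove.
    """

    u_mm: float
    amplitude: float
    ramp_mm: float = 4.0
    slope_per_mm: float = 0.0

    def evaluate(self, u_mm: np.ndarray) -> np.ndarray:
        x = (u_mm - self.u_mm) / self.ramp_mm
        band = np.clip(x, 0.0, 1.0)
        beyond = np.clip(u_mm - (self.u_mm + self.ramp_mm), 0.0, None)
        return self.amplitude * band + self.slope_per_mm * beyond


@dataclass(frozen=True)
class WobbleModel:
    """Per-angle isocentre wander and image-degradation model.

    ``harmonics`` is a list of (order k, amplitude_mm, phase_deg); each
    term displaces the ballbearing perpendicular to the beam by
    ``amp * cos(k * gantry + phase)`` in the isocentre plane.  A k = 0
    harmonic of amplitude A therefore offsets every axis line by A,
    producing axis lines tangent to a circle of radius A (true isocentre
    diameter exactly 2A), while ``fixed_offset`` is a constant in-plane
    displacement that leaves the axes concurrent.
    """

    fixed_offset_mm: tuple[float, float] = (0.0, 0.0)
    harmonics: tuple[tuple[float, float, float], ...] = ()
    gantry_angle_error_deg: float = 0.0
    noise_sd: float = 0.0
    background_affine: tuple[float, float, float] = (0.0, 0.0, 0.0)
    couch_edges: tuple[CouchEdge, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for _, amp, _ in self.harmonics:
            if amp < 0:
                raise ValueError("harmonic amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def perpendicular_offset_mm(self, angle: GantryAngle | float) -> float:
        """Scalar perpendicular (panel-u direction) ballbearing offset at
        the isocentre plane for this gantry angle, including the fixed
        in-plane offset's perpendicular component."""
        if not isinstance(angle, GantryAngle):
            angle = GantryAngle(angle)
        u_hat = panel_u_direction(angle)
        w = float(np.asarray(self.fixed_offset_mm) @ u_hat)
        for k, amp, phase in self.harmonics:
            w += amp * math.cos(k * angle.radians + math.radians(phase))
        return w

    def inplane_displacement_mm(self, angle: GantryAngle | float) -> np.ndarray:
        """The 2-D (x, z) displacement applied to the phantom for this
        angle: fixed offset plus the harmonic terms along the panel-u
        direction."""
        if not isinstance(angle, GantryAngle):
            angle = GantryAngle(angle)
        u_hat = panel_u_direction(angle)
        disp = np.asarray(self.fixed_offset_mm, dtype=float).copy()
        for k, amp, phase in self.harmonics:
            disp += amp * math.cos(k * angle.radians + math.radians(phase)) * u_hat
        return disp


@dataclass
class GroundTruth:
    """Known truth for a rendered projection (series).

    ``axis_offsets_mm[i]`` is the perpendicular offset of gantry angle
    ``angles_deg[i]``'s beam axis relative to the ballbearing, in the
    isocentre plane; ``diameter_mm`` is the diameter of the minimal circle
    touched by all the implied axis lines (0.0 for a single projection).
    """

    angles_deg: list[float]
    axis_offsets_mm: list[float]
    diameter_mm: float
    center_mm: tuple[float, float] = (0.0, 0.0)

    def axis_lines(self, geom: MachineGeometry) -> list[BeamAxisLine]:
        return [
            displacement_to_axis_line(w * geom.magnification, a, geom)
            for a, w in zip(self.angles_deg, self.axis_offsets_mm)
        ]


# Rendering constants: 16-bit well depth, near-opaque steel markers.
BASE_LEVEL = 30000.0
BB_ATTENUATION_PER_MM = 2.0
DEFAULT_BLUR_SIGMA_MM = 0.4  # at the isocentre plane


def _phantom_bbs(spec: PhantomSpec, y_offset_cm: float) -> list[tuple[np.ndarray, float, float]]:
    """All ballbearings as (xz_mm, y_mm, radius_mm) in room coordinates."""
    bbs: list[tuple[np.ndarray, float, float]] = [
        (np.zeros(2), y_offset_cm * 10.0, spec.central_bb_diameter_mm / 2.0)
    ]
    r = spec.ring_radius_cm * 10.0
    for ring_sign in (+1.0, -1.0):
        y = (y_offset_cm + ring_sign * spec.ring_longitudinal_offset_cm) * 10.0
        for k in range(spec.ring_count):
            phi = math.radians(k * spec.ring_angular_spacing_deg)
            xz = np.array([r * math.sin(phi), r * math.cos(phi)])
            bbs.append((xz, y, spec.ring_bb_diameter_mm / 2.0))
    return bbs


def render_mvi(spec: PhantomSpec,
               angle: GantryAngle | float,
               wobble: WobbleModel | None = None,
               field_cm: tuple[float, float] = (10.0, 9.5),
               geom: MachineGeometry | None = None,
               phantom_y_offset_cm: float = 0.0,
               blur_sigma_mm: float = DEFAULT_BLUR_SIGMA_MM,
               _rng: np.random.Generator | None = None) -> tuple[PortalImage, GroundTruth]:
    """Render one portal image of the alignment phantom.

    Parameters
    ----------
    field_cm :
        (width, height) of the imaged field at the isocentre plane; must
        fit within the panel extent.
    phantom_y_offset_cm :
        Longitudinal shift of the phantom (e.g. +-3.5 to centre one
        ballbearing ring at the isocentre for the gantry-angle test).
    blur_sigma_mm :
        Gaussian edge blur, expressed at the isocentre plane.

    Returns the image (ballbearings as intensity dips, truth in
    ``metadata``) and a single-angle :class:`GroundTruth`.
    """
    if geom is None:
        geom = MachineGeometry()
    if wobble is None:
        wobble = WobbleModel()
    if not isinstance(angle, GantryAngle):
        angle = GantryAngle(angle)
    fw, fh = field_cm
    pw, ph = geom.panel_extent_cm
    if fw > pw + 1e-9 or fh > ph + 1e-9:
        raise ValueError(
            f"field {fw} x {fh} cm exceeds panel extent {pw} x {ph} cm at isocentre")

    m = geom.magnification
    pitch = geom.pixel_pitch_mm
    nu = int(round(fw * 10.0 * m / pitch))
    nv = int(round(fh * 10.0 * m / pitch))
    cu = (nu - 1) / 2.0
    cv = (nv - 1) / 2.0
    u_mm = (np.arange(nu) - cu) * pitch           # panel mm, relative to CAX
    v_mm = (np.arange(nv) - cv) * pitch
    uu, vv = np.meshgrid(u_mm, v_mm)

    # effective gantry angle includes the deliberate/set error
    eff = GantryAngle(angle.degrees + wobble.gantry_angle_error_deg)
    u_hat = panel_u_direction(eff)
    d_hat = beam_direction(eff)
    disp = wobble.inplane_displacement_mm(angle)

    img = np.full((nv, nu), BASE_LEVEL)
    b0, bu, bv = wobble.background_affine
    img += b0 + bu * uu + bv * vv
    for edge in wobble.couch_edges:
        img += edge.evaluate(uu)

    bb_truth = []
    for xz, y_mm, r_mm in _phantom_bbs(spec, phantom_y_offset_cm):
        p = xz + disp
        w = float(p @ u_hat)
        ell_cm = float(p @ d_hat) / 10.0
        scale = geom.sid_cm / (geom.sad_cm + ell_cm)
        uc = w * scale
        vc = y_mm * scale
        r_proj = r_mm * scale
        margin = r_proj + 6.0 * blur_sigma_mm * m
        if (uc < u_mm[0] - margin or uc > u_mm[-1] + margin
                or vc < v_mm[0] - margin or vc > v_mm[-1] + margin):
            continue
        rho2 = (uu - uc) ** 2 + (vv - vc) ** 2
        chord = 2.0 * np.sqrt(np.clip(r_proj ** 2 - rho2, 0.0, None)) / scale
        img -= BASE_LEVEL * (1.0 - np.exp(-BB_ATTENUATION_PER_MM * chord))
        bb_truth.append({"u_mm": uc, "v_mm": vc, "radius_mm": r_mm,
                         "proj_radius_mm": r_proj})

    sigma_px = blur_sigma_mm * m / pitch
    if sigma_px > 0:
        img = gaussian_filter(img, sigma_px, mode="nearest")
    if wobble.noise_sd > 0:
        rng = _rng if _rng is not None else np.random.default_rng(wobble.seed)
        img = img + rng.normal(0.0, wobble.noise_sd, img.shape)

    pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    w_true = wobble.perpendicular_offset_mm(angle)
    image = PortalImage(
        pixels=pixels, angle=angle, geometry=geom,
        central_pixel_uv=(cu, cv),
        metadata={
            "bb_truth": bb_truth,
            "true_axis_offset_mm": w_true,
            "gantry_angle_error_deg": wobble.gantry_angle_error_deg,
            "blur_sigma_mm": blur_sigma_mm,
            "field_cm": (fw, fh),
            "phantom_y_offset_cm": phantom_y_offset_cm,
        },
    )
    truth = GroundTruth(angles_deg=[angle.degrees],
                        axis_offsets_mm=[w_true], diameter_mm=0.0)
    return image, truth


def default_isocentre_angles(step_deg: float = 10.0,
                             excluded: Sequence[float] = tuple(sorted(DEFAULT_EXCLUDED_ANGLES)),
                             both_directions: bool = True) -> list[float]:
    """The isocentre acquisition sequence: every ``step_deg`` over a full
    rotation, minus the excluded angles, optionally repeated in the
    reverse rotation sense (duplicate angles are intended — both rotation
    directions are pooled into one fit)."""
    excl = {float(a) % 360.0 for a in excluded}
    up = [float(a) for a in np.arange(0.0, 360.0 + step_deg / 2, step_deg)
          if a % 360.0 not in excl]
    if not both_directions:
        return up
    down = list(reversed(up))[1:]  # duplicates intended: both senses pooled
    return up + down


def render_projection_series(spec: PhantomSpec,
                             angles: Sequence[float] | None = None,
                             wobble: WobbleModel | None = None,
                             geom: MachineGeometry | None = None,
                             field_cm: tuple[float, float] = (5.0, 5.7),
                             localization_noise_mm: float = 0.0,
                             **render_kwargs) -> tuple[list[tuple[PortalImage, GroundTruth]], GroundTruth]:
    """Render a full isocentre projection series of the central ballbearing.

    Returns the per-angle (image, truth) list and the pooled series
    :class:`GroundTruth` whose ``diameter_mm`` is the minimax-circle
    diameter of the true axis lines (the quantity the analysis should
    recover).  ``localization_noise_mm`` adds independent per-angle jitter
    to the true ballbearing offset (simulating sub-pixel localisation
    noise) before rendering.
    """
    if geom is None:
        geom = MachineGeometry()
    if wobble is None:
        wobble = WobbleModel()
    if angles is None:
        angles = default_isocentre_angles()
    rng = np.random.default_rng(wobble.seed)

    out: list[tuple[PortalImage, GroundTruth]] = []
    offsets: list[float] = []
    for a in angles:
        w_model = wobble
        if localization_noise_mm > 0:
            # per-angle jitter injected as a zero-order harmonic (a pure
            # perpendicular offset for this one projection)
            jitter = float(rng.normal(0.0, localization_noise_mm))
            w_model = replace(wobble,
                              harmonics=wobble.harmonics
                              + ((0.0, abs(jitter), 0.0 if jitter >= 0 else 180.0),))
        img, t = render_mvi(spec, a, w_model, field_cm=field_cm, geom=geom,
                            _rng=rng, **render_kwargs)
        out.append((img, t))
        offsets.append(t.axis_offsets_mm[0])

    series = GroundTruth(angles_deg=[float(a) % 360.0 for a in angles],
                         axis_offsets_mm=offsets, diameter_mm=0.0)
    fit = fit_isocentre(series.axis_lines(geom))
    series.diameter_mm = fit.diameter
    series.center_mm = (float(fit.center[0]), float(fit.center[1]))
    return out, series


# ---------------------------------------------------------------------------
# Dose-map pairs for gamma testing
# ---------------------------------------------------------------------------

def _dose_pattern(pattern: str, x_mm: np.ndarray, y_mm: np.ndarray,
                  size_mm: float) -> np.ndarray:
    """Analytic dose patterns, evaluated on a coordinate grid (Gy)."""
    xx, yy = np.meshgrid(x_mm, y_mm)
    half = size_mm / 2.0
    if pattern == "uniform":
        return np.full(xx.shape, 1.0)
    if pattern == "wedge":
        # linear ramp 0.2 -> 1.8 Gy across the grid (steady gradient)
        return 0.2 + 1.6 * (xx + half) / size_mm
    if pattern == "peaked_fff":
        # flattening-filter-free-like: peaked centre, soft shoulder
        r2 = xx ** 2 + yy ** 2
        profile = 1.0 + 0.15 * np.exp(-r2 / (2 * (0.35 * half) ** 2))
        edge = (1 / (1 + np.exp((np.abs(xx) - 0.9 * half) / 2.0))
                * 1 / (1 + np.exp((np.abs(yy) - 0.9 * half) / 2.0)))
        return profile * edge
    if pattern == "multi_gaussian":
        centres = [(-0.4, -0.3, 0.9), (0.35, 0.1, 1.0), (-0.1, 0.45, 0.7),
                   (0.2, -0.45, 0.8)]
        dose = np.full(xx.shape, 0.05)
        for fx, fy, amp in centres:
            dose += amp * np.exp(-(((xx - fx * half) ** 2 + (yy - fy * half) ** 2)
                                   / (2 * (0.22 * half) ** 2)))
        return dose
    raise ValueError(f"unknown dose pattern {pattern!r}")


def make_dose_pair(pattern: str = "multi_gaussian",
                   dose_scale_pct: float = 0.0,
                   shift_mm: tuple[float, float] = (0.0, 0.0),
                   noise_pct: float = 0.0,
                   spacing_mm: float = 2.5,
                   size_mm: float = 100.0,
                   seed: int = 0) -> tuple[DoseGrid, DoseGrid]:
    """Generate a (reference, evaluated) dose-grid pair.

    The evaluated grid is the reference pattern with exactly the stated
    perturbation: a global dose rescale of ``dose_scale_pct`` percent, a
    rigid spatial shift of ``shift_mm`` (applied analytically, so there is
    no resampling error), and multiplicative Gaussian noise of
    ``noise_pct`` percent.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be > 0")
    n = int(round(size_mm / spacing_mm)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    ref = _dose_pattern(pattern, coords, coords, size_mm)
    ev = _dose_pattern(pattern, coords - shift_mm[0], coords - shift_mm[1], size_mm)
    ev = ev * (1.0 + dose_scale_pct / 100.0)
    if noise_pct > 0:
        rng = np.random.default_rng(seed)
        ev = ev * (1.0 + rng.normal(0.0, noise_pct / 100.0, ev.shape))
    origin = (float(coords[0]), float(coords[0]))
    return (DoseGrid(ref, (spacing_mm, spacing_mm), origin),
            DoseGrid(ev, (spacing_mm, spacing_mm), origin))


# ---------------------------------------------------------------------------
# Chamber-reading series for the dosimetry chain
# ---------------------------------------------------------------------------

@dataclass
class ChamberSeriesSim:
    """Simulated electrometer reading sets with known truth.

    Reading units are arbitrary electrometer units per 100 MU; the
    calibration coefficient ``n_dw`` converts corrected readings to Gy.
    Reference influence conditions are used (T = 20 C, P = 101.325 kPa,
    symmetric polarity, saturated two-voltage readings), so the correction
    chain is exercised at its unity fixed points while the beam-quality /
    output truth is carried by the reading ratios.
    """

    truth: dict
    n_dw: float
    k_bq: float
    mu: float
    readings_d10_g0: np.ndarray   # 10 cm depth, gantry 0  (TPR20,10 denominator)
    readings_d20_g0: np.ndarray   # 20 cm depth, gantry 0  (TPR20,10 numerator)
    readings_d5_g0: np.ndarray    # 5 cm depth, gantry 0   (TPR10,5 denominator)
    readings_d10_g0b: np.ndarray  # 10 cm depth, gantry 0  (TPR10,5 numerator)
    readings_d10_g90: np.ndarray  # 10 cm depth, gantry 90 (output series)
    temperature_c: float = 20.0
    pressure_kpa: float = 101.325


def simulate_chamber_series(truth: dict | None = None,
                            noise_cv: float = 0.003,
                            n: int = 7,
                            seed: int = 0,
                            n_dw: float = 0.005,
                            k_bq: float = 0.992) -> ChamberSeriesSim:
    """Simulate the reading sets of the beam-quality / output session.

    ``truth`` supplies ``tpr_20_10``, ``tpr_10_5`` and ``output_gy_per_100mu``
    (defaults 0.705 / 0.858 / 1.000); ``noise_cv`` is the relative SD of
    each individual reading.  Applying the dosimetry chain to the returned
    sets recovers the truth within sampling error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t = {"tpr_20_10": 0.705, "tpr_10_5": 0.858, "output_gy_per_100mu": 1.000}
    if truth:
        t.update(truth)
    rng = np.random.default_rng(seed)

    def series(mean: float, size: int) -> np.ndarray:
        vals = np.full(size, mean)
        if noise_cv > 0:
            vals = vals * (1.0 + rng.normal(0.0, noise_cv, size))
        return vals

    # G90 reading at 10 cm such that the corrected, depth-transferred dose
    # equals the truth output at 5 cm.
    d10_gy = t["output_gy_per_100mu"] * t["tpr_10_5"]
    m10_g90 = d10_gy / (k_bq * n_dw)
    # G0 ladder for the TPR ratios (arbitrary common scale).
    m5_g0 = 200.0
    m10_g0 = m5_g0 * t["tpr_10_5"]
    m20_g0 = m10_g0 * t["tpr_20_10"]

    return ChamberSeriesSim(
        truth=t, n_dw=n_dw, k_bq=k_bq, mu=100.0,
        readings_d10_g0=series(m10_g0, n),
        readings_d20_g0=series(m20_g0, n),
        readings_d5_g0=series(m5_g0, n),
        readings_d10_g0b=series(m10_g0, n),
        readings_d10_g90=series(m10_g90, n),
    )
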