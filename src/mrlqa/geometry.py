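"""Projection geometry shared by the phantom simulator and the image analyses.

Conventions (used everywhere in this package):

* IEC61217 fixed coordinates: +X to the patient's left, +Y craniocaudal
  (into the bore), +Z up.  The gantry rotates about Y; at 0 deg the source
  is above the isocentre and the beam travels in -Z, at 90 deg it travels
  in -X.
* The transverse isocentre plane is the X-Z plane; 2-vectors below are
  (x, z) in millimetres unless noted.
* Panel coordinates: the u axis is horizontal on the imager and increases
  with +X at gantry 0 (it co-rotates with the gantry); the v axis maps to
  +Y.  Pixel (0, 0) is the top-left corner; physical panel coordinates are
  millimetres at the panel plane, relative to the central pixel (the pixel
  the beam central axis strikes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "MachineGeometry",
    "GantryAngle",
    "PortalImage",
    "project_length",
    "inverse_project",
    "beam_direction",
    "panel_u_direction",
    "bb_panel_coordinate",
]


class GeometryError(ValueError):
    """Raised for non-physical geometry inputs (non-positive lengths etc.)."""


@dataclass(frozen=True)
class MachineGeometry:
    """Ring-gantry machine geometry.

    Parameters
    ----------
    sad_cm :
        Source-axis distance.  The default (143.5 cm) is the Elekta
        Unity-class value; the isocentre sits inside the MR bore.
    sid_cm :
        Source-to-imager distance of the fixed megavoltage panel.  Not a
        published machine constant, so it must come from configuration;
        the default is a realistic value for a panel mounted diametrically
        opposite the source on the gantry ring.
    pixel_pitch_mm :
        Detector pixel pitch at the panel plane.
    panel_extent_cm :
        Maximum imaged field at the isocentre plane, (width, height).
    central_pixel_uv :
        (u, v) pixel coordinates of the beam central axis at gantry 0.
    """

    sad_cm: float = 143.5
    sid_cm: float = 265.0
    pixel_pitch_mm: float = 0.4
    panel_extent_cm: tuple[float, float] = (22.0, 9.5)
    central_pixel_uv: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sad_cm <= 0:
            raise GeometryError(f"sad_cm must be > 0, got {self.sad_cm}")
        if self.sid_cm <= self.sad_cm:
            raise GeometryError(
                f"sid_cm ({self.sid_cm}) must exceed sad_cm ({self.sad_cm})"
            )
        if self.pixel_pitch_mm <= 0:
            raise GeometryError("pixel_pitch_mm must be > 0")
        if min(self.panel_extent_cm) <= 0:
            raise GeometryError("panel_extent_cm components must be > 0")

    @property
    def magnification(self) -> float:
        """Panel magnification M = SID / SAD (> 1)."""
        return self.sid_cm / self.sad_cm

    @property
    def pixel_pitch_at_iso_mm(self) -> float:
        """Pixel pitch back-projected to the isocentre plane."""
        return self.pixel_pitch_mm / self.magnification


@dataclass(frozen=True)
class GantryAngle:
    """Gantry angle in degrees, normalised to [0, 360), IEC61217 sense."""

    degrees: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "degrees", float(self.degrees) % 360.0)

    @property
    def radians(self) -> float:
        return float(np.deg2rad(self.degrees))


@dataclass
class PortalImage:
    """A 2-D portal (MV imager) frame plus its acquisition geometry.

    ``pixels`` is row-major with row index = v (top to bottom) and column
    index = u; higher pixel values mean more transmitted signal, so dense
    objects (ballbearings) appear as intensity dips.
    """

    pixels: np.ndarray
    angle: GantryAngle
    geometry: MachineGeometry
    central_pixel_uv: tuple[float, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PortalImage pixels must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_to_panel_mm(self, u_px: float, v_px: float) -> tuple[float, float]:
        """Pixel indices -> panel mm relative to the central pixel."""
        cu, cv = self.central_pixel_uv
        p = self.geometry.pixel_pitch_mm
        return ((u_px - cu) * p, (v_px - cv) * p)


def project_length(length_at_iso_cm: float, distance_cm: float,
                   geom: MachineGeometry) -> float:
    """Scale a field dimension from the isocentre plane to ``distance_cm``.

    Divergent-beam similar triangles: L(d) = L(iso) * d / SAD.
    """
    if length_at_iso_cm <= 0:
        raise GeometryError("length must be > 0")
    if distance_cm <= 0:
        raise GeometryError("distance must be > 0")
    return length_at_iso_cm * distance_cm / geom.sad_cm


def inverse_project(length_at_distance_cm: float, distance_cm: float,
                    geom: MachineGeometry) -> float:
    """Field dimension at the isocentre plane that projects to the given
    dimension at ``distance_cm`` (e.g. the field to set at isocentre so a
    chamber lowered below isocentre sees a 10 x 10 cm^2 field)."""
    if length_at_distance_cm <= 0:
        raise GeometryError("length must be > 0")
    if distance_cm <= 0:
        raise GeometryError("distance must be > 0")
    return length_at_distance_cm * geom.sad_cm / distance_cm


def beam_direction(angle: GantryAngle | float) -> np.ndarray:
    """Unit beam travel direction in the (x, z) plane.

    0 deg -> (0, -1) (from above, travelling down); 90 deg -> (-1, 0).
    """
    if not isinstance(angle, GantryAngle):
        angle = GantryAngle(angle)
    t = angle.radians
    return np.array([-np.sin(t), -np.cos(t)])


def panel_u_direction(angle: GantryAngle | float) -> np.ndarray:
    """Unit vector along the panel u axis, expressed in the (x, z) plane.

    Perpendicular to the beam; equals +X at gantry 0 and co-rotates with
    the gantry, so (u_hat, d_hat) is a right-handed pair for every angle.
    """
    if not isinstance(angle, GantryAngle):
        angle = GantryAngle(angle)
    t = angle.radians
    return np.array([np.cos(t), -np.sin(t)])


def bb_panel_coordinate(offset_mm: tuple[float, float] | np.ndarray,
                        angle: GantryAngle | float,
                        geom: MachineGeometry,
                        exact: bool = False) -> float:
    """Panel u displacement (mm, relative to the central pixel) of a point
    offset from the isocentre in the transverse plane.

    With ``exact=False`` the thin-object approximation u = M * w is used,
    where w is the component of the offset perpendicular to the beam.  With
    ``exact=True`` the full perspective projection is applied, accounting
    for the depth of the point along the beam:
    u = w * SID / (SAD + l), l = component along the beam direction.
    """
    p = np.asarray(offset_mm, dtype=float)
    u_hat = panel_u_direction(angle)
    w = float(p @ u_hat)
    if not exact:
        return w * geom.magnification
    d_hat = beam_direction(angle)
    ell_cm = float(p @ d_hat) / 10.0  # depth beyond isocentre, cm
    return w * geom.sid_cm / (geom.sad_cm + ell_cm)
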