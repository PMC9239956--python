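"""MV radiation-isocentre determination from per-projection ballbearing shifts.

At each gantry angle the measured displacement of the ballbearing peak from
the imager's central pixel is back-projected (divided by the panel
magnification) into the transverse isocentre plane, giving one beam central
axis line per projection.  The MV isocentre is the centre of the smallest
circle touched or crossed by every axis line — the Chebyshev point of the
line set — and its diameter (twice the minimax point-to-line distance) is
the machine alignment metric, conventionally checked against a 1.00 mm
tolerance for ring-gantry MR-linacs.

The minimax fit is a linear program in (cx, cz, t):

    minimise t  subject to  |n_i . c - b_i| <= t   for every line i,

where n_i is the line's unit normal and b_i = n_i . p_i for any point p_i
on the line.  This is solved exactly with ``scipy.optimize.linprog``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .geometry import GantryAngle, MachineGeometry, beam_direction, panel_u_direction

__all__ = [
    "BeamAxisLine",
    "IsocentreResult",
    "displacement_to_axis_line",
    "fit_isocentre",
    "run_isocentre_analysis",
    "DEFAULT_EXCLUDED_ANGLES",
]

logger = logging.getLogger(__name__)

#: Gantry angles (deg) skipped during the isocentre sequence: 10/20 are
#: blocked by the cryostat cross-over pipe, 60/300 suffer couch-edge
#: distortion through the ballbearing image.
DEFAULT_EXCLUDED_ANGLES = frozenset({10.0, 20.0, 60.0, 300.0})

#: Background subtraction is applied for projections inside the arcs where
#: couch edges and the QA platform distort the image: the lateral arcs
#: 130 deg down to 50 deg and 310 deg down to 230 deg (each traversed in
#: decreasing angle, i.e. the spans around 90 deg and 270 deg).
DISTORTION_ARCS = ((130.0, 50.0), (310.0, 230.0))


class InsufficientCoverageError(ValueError):
    """Raised when too few / too degenerate axis lines are supplied."""


@dataclass(frozen=True)
class BeamAxisLine:
    """A beam central axis in the transverse (x, z) plane.

    ``point`` is the perpendicular foot of the line from the origin, i.e.
    the measured perpendicular offset vector; ``direction`` is the unit
    beam travel direction.
    """

    angle: GantryAngle
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            d = d / n
        object.__setattr__(self, "direction", d)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal (the panel-u direction for this projection)."""
        dx, dz = self.direction
        return np.array([-dz, dx])

    def distance_to(self, pt: Sequence[float]) -> float:
        return abs(float((np.asarray(pt, dtype=float) - self.point) @ self.normal))


@dataclass
class IsocentreResult:
    """Chebyshev-fit isocentre: centre, diameter and per-line residuals."""

    center: np.ndarray
    diameter: float
    per_line_residuals: np.ndarray
    n_projections: int
    excluded_angles: tuple[float, ...] = ()
    failed_angles: tuple[float, ...] = field(default_factory=tuple)

    def within_tolerance(self, tolerance_mm: float = 1.00) -> bool:
        return self.diameter <= tolerance_mm


def displacement_to_axis_line(u_mm_at_panel: float,
                              angle: GantryAngle | float,
                              geom: MachineGeometry) -> BeamAxisLine:
    """Back-project a panel displacement into a transverse axis line.

    The perpendicular offset at the isocentre plane is u / M with
    M = SID/SAD; the line runs along the beam direction for that angle.
    """
    if not isinstance(angle, GantryAngle):
        angle = GantryAngle(angle)
    w = u_mm_at_panel / geom.magnification
    point = w * panel_u_direction(angle)
    return BeamAxisLine(angle=angle, point=point, direction=beam_direction(angle))


def _angular_span_deg(lines: Sequence[BeamAxisLine]) -> float:
    """Largest pairwise separation of line orientations, folded to [0, 180)."""
    orient = sorted({round(ln.angle.degrees % 180.0, 6) for ln in lines})
    if len(orient) < 2:
        return 0.0
    return orient[-1] - orient[0]


def fit_isocentre(lines: Sequence[BeamAxisLine]) -> IsocentreResult:
    """Fit the minimax (Chebyshev) isocentre of a set of beam axis lines.

    Returns the centre minimising the maximum point-to-line distance and
    the diameter = 2x that distance.  Deterministic for a fixed input.

    Raises
    ------
    InsufficientCoverageError
        Fewer than 3 lines, or all lines (anti)parallel.
    """
    lines = list(lines)
    if len(lines) < 3:
        raise InsufficientCoverageError(
            f"need >= 3 axis lines, got {len(lines)}")
    if _angular_span_deg(lines) <= 1e-9:
        raise InsufficientCoverageError(
            "insufficient angular coverage: all axis lines are parallel")

    normals = np.array([ln.normal for ln in lines])          # (n, 2)
    offsets = np.array([float(ln.normal @ ln.point) for ln in lines])

    # LP variables x = (cx, cz, t): minimise t s.t. +-(N c - b) <= t
    n = len(lines)
    c_obj = np.array([0.0, 0.0, 1.0])
    a_ub = np.vstack([
        np.column_stack([normals, -np.ones(n)]),
        np.column_stack([-normals, -np.ones(n)]),
    ])
    b_ub = np.concatenate([offsets, -offsets])
    res = linprog(c_obj, A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None), (None, None), (0, None)],
                  method="highs")
    if not res.success:  # pragma: no cover - highs is robust on these LPs
        raise RuntimeError(f"isocentre LP failed: {res.message}")

    center = res.x[:2]
    residuals = np.abs(normals @ center - offsets)
    diameter = 2.0 * float(residuals.max(initial=0.0))
    return IsocentreResult(
        center=center,
        diameter=diameter,
        per_line_residuals=residuals,
        n_projections=n,
    )


def in_distortion_arc(angle_deg: float,
                      arcs: Iterable[tuple[float, float]] = DISTORTION_ARCS) -> bool:
    """True if the gantry angle lies in an arc where couch-edge / platform
    distortion warrants background subtraction.  Arcs are (start, stop)
    traversed in decreasing angle, so (130, 50) spans 50..130 deg while
    (50, 130) would span the complement through 0."""
    a = angle_deg % 360.0
    for start, stop in arcs:
        if start > stop:
            if stop <= a <= start:
                return True
        else:  # traversal passes through 0: [0, start] u [stop, 360)
            if a <= start or a >= stop:
                return True
    return False


def run_isocentre_analysis(images: Sequence["object"],
                           geom: MachineGeometry | None = None,
                           excluded_angles: Iterable[float] = DEFAULT_EXCLUDED_ANGLES,
                           background_subtraction: str = "auto",
                           roi_half_width_mm: float = 15.0) -> IsocentreResult:
    """Full pipeline: locate the ballbearing on every projection, back-project
    and fit the isocentre.

    Parameters
    ----------
    images :
        Sequence of :class:`~mrlqa.geometry.PortalImage`, each carrying its
        gantry angle.
    geom :
        Geometry; defaults to the geometry of the first image.
    excluded_angles :
        Gantry angles (deg) dropped before analysis (logged).
    background_subtraction :
        "auto" (only inside the couch-distortion arcs), "always" or "never".
    roi_half_width_mm :
        Half-width of the search region about the central pixel, at the
        panel plane.

    Images whose ballbearing cannot be localised are reported in
    ``failed_angles``; the fit proceeds while >= 3 usable lines remain.
    """
    from .bb_analysis import AmbiguousPeakError, TruncatedPeakError, locate_bb

    if not images:
        raise InsufficientCoverageError("no images supplied")
    if geom is None:
        geom = images[0].geometry
    excluded = {float(a) % 360.0 for a in excluded_angles}

    lines: list[BeamAxisLine] = []
    dropped: list[float] = []
    failed: list[float] = []
    for img in images:
        a = img.angle.degrees
        if a in excluded:
            logger.info("excluding gantry angle %.1f deg from isocentre fit", a)
            dropped.append(a)
            continue
        if background_subtraction == "always":
            subtract = True
        elif background_subtraction == "never":
            subtract = False
        else:
            subtract = in_distortion_arc(a)
        try:
            loc = locate_bb(img, roi_half_width_mm=roi_half_width_mm,
                            background_subtraction=subtract)
        except (AmbiguousPeakError, TruncatedPeakError, ValueError) as exc:
            logger.warning("localisation failed at %.1f deg: %s", a, exc)
            failed.append(a)
            continue
        lines.append(displacement_to_axis_line(loc.u_mm, img.angle, geom))

    if len(lines) < 3:
        raise InsufficientCoverageError(
            f"only {len(lines)} usable projections "
            f"(failed at angles {sorted(failed)})")
    result = fit_isocentre(lines)
    result.excluded_angles = tuple(sorted(dropped))
    result.failed_angles = tuple(sorted(failed))
    return result
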