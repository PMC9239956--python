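"""Ballbearing localisation and gantry-angle reproducibility from portal images.

The workhorse is sub-pixel peak localisation: a pixel-intensity profile
through the ballbearing is inverted (so the transmission dip becomes a
positive peak), a structured background is removed by subtracting the
average of companion profiles taken just above and below the ballbearing,
and the peak centre is taken as the midpoint of the two half-maximum
crossings (each located by linear interpolation between bracketing
samples).  The half-maximum level is ``baseline + (peak - baseline)/2``
with the baseline estimated as the median of the outer 20% of the profile,
which is robust to residual background ramps.

Gantry-angle reproducibility compares an image of the ballbearing ring
against a baseline (nominally gantry 0) image: RMS profile difference,
changes in the separations of peripheral ballbearing peaks, and an
"eclipse score" measuring how cleanly the diametrically opposed pair on
the beam axis superimposes.  These metrics are zero/unity for identical
images and grow monotonically with a deliberate gantry-angle offset; they
quantify reproducibility, not the absolute gantry angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .geometry import PortalImage

__all__ = [
    "Profile", "BBLocation",
    "extract_profile", "subtract_background", "fwhm_center", "locate_bb",
    "gantry_reproducibility", "peripheral_peaks",
    "TruncatedPeakError", "AmbiguousPeakError",
]


class TruncatedPeakError(ValueError):
    """The half-maximum level is not crossed on one side of the peak."""


class AmbiguousPeakError(ValueError):
    """More than one disjoint region exceeds the half-maximum level."""


@dataclass
class Profile:
    """A 1-D intensity profile with physical coordinates.

    ``samples`` are inverted pixel values (ballbearings appear as positive
    peaks); ``coordinates_mm`` are strictly increasing and uniformly
    spaced, in mm at the panel plane relative to the central pixel.
    """

    samples: np.ndarray
    coordinates_mm: np.ndarray
    axis: str = "horizontal"
    source_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.coordinates_mm = np.asarray(self.coordinates_mm, dtype=float)
        if self.samples.shape != self.coordinates_mm.shape:
            raise ValueError("samples and coordinates must have equal length")
        if len(self.coordinates_mm) > 1:
            d = np.diff(self.coordinates_mm)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
                raise ValueError("coordinates must be strictly increasing and uniform")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class BBLocation:
    """Sub-pixel ballbearing centre.

    ``u_mm``/``v_mm`` are panel-plane millimetres relative to the central
    pixel (divide by the magnification for isocentre-plane mm).
    """

    u_px: float
    v_px: float
    u_mm: float
    v_mm: float
    fwhm_u_mm: float
    fwhm_v_mm: float
    peak_height: float
    background_corrected: bool


def extract_profile(image: PortalImage, axis: str, index: int,
                    span: tuple[int, int] | None = None) -> Profile:
    """Extract an inverted pixel profile from a portal image.

    ``axis="horizontal"`` reads row ``index`` (profile along u);
    ``axis="vertical"`` reads column ``index``.  ``span`` optionally
    restricts the profile to pixel indices [lo, hi) along its length.
    Values are inverted (max_pixel - value) so attenuation dips become
    positive peaks; coordinates come from the pixel pitch, relative to the
    central pixel.
    """
    nv, nu = image.shape
    cu, cv = image.central_pixel_uv
    pitch = image.geometry.pixel_pitch_mm
    if axis == "horizontal":
        if not 0 <= index < nv:
            raise IndexError(f"row {index} outside image with {nv} rows")
        values = image.pixels[index, :].astype(float)
        coords = (np.arange(nu) - cu) * pitch
    elif axis == "vertical":
        if not 0 <= index < nu:
            raise IndexError(f"column {index} outside image with {nu} columns")
        values = image.pixels[:, index].astype(float)
        coords = (np.arange(nv) - cv) * pitch
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    if span is not None:
        lo, hi = span
        if lo < 0 or hi > len(values) or lo >= hi:
            raise IndexError(f"span {span} outside profile of length {len(values)}")
        values = values[lo:hi]
        coords = coords[lo:hi]
    inverted = float(image.pixels.max()) - values
    return Profile(inverted, coords, axis=axis, source_index=index)


def subtract_background(bb_profile: Profile, above: Profile,
                        below: Profile) -> Profile:
    """Remove structured background: bb - mean(above, below), element-wise.

    The companion profiles run parallel to the ballbearing profile at
    equal offsets above and below it, so any background that is affine in
    the image coordinates cancels exactly.
    """
    for other in (above, below):
        if (len(other) != len(bb_profile)
                or not np.allclose(other.coordinates_mm, bb_profile.coordinates_mm)):
            raise ValueError("background profiles must share the ballbearing "
                             "profile's coordinates")
    corrected = bb_profile.samples - 0.5 * (above.samples + below.samples)
    return Profile(corrected, bb_profile.coordinates_mm.copy(),
                   axis=bb_profile.axis, source_index=bb_profile.source_index)


def _baseline(samples: np.ndarray) -> float:
    """Median of the outer 20% of the profile (10% from each end)."""
    n = len(samples)
    k = max(1, int(round(0.1 * n)))
    return float(np.median(np.concatenate([samples[:k], samples[-k:]])))


def fwhm_center(profile: Profile) -> tuple[float, float]:
    """Sub-pixel peak centre and width from half-maximum crossings.

    Returns ``(center_mm, fwhm_mm)``.  The half-max level is
    baseline + (peak - baseline)/2; each crossing is linearly interpolated
    between the bracketing samples; the centre is the midpoint of the two
    crossings (for a flat-topped plateau this is the plateau midpoint).

    Raises
    ------
    TruncatedPeakError
        The half-max level is not crossed on one side (peak at the edge).
    AmbiguousPeakError
        Multiple disjoint regions exceed the half-max level (e.g. two
        ballbearings in the profile).
    """
    y = profile.samples
    x = profile.coordinates_mm
    if len(y) < 3:
        raise TruncatedPeakError("profile too short to bracket a peak")
    base = _baseline(y)
    peak = float(y.max())
    if peak <= base:
        raise TruncatedPeakError("no peak above baseline")
    half = base + (peak - base) / 2.0

    above = y > half
    # count disjoint super-half-max regions; > 1 is ambiguous
    n_regions = int(above[0]) + int((np.diff(above.astype(int)) == 1).sum())
    if n_regions > 1:
        raise AmbiguousPeakError(
            f"{n_regions} disjoint regions exceed the half-maximum")
    if n_regions == 0:  # pragma: no cover - peak>half guarantees one region
        raise TruncatedPeakError("no samples above the half-maximum")
    if above[0] or above[-1]:
        raise TruncatedPeakError("peak truncated at the profile edge")

    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    # left crossing between i0-1 and i0; right between i1 and i1+1
    xl = x[i0 - 1] + (half - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * (x[i0] - x[i0 - 1])
    xr = x[i1] + (half - y[i1]) / (y[i1 + 1] - y[i1]) * (x[i1 + 1] - x[i1])
    return (0.5 * (xl + xr), xr - xl)


def _coarse_peak(patch: np.ndarray) -> tuple[int, int]:
    """Row, column of the dominant dip in an image patch (min of a lightly
    smoothed inverted patch)."""
    from scipy.ndimage import uniform_filter
    inv = patch.max() - patch.astype(float)
    sm = uniform_filter(inv, size=3, mode="nearest")
    r, c = np.unravel_index(int(np.argmax(sm)), sm.shape)
    return int(r), int(c)


def locate_bb(image: PortalImage,
              roi: tuple[int, int, int, int] | None = None,
              roi_half_width_mm: float = 15.0,
              background_subtraction: bool = True,
              background_offset_px: int | None = None) -> BBLocation:
    """Locate one ballbearing with sub-pixel accuracy.

    The u coordinate comes from the background-subtracted horizontal
    profile through the ballbearing, the v coordinate from the vertical
    profile.  ``roi`` is (row_lo, row_hi, col_lo, col_hi) in pixels; by
    default a square of half-width ``roi_half_width_mm`` (panel mm) about
    the central pixel.  Background companion rows are offset by
    ``background_offset_px`` (default: 2.5x the projected central-BB
    radius) above and below the ballbearing row.
    """
    nv, nu = image.shape
    cu, cv = image.central_pixel_uv
    pitch = image.geometry.pixel_pitch_mm
    if roi is None:
        h = int(round(roi_half_width_mm / pitch))
        roi = (max(0, int(cv) - h), min(nv, int(cv) + h + 1),
               max(0, int(cu) - h), min(nu, int(cu) + h + 1))
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= nv and 0 <= c0 < c1 <= nu):
        raise IndexError(f"roi {roi} outside image of shape {image.shape}")

    pr, pc = _coarse_peak(image.pixels[r0:r1, c0:c1])
    row, col = r0 + pr, c0 + pc

    if background_offset_px is None:
        bb_r_mm = 5.0 * image.geometry.magnification  # central 10 mm BB
        background_offset_px = int(round(2.5 * bb_r_mm / pitch))

    horiz = extract_profile(image, "horizontal", row, span=(c0, c1))
    if background_subtraction:
        up = min(nv - 1, row + background_offset_px)
        dn = max(0, row - background_offset_px)
        above = extract_profile(image, "horizontal", dn, span=(c0, c1))
        below = extract_profile(image, "horizontal", up, span=(c0, c1))
        horiz = subtract_background(horiz, above, below)
    u_mm, fwhm_u = fwhm_center(horiz)

    vert = extract_profile(image, "vertical", col, span=(r0, r1))
    v_mm, fwhm_v = fwhm_center(vert)

    u_px = cu + u_mm / pitch
    v_px = cv + v_mm / pitch
    if not (0 <= u_px < nu and 0 <= v_px < nv):  # pragma: no cover
        raise ValueError("fitted centre outside image bounds")
    peak_h = float(horiz.samples.max() - _baseline(horiz.samples))
    return BBLocation(u_px=u_px, v_px=v_px, u_mm=u_mm, v_mm=v_mm,
                      fwhm_u_mm=fwhm_u, fwhm_v_mm=fwhm_v,
                      peak_height=peak_h,
                      background_corrected=background_subtraction)


# ---------------------------------------------------------------------------
# Gantry-angle reproducibility
# ---------------------------------------------------------------------------

def _central_row_profile(image: PortalImage) -> Profile:
    """Inverted horizontal profile through the centre of the dip nearest
    the image centre (the eclipsed ballbearing pair).

    The row is the intensity-weighted centroid of the above-half-maximum
    part of the central dip, which is stable against noise and against
    ties inside a saturated (fully attenuated) ballbearing core.
    """
    nv, nu = image.shape
    cu, cv = image.central_pixel_uv
    band = max(3, nv // 8)
    r0 = max(0, int(cv) - band)
    r1 = min(nv, int(cv) + band + 1)
    c_half = max(3, nu // 8)
    c0 = max(0, int(cu) - c_half)
    c1 = min(nu, int(cu) + c_half + 1)
    patch = image.pixels[r0:r1, c0:c1].astype(float)
    inv = patch.max() - patch
    mask = inv > 0.5 * inv.max()
    weights = (inv * mask).sum(axis=1)
    row = int(round(float((np.arange(len(weights)) * weights).sum()
                          / weights.sum())))
    return extract_profile(image, "horizontal", r0 + row)


def _normalise(p: np.ndarray) -> np.ndarray:
    rng = p.max() - p.min()
    if rng == 0:
        return np.zeros_like(p)
    return (p - p.min()) / rng


def peripheral_peaks(profile: Profile, min_rel_height: float = 0.3,
                     min_rel_prominence: float = 0.15,
                     min_separation_mm: float = 1.5) -> np.ndarray:
    """Coordinates (mm) of the resolved ballbearing peaks in a profile.

    A peak counts as resolved when it rises above ``min_rel_height`` of
    the profile maximum with at least ``min_rel_prominence`` relative
    prominence and sits more than ``min_separation_mm`` from its
    neighbours — partially eclipsed pairs merge into a single peak until a
    gantry offset pulls them apart.
    """
    y = profile.samples - _baseline(profile.samples)
    if y.max() <= 0:
        return np.array([])
    dx = float(np.diff(profile.coordinates_mm).mean()) if len(profile) > 1 else 1.0
    peaks, _ = find_peaks(y, height=min_rel_height * y.max(),
                          prominence=min_rel_prominence * y.max(),
                          distance=max(1, int(round(min_separation_mm / dx))))
    return profile.coordinates_mm[peaks]


def _half_max_extent(profile: Profile, window_mm: float = 12.0) -> float:
    """Total extent (mm) between the outermost half-max crossings of the
    central feature, tolerant of a split (double-peaked) feature."""
    x, y = profile.coordinates_mm, profile.samples
    sel = np.abs(x) <= window_mm
    xs, ys = x[sel], y[sel]
    base = _baseline(ys)
    half = base + (ys.max() - base) / 2.0
    above = np.flatnonzero(ys > half)
    if len(above) == 0:
        return 0.0
    i0, i1 = above[0], above[-1]
    xl = xs[i0] if i0 == 0 else xs[i0 - 1] + (half - ys[i0 - 1]) / (ys[i0] - ys[i0 - 1]) * (xs[i0] - xs[i0 - 1])
    xr = xs[i1] if i1 == len(ys) - 1 else xs[i1] + (half - ys[i1]) / (ys[i1 + 1] - ys[i1]) * (xs[i1 + 1] - xs[i1])
    return float(xr - xl)


def gantry_reproducibility(image: PortalImage,
                           baseline_image: PortalImage) -> dict:
    """Compare a ballbearing-ring image with a baseline image.

    Returns a dict with

    * ``rms_profile_diff`` — RMS difference of the min-max normalised
      central horizontal profiles (0 for identical images);
    * ``peripheral_separation_diffs`` — per-gap changes (mm) in the
      separations between adjacent resolved ballbearing peaks relative to
      the baseline image;
    * ``eclipse_score`` — in [0, 1]; the ratio of the baseline central
      feature's half-max extent to the image's (1 when the diametrically
      opposed pair superimposes as cleanly as in the baseline, decreasing
      as a gantry-angle offset pulls the pair apart).

    Raises ``ValueError`` when the two images resolve different numbers of
    peripheral peaks (listing the counts).
    """
    p_img = _central_row_profile(image)
    p_base = _central_row_profile(baseline_image)
    n = min(len(p_img), len(p_base))
    rms = float(np.sqrt(np.mean(
        (_normalise(p_img.samples[:n]) - _normalise(p_base.samples[:n])) ** 2)))

    pk_img = peripheral_peaks(p_img)
    pk_base = peripheral_peaks(p_base)
    if len(pk_img) != len(pk_base):
        raise ValueError(
            f"peripheral peak mismatch: image resolves {len(pk_img)} peaks, "
            f"baseline {len(pk_base)}")
    sep_img = np.diff(pk_img)
    sep_base = np.diff(pk_base)
    sep_diffs = (sep_img - sep_base).tolist()

    ext_img = _half_max_extent(p_img)
    ext_base = _half_max_extent(p_base)
    if ext_img <= 0 or ext_base <= 0:
        eclipse = 0.0
    else:
        eclipse = float(min(1.0, ext_base / ext_img))

    return {
        "rms_profile_diff": rms,
        "peripheral_separation_diffs": sep_diffs,
        "eclipse_score": eclipse,
    }
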