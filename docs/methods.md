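# Methods

This note records the models behind each analysis, the parameters that
matter (with units and defaults), the numerical conventions, and what the
synthetic phantom simulator does and does not emulate.

## Coordinates and machine geometry

IEC61217 throughout: +X patient-left, +Y craniocaudal, +Z up; the gantry
rotates about Y, with the beam travelling −Z at 0° and −X at 90°. The
transverse isocentre plane is X–Z. On the imager, the u axis increases
with +X at gantry 0 and co-rotates with the gantry; v maps to +Y. Pixel
(0, 0) is top-left; physical panel coordinates are millimetres relative
to the central pixel (the pixel the beam central axis strikes).

`MachineGeometry` defaults describe a Unity-class machine: SAD 143.5 cm,
maximum imaged field 22.0 × 9.5 cm² at the isocentre plane. The
source-to-imager distance and the panel pixel pitch are not published
machine constants; the defaults (SID 265.0 cm, pitch 0.4 mm, giving
M ≈ 1.85 and an iso-plane pitch of ≈ 0.22 mm) are realistic for a fixed
MV panel mounted diametrically opposite the source, and both are
configurable — simulator and analyses always share one geometry object,
so every test is self-consistent under a change of these values. Full
similar-triangle magnification is used everywhere; no parallel-ray
approximation.

## Ballbearing localisation

Profiles are inverted (max − value) so the transmission dip of a
ballbearing is a positive peak. The u coordinate comes from a horizontal
profile through the ballbearing with the average of two companion
profiles (taken a fixed offset above and below, default 2.5× the
projected ballbearing radius) subtracted; any background affine in the
image coordinates cancels exactly under this subtraction, which is the
point — couch edges and the QA platform add structured background over
the lateral gantry arcs (130°→50° and 310°→230°), where subtraction is
enabled automatically.

The peak centre is the midpoint of the two half-maximum crossings, each
linearly interpolated between bracketing samples. The half-maximum level
is baseline + (peak − baseline)/2 with the baseline taken as the median
of the outer 20% of the profile — robust to residual ramps; the
convention for a flat-topped (saturated) peak is the plateau midpoint.
Error contracts are strict: a peak whose half-level is not crossed on
both sides raises "truncated", more than one disjoint super-half-max
region raises "ambiguous" (e.g. two ballbearings in the ROI).

## MV isocentre

Each projection's measured displacement u (panel mm, relative to the
central pixel) back-projects to a beam axis line with perpendicular
offset u/M in the isocentre plane. The isocentre is defined as the
Chebyshev point of the line set — the centre minimising the maximum
point-to-line distance — and the diameter as twice that minimax
distance: the smallest circle touched or crossed by every axis. This is
the standard radiation-isocentre construction; commercial tools do not
publish their statistic, so the definition here is validated not against
vendor numbers but against an exhaustive grid-search oracle (0.005 mm
resolution) in the test suite. The fit is solved exactly as a linear
program in (c_x, c_z, t) with HiGHS, deterministic for fixed input.

The fit is 2-D in the transverse plane (ring gantry); the longitudinal
(v) displacement is reported per projection but excluded from the
diameter. Projections at 10°, 20° (cryostat cross-over pipe) and 60°,
300° (couch-edge distortion through the ballbearing) are excluded by
default, with a log entry; both rotation senses are pooled into one fit.
Analysis continues while at least three usable, non-parallel lines
remain, with failed angles listed in the result. The default acquisition
list (10° steps, 0–360° inclusive, both senses, exclusions applied)
contains 65 projections.

## Gantry-angle reproducibility

With one ballbearing ring centred at the isocentre, the diametrically
opposed pair lying along the beam axis projects to a single eclipsed
image at every 30° position; a gantry-angle error δ separates the pair
by ≈ 2rδM at the panel (r = ring radius). The comparison against a
baseline image reports: the RMS difference of min–max-normalised central
profiles; the change in separation of each adjacent pair of resolved
peripheral peaks (mm); and an eclipse score, the ratio of the baseline
central feature's half-maximum extent to the image's (1 when the pair
superimposes as cleanly as the baseline). These metrics quantify
*reproducibility* — the absolute gantry angle is deliberately not
computed, since a profile comparison cannot determine it. Visual
thresholds are replaced by the simulator-calibrated behaviour checked in
the tests: a 0.3° error separates the eclipsed pair by more than the
rendering blur width while 0.1° does not, and a 1.0° error splits
mirrored peripheral pairs into resolved doublets.

## Gamma index

Reference-to-evaluation convention: each unsuppressed reference point
interrogates the evaluated distribution. The evaluated grid is
bilinearly interpolated; the minimisation runs over a square offset
lattice of step 0.1 × DTA within a search radius of 3 × DTA, followed by
a local refinement pass at one tenth of that step around each point's
best offset, which removes the coarse-lattice discretisation error (a
plain 0.1 × DTA lattice can overestimate γ by ~0.04 even on smooth
fields). Normalisation: "global" divides dose differences by the
criterion percentage of the reference maximum, "local" by the same
percentage of the point's own reference dose. Suppression applies to
reference dose relative to the reference maximum (default 10%);
suppressed points are excluded from the pass rate. Boundary convention:
γ ≤ 1.0 passes (with a 1e-9 float guard, so an exactly-on-criterion
uniform offset passes). Grid spacing coarser than the DTA logs a
warning.

The test-suite oracle is an independent exhaustive search at one tenth
of the interpolation step with its own bilinear interpolation. Oracle
agreement is asserted on spatially correlated random fields
(Gaussian-filtered noise): physical dose maps are smooth at the
millimetre scale, and uncorrelated white-noise "dose" would exercise
gradients no measurement produces, where any lattice-based gamma is
interpolation-limited.

## Reference dosimetry

TRS-398 forms, implemented from the protocol:

* k_TP = (273.2 + T)/(273.2 + 20.0) × 101.325/P (T in °C, P in kPa).
* k_pol = (|M⁺| + |M⁻|)/(2|M⁺|), the routine polarity being positive.
* k_s from the pulsed-beam two-voltage quadratic
  a₀ + a₁(M₁/M₂) + a₂(M₁/M₂)², coefficients tabulated against the
  voltage ratio V₁/V₂ ∈ [2, 5] and interpolated linearly. Pulsed-beam
  coefficients are the appropriate choice for an FFF linac.
* The combined magnetic-field correction is k_B,Q = k_B,M,Q × c_B̃,
  rounded to 3 decimals — the precision at which these factors are
  applied. Bundled chamber constants: k_B,M,Q = 0.995 / 0.996 for the
  two PTW 30013 chambers (S/N 10765, 11298) at 5.0 cm and 0.999 for both
  at 10.0 cm; c_B̃ = 0.995 (constant over 5–25 cm depth); published
  combined factor 0.992.
* TPR = mean(deep)/mean(shallow); with multiple sessions the SD is the
  session-wise SD of per-session ratios.
* Output: D(10) = M·k_TP·k_pol·k_s·k_B,Q·N_D,w per 100 MU at gantry 90,
  D(5) = D(10)/TPR₁₀,₅; the gantry-0 expectation applies the machine's
  cryostat transmission difference (+0.5% by default, so a 1.000 Gy
  calibration implies 1.005 Gy per 100 MU at gantry 0).
* No FFF non-uniformity correction is applied (the 10 cm-depth profile
  is flat over the chamber's sensitive length), and no reference-chamber
  cross-normalisation enters the magnetic-field factor determination.

Reporting precision follows the field's custom: k-factors and TPR to 3
decimals, output to 3 decimals, attenuation to 1 decimal (percent).

Anterior-coil attenuation is 100 × (1 − M_with/M_without) per gantry
angle; slightly negative values are legitimate (noise exceeding a small
effect) and flagged rather than clipped. The summary mean excludes
angles of zero attenuation by default — at those angles the beam misses
the coil entirely, so they carry no information about the coil. The
quoted ± is the sample SD of the per-angle values. The bundled
commissioning dataset (15° steps, 75°–285°) gives (0.6 ± 0.1)% measured
and (0.8 ± 0.1)% TPS-calculated under this rule.

## The synthetic phantom simulator

The simulator emulates the MV alignment phantom: a central 10.0 mm
ballbearing and two rings of twelve 4.0 mm ballbearings at 30.0°
spacing, offset ±3.5 cm longitudinally. The ring radius is not a
published constant; the default 6.5 cm fits the 22.0 cm imaged field and
no analysis depends on its absolute value. Each ballbearing is rendered
by full perspective projection (per-ballbearing magnification
SID/(SAD + depth)) as a transmission dip 1 − exp(−μ·chord) with
μ = 2.0 mm⁻¹: deliberately near-opaque, so the integrated deficit tracks
the projected area (∝ diameter²) within 5% — the spheres are treated as
markers, not as a radiation-transport model. Edges are blurred with a
Gaussian of σ = 0.4 mm (expressed at the isocentre plane) emulating
source size and detector response; additive Gaussian pixel noise and a
background model (affine field plus couch-edge step/ramp bands) complete
the image; output is 16-bit with all randomness driven by one seed
(bit-identical re-renders).

The wobble model separates two physically distinct effects. A fixed
in-plane offset displaces the phantom and leaves all axis lines
concurrent (the fit recovers the offset as the centre with zero
diameter). Harmonic terms of order k displace the ballbearing
perpendicular to the beam by amp·cos(kθ + phase) at gantry angle θ; a
k = 0 harmonic of amplitude A offsets every axis by A, making the truth
lines exactly tangent to a circle of radius A — the truth diameter is
2A by construction, which is how the recovery tests know their ground
truth. The series ground-truth diameter is always computed as the
minimax diameter of the true lines (validated against the grid-search
oracle), never assumed.

Dose-map pairs are generated from analytic patterns (uniform, wedge,
FFF-like peaked, multi-Gaussian) with perturbations applied exactly:
dose rescale as a multiplication, spatial shift by evaluating the
analytic pattern at shifted coordinates (no resampling error),
multiplicative noise from the seed. Chamber-reading series place the
truth in the reading ratios (TPR₂₀,₁₀ 0.705, TPR₁₀,₅ 0.858, output
1.000 Gy/100 MU by default — the commissioning operating point) with
multiplicative noise of CV 0.3%, the reproducibility the G90 technique
achieves in practice; influence quantities sit at reference conditions
so the correction chain is exercised at its unity fixed points.

What the simulator does **not** emulate: radiation transport and
scatter, the energy dependence of detector response, cryostat angular
transmission structure, MR-related distortion, panel sag or central-pixel
drift with gantry angle, and couch attenuation beyond the additive edge
artifact. Passing tests therefore demonstrate the correctness of the
*analysis chain* (localisation, back-projection, fitting, gamma
arithmetic, dosimetry algebra) under controlled truth — not the
machine-specific magnitudes of those physical effects, which only
measurements provide.

## Numerical conventions and degenerate inputs

* Isocentre fit: < 3 lines or all lines parallel → error; the LP is
  otherwise bounded and exact. Adding a line never decreases the minimax
  radius; translation and rotation equivariance are asserted in tests.
* FWHM: profiles shorter than 3 samples, peaks at the profile edge and
  multi-region half-max sets raise typed errors rather than returning
  numbers.
* Gamma: non-overlapping grids raise; a reference grid with no positive
  dose raises; local normalisation treats unsuppressed zero-dose points
  as infinite-denominator (γ driven by distance alone).
* Dose-grid text format: three-line header (nx/ny, spacing, origin), 6
  significant figures; write∘read∘write is byte-stable.
* Chamber constants are validated into (0.9, 1.1); temperatures outside
  −10…50 °C and non-positive pressures are rejected.

## Problem sizes used in the checked examples

Tests and the worked example run at the scale a desk check affords: the
isocentre pipeline on the 65-projection simulated series at ~0.2 mm
iso-plane sampling; oracle cross-checks on 100 random line sets and on
11 × 11 dose grids; dosimetry recovery on 7-session series replicated
over 5 seeds. These sizes were chosen so the full suite re-derives every
oracle from scratch in well under a minute of compute per check.

## Known limitations

* The eclipse/reproducibility thresholds are simulator-calibrated; on a
  real machine the mapping from metric to degrees depends on phantom
  positioning reproducibility, which must be established locally.
* The isocentre statistic (minimax diameter) need not equal the
  statistic of commercial analysis tools, whose definitions are
  unpublished; cross-method differences of ~0.1 mm are expected and the
  package makes no attempt to calibrate to any vendor value.
* "Local" gamma normalisation divides by the *reference* dose at the
  point; tools that normalise by the evaluated dose will differ in high
  gradient regions.
* The dosimetry chain adjudicates nothing about the depth dependence of
  the magnetic-field factors; it computes the combined factors at
  whichever depth's chamber factor it is given.
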