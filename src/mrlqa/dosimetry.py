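"""Beam-quality and reference-output dosimetry for a 1.5 T MR-linac.

Implements the reference-dosimetry chain for a Farmer-type ionisation
chamber in a transverse 7 MV FFF beam with the magnetic field parallel to
the chamber axis:

* TRS-398 influence-quantity corrections — air density (k_tp), polarity
  (k_pol) and ion recombination (k_s, pulsed-beam two-voltage method);
* magnetic-field corrections — the detector response factor k_B,M,Q and
  the dose conversion factor c_B, whose product is the combined factor
  k_B,Q applied to readings;
* beam quality via tissue-phantom ratios (TPR20,10 as the quality
  specifier; TPR10,5 as the depth-transfer ratio used to express a 10 cm
  deep measurement at the 5 cm calibration depth);
* machine output in Gy per 100 MU from gantry-90 readings, with the
  gantry-0 expectation obtained from the known cryostat transmission
  difference between the two angles;
* anterior-coil attenuation statistics from paired with/without-coil
  readings over gantry angle.

Reported quantities follow the field's customary precision: correction
factors and TPR to 3 decimals, attenuation to 1 decimal (percent), output
to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ChamberReading", "CorrectionSet", "BeamQuality", "AttenuationRecord",
    "k_tp", "k_pol", "k_s", "combine_kb", "tpr",
    "output_from_g90", "expected_g0_output",
    "attenuation_pct", "mean_attenuation",
    "KBMQ_FACTORS", "C_B_TILDE", "COIL_ATTENUATION_COMMISSIONING",
]

T_REF_C = 20.0
P_REF_KPA = 101.325
ZERO_C_K = 273.2  # protocol convention

#: Chamber-specific magnetic-field response factors (k_B,M,Q, field parallel
#: to the chamber axis) measured for two PTW 30013 Farmer chambers during a
#: Unity-class commissioning, by serial number and depth (cm).
KBMQ_FACTORS: dict[tuple[str, float], float] = {
    ("10765", 5.0): 0.995,
    ("11298", 5.0): 0.996,
    ("10765", 10.0): 0.999,
    ("11298", 10.0): 0.999,
}

#: Dose conversion factor c_B for the same configuration (constant over
#: 5-25 cm depth).
C_B_TILDE = 0.995

#: Anterior-coil attenuation vs gantry angle from the same commissioning:
#: measured (chamber ratio) and TPS-calculated percentages at 15 deg steps,
#: 75 deg through 285 deg. The beam misses the coil entirely at 75/285 deg.
COIL_ATTENUATION_COMMISSIONING: list[tuple[float, float, float]] = [
    # (gantry deg, measured %, calculated %)
    (75.0, 0.0, 0.0),
    (60.0, 0.6, 0.8),
    (45.0, 0.6, 0.9),
    (30.0, 0.5, 1.0),
    (0.0, 0.5, 0.7),
    (345.0, 0.4, 0.8),
    (330.0, 0.7, 0.9),
    (315.0, 0.6, 0.8),
    (300.0, 0.6, 0.7),
    (285.0, 0.0, 0.0),
]

# TRS-398 pulsed-beam two-voltage quadratic coefficients:
# k_s = a0 + a1 (M1/M2) + a2 (M1/M2)^2, tabulated vs voltage ratio V1/V2,
# interpolated linearly in the ratio.
_KS_PULSED = {
    2.0: (2.337, -3.636, 2.299),
    2.5: (1.474, -1.587, 1.114),
    3.0: (1.198, -0.875, 0.677),
    3.5: (1.080, -0.542, 0.463),
    4.0: (1.022, -0.363, 0.341),
    5.0: (0.975, -0.188, 0.214),
}


@dataclass
class ChamberReading:
    """One corrected-output measurement point (per exposure or averaged)."""

    charge_or_dose: float
    mu: float = 100.0
    temperature_c: float = T_REF_C
    pressure_kpa: float = P_REF_KPA
    voltage_nominal: float | None = None
    voltage_reduced: float | None = None
    reading_reduced: float | None = None
    reading_opposite_polarity: float | None = None
    gantry_angle_deg: float = 0.0
    depth_cm: float = 10.0
    field_cm: tuple[float, float] = (10.0, 10.0)
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.pressure_kpa <= 0:
            raise ValueError("pressure must be > 0")
        if not -10.0 <= self.temperature_c <= 50.0:
            raise ValueError(f"unphysical temperature {self.temperature_c} C")


@dataclass
class CorrectionSet:
    """The multiplicative correction chain for one chamber.

    ``k_bq`` may be given directly (a published combined factor) or
    composed from the chamber factor ``k_bmq`` and the dose conversion
    factor ``c_b`` via :func:`combine_kb`.  ``n_dw`` converts the fully
    corrected reading to dose to water (Gy per reading unit).
    """

    k_tp: float | None = None
    k_pol: float | None = None
    k_s: float | None = None
    k_bmq: float | None = None
    c_b: float | None = None
    k_bq: float | None = None
    n_dw: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_tp", "k_pol", "k_s", "k_bmq", "c_b", "k_bq"):
            v = getattr(self, name)
            if v is not None and not 0.9 < v < 1.1:
                raise ValueError(f"{name} = {v} outside the plausible (0.9, 1.1)")
        if self.k_bq is None and self.k_bmq is not None and self.c_b is not None:
            self.k_bq = combine_kb(self.k_bmq, self.c_b)

    def missing(self) -> list[str]:
        out = [n for n in ("k_tp", "k_pol", "k_s", "k_bq", "n_dw")
               if getattr(self, n) is None]
        return out


@dataclass
class BeamQuality:
    tpr_20_10: float
    tpr_10_5: float
    n_sessions: int = 1
    sd: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.tpr_20_10, self.tpr_10_5):
            if not 0.0 < v < 1.0:
                raise ValueError("TPR values must lie in (0, 1)")
        if self.tpr_10_5 <= self.tpr_20_10:
            raise ValueError("tpr_10_5 must exceed tpr_20_10")


@dataclass
class AttenuationRecord:
    gantry_angle_deg: float
    reading_with: float
    reading_without: float

    @property
    def attenuation_pct(self) -> float:
        return attenuation_pct(self.reading_with, self.reading_without)


def k_tp(temperature_c: float, pressure_kpa: float,
         t_ref_c: float = T_REF_C, p_ref_kpa: float = P_REF_KPA) -> float:
    """Air-density correction (273.2 + T)/(273.2 + T0) * P0/P."""
    if pressure_kpa <= 0:
        raise ValueError("pressure must be > 0")
    return ((ZERO_C_K + temperature_c) / (ZERO_C_K + t_ref_c)
            * p_ref_kpa / pressure_kpa)


def k_pol(m_plus: float, m_minus: float) -> float:
    """Polarity correction (|M+| + |M-|) / (2 |M|), M = routine polarity (+)."""
    if m_plus == 0 or m_minus == 0:
        raise ValueError("polarity readings must be nonzero")
    return (abs(m_plus) + abs(m_minus)) / (2.0 * abs(m_plus))


def k_s(m_v1: float, m_v2: float, voltage_ratio: float) -> float:
    """Recombination correction, pulsed-beam two-voltage method.

    ``m_v1`` is the reading at the normal (higher) voltage V1, ``m_v2`` at
    the reduced voltage V2; ``voltage_ratio`` = V1/V2 must exceed 1.  The
    quadratic in M1/M2 uses the pulsed-beam coefficient table,
    interpolated linearly in the voltage ratio.
    """
    if voltage_ratio <= 1:
        raise ValueError("voltage_ratio must be > 1")
    if m_v1 == 0 or m_v2 == 0:
        raise ValueError("readings must be nonzero")
    ratios = sorted(_KS_PULSED)
    if not ratios[0] <= voltage_ratio <= ratios[-1]:
        raise ValueError(
            f"voltage_ratio {voltage_ratio} outside tabulated range "
            f"[{ratios[0]}, {ratios[-1]}]")
    hi = next(r for r in ratios if r >= voltage_ratio)
    lo = max(r for r in ratios if r <= voltage_ratio)
    if hi == lo:
        a = _KS_PULSED[lo]
    else:
        f = (voltage_ratio - lo) / (hi - lo)
        a = tuple((1 - f) * x + f * y
                  for x, y in zip(_KS_PULSED[lo], _KS_PULSED[hi]))
    r = m_v1 / m_v2
    return a[0] + a[1] * r + a[2] * r ** 2


def combine_kb(k_bmq: float, c_b: float) -> float:
    """Combined magnetic-field correction k_B,Q = k_B,M,Q * c_B, rounded to
    3 decimals (the precision at which these factors are applied)."""
    for name, v in (("k_bmq", k_bmq), ("c_b", c_b)):
        if not 0.9 < v < 1.1:
            raise ValueError(f"{name} = {v} outside the plausible (0.9, 1.1)")
    return round(k_bmq * c_b, 3)


def tpr(readings_deep: Sequence[float] | Sequence[Sequence[float]],
        readings_shallow: Sequence[float] | Sequence[Sequence[float]]
        ) -> tuple[float, float]:
    """Tissue-phantom ratio: mean(deep) / mean(shallow).

    Accepts flat reading lists (one session) or lists of per-session
    lists; with multiple sessions the returned SD is the session-wise SD
    of the per-session ratios (ddof 1), otherwise 0.
    """
    def sessions(x):
        if len(x) == 0:
            raise ValueError("need >= 1 reading")
        if np.ndim(x[0]) == 0:
            return [np.asarray(x, dtype=float)]
        return [np.asarray(s, dtype=float) for s in x]

    deep, shallow = sessions(readings_deep), sessions(readings_shallow)
    if len(deep) != len(shallow):
        raise ValueError("deep and shallow must have the same session count")
    ratios = []
    for d, s in zip(deep, shallow):
        ms = float(s.mean())
        if ms == 0:
            raise ValueError("zero mean shallow reading")
        ratios.append(float(d.mean()) / ms)
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return mean, sd


def output_from_g90(reading_10cm: ChamberReading, corr: CorrectionSet,
                    tpr_10_5: float) -> float:
    """Machine output (Gy per 100 MU) at 5 cm depth from a gantry-90
    reading at 10 cm depth.

    D(10) = M * k_tp * k_pol * k_s * k_BQ * N_DW, scaled to 100 MU, then
    transferred to the calibration depth with the gantry-0 depth ratio:
    D(5) = D(10) / TPR10,5.
    """
    if not 0.0 < tpr_10_5 < 1.0:
        raise ValueError("tpr_10_5 must lie in (0, 1)")
    missing = corr.missing()
    if missing:
        raise ValueError(f"correction set incomplete, missing: {', '.join(missing)}")
    d10 = (reading_10cm.charge_or_dose * corr.k_tp * corr.k_pol * corr.k_s
           * corr.k_bq * corr.n_dw) * (100.0 / reading_10cm.mu)
    return d10 / tpr_10_5


def expected_g0_output(g90_output_gy: float,
                       cryostat_diff_pct: float = 0.5) -> float:
    """Expected gantry-0 output given the gantry-90 output and the known
    cryostat transmission difference (G0 higher by ``cryostat_diff_pct``
    percent), rounded to 3 decimals."""
    if g90_output_gy <= 0:
        raise ValueError("output must be > 0")
    return round(g90_output_gy * (1.0 + cryostat_diff_pct / 100.0), 3)


def attenuation_pct(with_reading: float, without_reading: float) -> float:
    """Attenuation 100 * (1 - with/without), percent.  May legitimately be
    slightly negative when measurement noise exceeds the effect."""
    if without_reading == 0:
        raise ValueError("without-coil reading must be nonzero")
    return 100.0 * (1.0 - with_reading / without_reading)


def mean_attenuation(values_pct: Sequence[float] | Sequence[AttenuationRecord],
                     exclude_zero: bool = True) -> tuple[float, float]:
    """Mean +- sample SD of per-angle attenuations, rounded to 1 decimal.

    With ``exclude_zero`` (default) angles with attenuation <= 0 are
    dropped — at those gantry angles the beam does not intersect the coil,
    so they carry no information about the coil's attenuation.
    """
    vals = [v.attenuation_pct if isinstance(v, AttenuationRecord) else float(v)
            for v in values_pct]
    if exclude_zero:
        vals = [v for v in vals if v > 0]
    if not vals:
        raise ValueError("no records remain after zero-attenuation exclusion")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return round(mean, 1), round(sd, 1)
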