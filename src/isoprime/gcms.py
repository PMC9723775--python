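"""GC/MS calibration and headspace CO2 quantification.

Converts per-channel detector responses (m/z 44 = 12CO2, m/z 45 = 13CO2)
into mixing ratios via an ordinary-least-squares calibration line, and then
into micromoles of CO2-C per gram dry soil via the ideal gas law applied to
the vial headspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

R_GAS = 8.31446261815324  # J mol-1 K-1


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line response = slope * ppm + intercept for one m/z channel."""

    channel: int
    slope: float
    intercept: float
    r_squared: float
    ppm_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"non-positive calibration slope: {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise CalibrationError(f"r_squared outside [0, 1]: {self.r_squared}")
        if self.ppm_range[0] >= self.ppm_range[1]:
            raise CalibrationError(f"degenerate ppm range: {self.ppm_range}")

    def to_ppm(self, response):
        """Invert the line; no clipping or range check here."""
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope

    def is_extrapolated(self, ppm):
        lo, hi = self.ppm_range
        ppm = np.asarray(ppm, dtype=float)
        return (ppm < lo) | (ppm > hi)

    @classmethod
    def identity(cls, channel: int, ppm_range=(0.0, 1e6)) -> "CalibrationCurve":
        """Unit curve for inputs already expressed in ppm."""
        return cls(channel=channel, slope=1.0, intercept=0.0, r_squared=1.0,
                   ppm_range=ppm_range)


@dataclass(frozen=True)
class VialGeometry:
    """Serum-vial geometry and conditions for headspace gas accounting.

    Default mirrors a 120-mL vial holding 10 g dry soil; headspace volume
    defaults to vial volume minus soil volume at a bulk density of
    1.0 g/mL (110 mL).
    """

    vial_volume_ml: float = 120.0
    soil_mass_g: float = 10.0
    headspace_volume_ml: float | None = None
    temperature_k: float = 298.15
    pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        if self.headspace_volume_ml is None:
            object.__setattr__(
                self, "headspace_volume_ml", self.vial_volume_ml - self.soil_mass_g / 1.0
            )
        if self.headspace_volume_ml > self.vial_volume_ml:
            raise ValueError("headspace volume exceeds vial volume")
        for name in ("vial_volume_ml", "soil_mass_g", "headspace_volume_ml",
                     "temperature_k", "pressure_kpa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CO2Measurement:
    """Quantified 12CO2/13CO2 for one vial at one sampling time."""

    vial_id: str
    time_h: float
    ppm12: float
    ppm13: float
    umol12_per_g: float
    umol13_per_g: float
    atom_fraction_13c: float | None
    clipped: bool = False
    extrapolated: bool = False


def fit_calibration(standards, channel: int) -> CalibrationCurve:
    """OLS calibration line from (ppm, response) standards.

    Parameters
    ----------
    standards : sequence of (ppm, response) pairs
        At least two distinct ppm levels are required.
    """
    arr = np.asarray(list(standards), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need at least two (ppm, response) standards")
    ppm, resp = arr[:, 0], arr[:, 1]
    if np.allclose(ppm, ppm[0]):
        raise CalibrationError("degenerate design: all standards at the same ppm")
    res = stats.linregress(ppm, resp)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return CalibrationCurve(
        channel=channel,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        ppm_range=(float(ppm.min()), float(ppm.max())),
    )


def umol_from_ppm(ppm, geom: VialGeometry):
    """Micromoles of gas in the headspace at a given mixing ratio (ppm)."""
    ppm = np.asarray(ppm, dtype=float)
    # n = x * P V / (R T); P in Pa, V in m3 -> mol, expressed in umol
    mol = (ppm * 1e-6) * (geom.pressure_kpa * 1e3) * (geom.headspace_volume_ml * 1e-6) \
        / (R_GAS * geom.temperature_k)
    return mol * 1e6


def ppm_from_umol(umol, geom: VialGeometry):
    """Inverse of :func:`umol_from_ppm`."""
    umol = np.asarray(umol, dtype=float)
    mol = umol * 1e-6
    x = mol * R_GAS * geom.temperature_k \
        / ((geom.pressure_kpa * 1e3) * (geom.headspace_volume_ml * 1e-6))
    return x * 1e6


def atom_fraction(umol12, umol13):
    """13C atom fraction of a CO2 pool: umol13 / (umol12 + umol13)."""
    total = umol12 + umol13
    if np.ndim(total) == 0:
        if total <= 0:
            raise ValueError("atom fraction undefined for zero total CO2")
        return umol13 / total
    total = np.asarray(total, dtype=float)
    out = np.full(total.shape, np.nan)
    ok = total > 0
    out[ok] = np.asarray(umol13, dtype=float)[ok] / total[ok]
    return out


def quantify_headspace(reading, cal44: CalibrationCurve, cal45: CalibrationCurve,
                       geom: VialGeometry) -> CO2Measurement:
    """Convert one headspace reading into umol CO2-C per g dry soil.

    ``reading`` is a mapping with keys ``vial_id``, ``time_h`` and either
    detector responses (``response44``/``response45``) or mixing ratios
    (``ppm44``/``ppm45``; quantified through identity curves upstream).
    """
    if cal44 is None or cal45 is None:
        raise CalibrationError("calibration curves required for both channels")
    vial_id = str(reading.get("vial_id", ""))
    time_h = float(reading.get("time_h", np.nan))

    def _ppm(cal, resp_key, ppm_key):
        if resp_key in reading and reading[resp_key] is not None and \
                not (isinstance(reading[resp_key], float) and np.isnan(reading[resp_key])):
            return float(cal.to_ppm(reading[resp_key]))
        if ppm_key in reading:
            return float(reading[ppm_key])
        raise CalibrationError(f"reading missing both {resp_key} and {ppm_key}")

    ppm12 = _ppm(cal44, "response44", "ppm44")
    ppm13 = _ppm(cal45, "response45", "ppm45")
    extrapolated = bool(cal44.is_extrapolated(ppm12) | cal45.is_extrapolated(ppm13))
    clipped = False
    if ppm12 < 0 or ppm13 < 0:
        warnings.warn(
            f"negative back-calculated ppm clipped to 0 for vial {vial_id!r}",
            stacklevel=2,
        )
        clipped = True
        ppm12, ppm13 = max(ppm12, 0.0), max(ppm13, 0.0)
    umol12 = float(umol_from_ppm(ppm12, geom)) / geom.soil_mass_g
    umol13 = float(umol_from_ppm(ppm13, geom)) / geom.soil_mass_g
    total = umol12 + umol13
    frac = umol13 / total if total > 0 else None
    return CO2Measurement(
        vial_id=vial_id, time_h=time_h, ppm12=ppm12, ppm13=ppm13,
        umol12_per_g=umol12, umol13_per_g=umol13, atom_fraction_13c=frac,
        clipped=clipped, extrapolated=extrapolated,
    )


def quantify_table(readings: pd.DataFrame, cal44: CalibrationCurve,
                   cal45: CalibrationCurve, geom: VialGeometry) -> pd.DataFrame:
    """Vectorized :func:`quantify_headspace` over a headspace readings table.

    Carries through any design columns present (treatment, ecoplot,
    replicate) so downstream partitioning can stratify.
    """
    rows = []
    carry = [c for c in ("treatment", "ecoplot", "replicate") if c in readings.columns]
    for _, rec in readings.iterrows():
        m = quantify_headspace(rec.to_dict(), cal44, cal45, geom)
        row = {
            "vial_id": m.vial_id,
            "time_h": m.time_h,
            "ppm12": m.ppm12,
            "ppm13": m.ppm13,
            "umol12_per_g": m.umol12_per_g,
            "umol13_per_g": m.umol13_per_g,
            "atom_fraction_13c": m.atom_fraction_13c,
            "clipped": m.clipped,
            "extrapolated": m.extrapolated,
        }
        for c in carry:
            row[c] = rec[c]
        rows.append(row)
    return pd.DataFrame(rows)
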