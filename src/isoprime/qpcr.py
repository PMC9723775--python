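"""RT-qPCR standard curves, copy-number quantification, and censoring.

Transcript copies follow the log-linear response Ct = intercept +
slope x log10(copies); amplification efficiency is 10^(-1/slope) - 1.
Copies below the assay detection limit (~300 copies per uL) are reported
as non-detects, never as zeros, and ratios involving a censored target are
censored too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DETECTION_LIMIT = 300.0  # copies per uL

EFFICIENCY_FLAG_RANGE = (0.8, 1.1)


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10(copies) for one target."""

    target: str
    slope: float       # Ct per log10 copies; negative
    intercept: float   # Ct at one copy
    efficiency: float  # 10^(-1/slope) - 1
    r_squared: float
    flagged: bool      # efficiency outside the plausible range

    def copies_from_ct(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass
class ExpressionResult:
    sample_id: str
    copies: float | None
    below_detection: bool


def fit_standard_curve(dilution_series, target: str) -> StandardCurve:
    """Fit a standard curve from (copies, Ct) pairs.

    Requires at least three points spanning at least two orders of
    magnitude in copy number.  Efficiency outside (0.8, 1.1) is flagged
    but not rejected.
    """
    arr = np.asarray(list(dilution_series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise QpcrError("need at least three (copies, Ct) standards")
    copies, ct = arr[:, 0], arr[:, 1]
    if np.any(copies <= 0):
        raise QpcrError("standard copy numbers must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise QpcrError("standards must span at least two orders of magnitude")
    res = stats.linregress(logc, ct)
    slope = float(res.slope)
    if slope >= 0:
        raise QpcrError(f"standard curve slope must be negative, got {slope}")
    eff = 10.0 ** (-1.0 / slope) - 1.0
    flagged = not (EFFICIENCY_FLAG_RANGE[0] < eff < EFFICIENCY_FLAG_RANGE[1])
    if flagged:
        warnings.warn(
            f"{target}: amplification efficiency {eff:.1%} outside "
            f"{EFFICIENCY_FLAG_RANGE}", stacklevel=2,
        )
    r2 = float(res.rvalue**2)
    return StandardCurve(target=target, slope=slope, intercept=float(res.intercept),
                         efficiency=float(eff), r_squared=r2, flagged=flagged)


def quantify_copies(ct, curve: StandardCurve,
                    detection_limit: float = DEFAULT_DETECTION_LIMIT,
                    ) -> tuple[float | None, bool]:
    """Back-calculate copies from a Ct value with detection-limit censoring.

    Returns ``(copies, below_detection)``; missing Ct (None/NaN) or copies
    below the detection limit yield ``(None, True)``.
    """
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return None, True
    ct = float(ct)
    if not math.isfinite(ct):
        raise QpcrError(f"non-finite Ct: {ct}")
    copies = curve.copies_from_ct(ct)
    if copies < detection_limit:
        return None, True
    return copies, False


def relative_expression(target_results: pd.DataFrame,
                        reference_results: pd.DataFrame) -> pd.DataFrame:
    """Target/reference copy ratio per sample (e.g. pobA relative to 16S).

    Inputs need columns ``sample_id``, ``copies``, ``below_detection``.
    The ratio is censored (NaN, flag set) whenever either target is below
    detection.
    """
    for name, df in (("target", target_results), ("reference", reference_results)):
        need = {"sample_id", "copies", "below_detection"}
        if not need.issubset(df.columns):
            raise QpcrError(f"{name} results need columns {sorted(need)}")
    merged = target_results.merge(
        reference_results, on="sample_id", suffixes=("_target", "_ref"), how="left",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", "sample_id"].tolist()
        raise QpcrError(f"missing reference measurements for samples: {missing}")
    censored = merged["below_detection_target"] | merged["below_detection_ref"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = merged["copies_target"] / merged["copies_ref"]
    ratio = ratio.where(~censored, np.nan)
    return pd.DataFrame({
        "sample_id": merged["sample_id"],
        "copies_target": merged["copies_target"],
        "copies_reference": merged["copies_ref"],
        "ratio": ratio,
        "censored": censored,
    })


def quantify_plate(plate: pd.DataFrame,
                   detection_limit: float = DEFAULT_DETECTION_LIMIT,
                   ) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Fit per-target standard curves from a plate table and quantify samples.

    The plate table needs columns ``sample_id``, ``target``, ``ct``,
    ``is_standard`` and, for standards, ``copies``.  Returns the quantified
    sample rows and the fitted curves.
    """
    need = {"sample_id", "target", "ct", "is_standard"}
    if not need.issubset(plate.columns):
        raise QpcrError(f"plate needs columns {sorted(need)}")
    curves = {}
    rows = []
    for target, sub in plate.groupby("target"):
        standards = sub.loc[sub["is_standard"] & sub["ct"].notna()]
        if len(standards) < 3:
            raise QpcrError(f"{target}: not enough standards to fit a curve")
        curve = fit_standard_curve(
            list(zip(standards["copies"], standards["ct"])), target=str(target)
        )
        curves[str(target)] = curve
        for _, rec in sub.loc[~sub["is_standard"]].iterrows():
            copies, censored = quantify_copies(rec["ct"], curve, detection_limit)
            rows.append({
                "sample_id": rec["sample_id"], "target": target,
                "ct": rec["ct"],
                "copies": np.nan if copies is None else copies,
                "below_detection": censored,
            })
    return pd.DataFrame(rows), curves
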