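"""Internal-standard-normalized calibration curves and absolute
quantification (ng per mg tissue wet weight).

Calibration points are (known amount ng, peak-area ratio analyte/IS); the
curve is an ordinary least-squares line fitted on the pooled points of all
injections.  Concentrations of identified sterols are inverse-interpolated
from their own curve (level 1) or from a standard of the same sterol
subclass (level 2), scaled by the dilution factor and normalized to tissue
wet weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["CalibrationCurve", "QuantResult", "fit_calibration", "quantify"]


class CalibrationCurve(BaseEstimator):
    """OLS calibration line: area ratio = slope · amount + intercept.

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``range_`` (min/max calibrated amount, ng).  ``weighting="1/x"``
    applies inverse-concentration weights.
    """

    def __init__(self, analyte: str = "", internal_standard: str = "",
                 weighting: str | None = None):
        self.analyte = analyte
        self.internal_standard = internal_standard
        self.weighting = weighting

    def fit(self, amount_ng, ratio):
        x = np.asarray(amount_ng, dtype=float).ravel()
        y = np.asarray(ratio, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("amounts and ratios must align")
        if np.unique(x).size < 3:
            raise ValueError("calibration needs >= 3 distinct concentrations")
        if self.weighting == "1/x":
            w = 1.0 / np.where(x > 0, x, np.nan)
            if np.any(~np.isfinite(w)):
                raise ValueError("1/x weighting requires positive amounts")
        elif self.weighting is None:
            w = np.ones_like(x)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        W = np.diag(w)
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
        self.slope_, self.intercept_ = float(beta[0]), float(beta[1])
        if self.slope_ <= 0:
            raise ValueError(f"{self.analyte or 'calibration'}: non-positive slope "
                             f"({self.slope_:g}); curve unusable")
        yhat = A @ beta
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        self.range_ = (float(x.min()), float(x.max()))
        return self

    def inverse(self, ratio: float) -> tuple[float, str]:
        """Amount (ng) at an observed area ratio, plus a range flag
        (``"ok"`` / ``"below_range"`` / ``"above_range"``)."""
        amount = (float(ratio) - self.intercept_) / self.slope_
        lo, hi = self.range_
        flag = "ok"
        if amount < lo:
            flag = "below_range"
        elif amount > hi:
            flag = "above_range"
        return amount, flag


def fit_calibration(points: pd.DataFrame, analyte: str = "",
                    internal_standard: str = "",
                    weighting: str | None = None) -> CalibrationCurve:
    """Fit a curve from a points table with columns ``level_ng``, ``area``,
    ``is_area`` (all injections pooled)."""
    ratio = points["area"].astype(float) / points["is_area"].astype(float)
    return CalibrationCurve(analyte, internal_standard, weighting).fit(
        points["level_ng"].astype(float), ratio)


@dataclass(frozen=True)
class QuantResult:
    analyte: str
    sample: str
    concentration: float      # ng per mg tissue wet weight
    curve_used: str           # "own" | "subclass-surrogate"
    surrogate: str
    dilution: float
    flag: str                 # "ok" | "below_range" | "above_range"


def quantify(areas: pd.DataFrame,
             curves: Mapping[str, CalibrationCurve],
             tissue_mass_mg: float | Mapping[str, float],
             subclass_map: Mapping[str, str] | None = None,
             dilution: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Absolute quantification of analyte areas.

    ``areas``: long table with columns ``analyte``, ``sample``, ``area``,
    ``is_area``.  ``curves`` maps analyte names to fitted curves; analytes
    without their own curve fall back to the curve of the surrogate named in
    ``subclass_map`` (level-2 convention).  ``dilution`` maps analyte to the
    pre-injection dilution factor (default 1).  Analytes lacking IS areas or
    any usable curve are skipped with a warning.
    """
    results: list[QuantResult] = []
    for _, row in areas.iterrows():
        analyte = str(row["analyte"])
        sample = str(row.get("sample", ""))
        is_area = float(row["is_area"]) if pd.notna(row["is_area"]) else 0.0
        if is_area <= 0:
            warnings.warn(f"{analyte}/{sample}: missing or non-positive IS area; skipped")
            continue
        curve = curves.get(analyte)
        curve_used, surrogate = "own", ""
        if curve is None and subclass_map is not None:
            surrogate = subclass_map.get(analyte, "")
            curve = curves.get(surrogate)
            curve_used = "subclass-surrogate"
        if curve is None:
            warnings.warn(f"{analyte}: no calibration curve or surrogate; skipped")
            continue
        amount, flag = curve.inverse(float(row["area"]) / is_area)
        dil = float(dilution.get(analyte, 1.0)) if dilution else 1.0
        mass = tissue_mass_mg[sample] if isinstance(tissue_mass_mg, Mapping) else tissue_mass_mg
        conc = amount * dil / float(mass)
        if conc < 0 and flag == "ok":
            flag = "below_range"
        results.append(QuantResult(analyte, sample, conc, curve_used, surrogate, dil, flag))
    return pd.DataFrame([r.__dict__ for r in results])
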