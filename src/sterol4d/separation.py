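"""Isomer separability metrics and the m/z–CCS trend-line chemical space.

Two library sterols sharing an exact mass form an isomer pair.  Pair-level
separability is quantified by the percent CCS difference and by
chromatographic/mobility peak resolutions:

* ``CCS_diff = |CCS_A − CCS_B| / CCS_A × 100`` (A taken as the smaller CCS,
  giving the conservative larger percentage);
* one-dimensional resolution ``R_S = 2|pos_A − pos_B| / (W_A + W_B)`` with
  full base widths;
* two-dimensional LC-IM resolution ``R_S = sqrt(R_LC² + R_IM²)``.

The class-level chemical space is a power-law trend line ``CCS = a·mz^b``
with a 99% predictive interval
``Δy = z·s_yx·sqrt(1 + 1/n + (x − x̄)²/SS_x)``, used to filter annotations
whose CCS is implausible for a sterol of that mass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from . import chem
from .library import LibraryEntry, SterolLibrary

__all__ = [
    "ccs_difference", "ChromPeak", "resolution_1d", "resolution_2d",
    "IsomerPair", "assign_isomer_pairs", "summarize_separability",
    "CcsMzTrendline", "fit_trendline",
]


def ccs_difference(ccs_a: float, ccs_b: float) -> float:
    """Percent CCS difference |CCS_A − CCS_B| / CCS_A × 100."""
    if ccs_a <= 0 or ccs_b <= 0:
        raise ValueError("CCS values must be positive")
    return abs(ccs_a - ccs_b) / ccs_a * 100.0


def pair_ccs_difference(ccs_a: float, ccs_b: float) -> float:
    """Pair-level convention: denominator is the smaller CCS (conservative,
    larger percentage; order-independent)."""
    return ccs_difference(min(ccs_a, ccs_b), max(ccs_a, ccs_b))


@dataclass(frozen=True)
class ChromPeak:
    """A chromatographic (RT, s) or mobility (CCS, Å²) peak with its full
    width at base in the same units."""

    position: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")

    @classmethod
    def from_sigma(cls, position: float, sigma: float) -> "ChromPeak":
        """Gaussian peak: base width taken as 4σ."""
        return cls(position, 4.0 * sigma)


def resolution_1d(peak_a: ChromPeak, peak_b: ChromPeak) -> float:
    """One-dimensional peak resolution 2|Δposition| / (W_A + W_B)."""
    return 2.0 * abs(peak_a.position - peak_b.position) / (peak_a.width + peak_b.width)


def resolution_2d(rs_lc: float, rs_im: float) -> float:
    """Two-dimensional resolution of orthogonal LC and IM separations:
    the Euclidean norm sqrt(R_LC² + R_IM²)."""
    if rs_lc < 0 or rs_im < 0:
        raise ValueError("resolutions must be non-negative")
    return float(np.hypot(rs_lc, rs_im))


@dataclass(frozen=True)
class IsomerPair:
    entry_a: LibraryEntry
    entry_b: LibraryEntry
    mode: str                 # "derivatized" | "underivatized"
    mass_key: float
    ccs_diff: float
    rs_lc: float = np.nan
    rs_im: float = np.nan
    rs_2d: float = np.nan


def _mass_keys(entry: LibraryEntry, mode: str) -> list[float]:
    """Mass keys under the pairing mode.

    Derivatized: the derivatized neutral exact mass.  Underivatized: the
    detected-ion m/z values — [M+H]+ plus water-loss adducts up to the
    hydroxyl count, because in-source water loss can collapse distinct
    masses onto the same detected ion.
    """
    c = entry.compound
    if mode == "derivatized":
        return [chem.derivatized_mass(c.monoisotopic_mass, c.n_hydroxyl)]
    if mode == "underivatized":
        keys = [chem.adduct_mz(c.monoisotopic_mass, "[M+H]+")]
        if c.n_hydroxyl >= 1:
            keys.append(chem.adduct_mz(c.monoisotopic_mass, "[M+H-H2O]+"))
        if c.n_hydroxyl >= 2:
            keys.append(chem.adduct_mz(c.monoisotopic_mass, "[M+H-2H2O]+"))
        return keys
    raise ValueError(f"unknown isomer mode {mode!r}")


def assign_isomer_pairs(library: SterolLibrary, mode: str = "derivatized",
                        mass_tol: float = 0.005,
                        widths: pd.DataFrame | None = None) -> list[IsomerPair]:
    """All unordered pairs of distinct library compounds sharing a mass key
    within ``mass_tol`` (Da).

    ``widths`` optionally supplies peak widths (columns ``name``,
    ``w_rt_s``, ``w_ccs_A2``) from which LC/IM/2-D resolutions are filled;
    without widths the resolution fields stay NaN.
    """
    # one entry per compound (primary adduct) — pairing is compound-level
    seen: dict[str, LibraryEntry] = {}
    for e in library:
        seen.setdefault(e.compound.name, e)
    entries = list(seen.values())
    wmap = {}
    if widths is not None:
        wmap = widths.set_index("name")[["w_rt_s", "w_ccs_A2"]].to_dict("index")
    pairs: list[IsomerPair] = []
    for ea, eb in itertools.combinations(entries, 2):
        keys_a = _mass_keys(ea, mode)
        keys_b = _mass_keys(eb, mode)
        hit = next((ka for ka in keys_a for kb in keys_b if abs(ka - kb) <= mass_tol), None)
        if hit is None:
            continue
        rs_lc = rs_im = rs_2d = np.nan
        wa, wb = wmap.get(ea.compound.name), wmap.get(eb.compound.name)
        if wa and wb:
            rs_lc = resolution_1d(ChromPeak(ea.rt, wa["w_rt_s"]), ChromPeak(eb.rt, wb["w_rt_s"]))
            rs_im = resolution_1d(ChromPeak(ea.ccs, wa["w_ccs_A2"]), ChromPeak(eb.ccs, wb["w_ccs_A2"]))
            rs_2d = resolution_2d(rs_lc, rs_im)
        pairs.append(IsomerPair(ea, eb, mode, float(hit),
                                pair_ccs_difference(ea.ccs, eb.ccs),
                                rs_lc, rs_im, rs_2d))
    return pairs


def pairs_to_frame(pairs: Sequence[IsomerPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name_a": p.entry_a.compound.name, "name_b": p.entry_b.compound.name,
        "mode": p.mode, "mass_key": p.mass_key, "ccs_diff_pct": p.ccs_diff,
        "rs_lc": p.rs_lc, "rs_im": p.rs_im, "rs_2d": p.rs_2d,
    } for p in pairs])


def summarize_separability(pairs: Sequence[IsomerPair],
                           ccs_diff_threshold: float = 2.0,
                           rs_threshold: float = 1.0) -> dict[str, float]:
    """Percent of pairs exceeding the CCS-difference and resolution
    thresholds (resolution fractions over pairs with widths only)."""
    if not pairs:
        return {}
    df = pairs_to_frame(pairs)
    out = {
        "n_pairs": float(len(df)),
        "pct_ccs_diff_ge_threshold": 100.0 * float((df.ccs_diff_pct >= ccs_diff_threshold).mean()),
    }
    with_rs = df.dropna(subset=["rs_2d"])
    if len(with_rs):
        out["pct_rs_lc_ge_threshold"] = 100.0 * float((with_rs.rs_lc >= rs_threshold).mean())
        out["pct_rs_im_ge_threshold"] = 100.0 * float((with_rs.rs_im >= rs_threshold).mean())
        out["pct_rs_2d_ge_threshold"] = 100.0 * float((with_rs.rs_2d >= rs_threshold).mean())
    return out


class CcsMzTrendline(BaseEstimator, RegressorMixin):
    """Power-law trend line CCS = a·mz^b with a 99% predictive interval.

    Fitted by nonlinear least squares from the starting point
    (a0=1, b0=0.05).  Fitted attributes: ``a_``, ``b_``, ``r_`` (Pearson
    correlation of observed vs fitted), ``s_yx_`` (standard error of the
    estimate, Å²), ``ss_x_``, ``x_bar_``, ``n_``.

    Parameters
    ----------
    a0, b0 : float
        Optimizer starting point.
    z : float
        Normal quantile for the predictive interval (2.576 → 99%).
    ss_x_override : float or None
        Replaces the data-derived SS_x in the interval formula when an
        externally printed constant must be honoured.
    """

    def __init__(self, a0: float = 1.0, b0: float = 0.05, z: float = 2.576,
                 ss_x_override: float | None = None):
        self.a0 = a0
        self.b0 = b0
        self.z = z
        self.ss_x_override = ss_x_override

    def fit(self, mz, ccs):
        x = np.asarray(mz, dtype=float).ravel()
        y = np.asarray(ccs, dtype=float).ravel()
        if x.size != y.size or x.size < 3:
            raise ValueError("need at least 3 (mz, ccs) points")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("mz and ccs must be positive")
        try:
            (a, b), _ = curve_fit(lambda t, a, b: a * np.power(t, b), x, y,
                                  p0=(self.a0, self.b0), maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"trend-line fit did not converge: {exc}") from exc
        self.a_, self.b_ = float(a), float(b)
        yhat = self.a_ * np.power(x, self.b_)
        resid = y - yhat
        self.n_ = int(x.size)
        self.s_yx_ = float(np.sqrt(np.sum(resid**2) / (self.n_ - 2)))
        self.x_bar_ = float(np.mean(x))
        self.ss_x_ = float(np.sum((x - self.x_bar_) ** 2))
        sy = float(np.std(y))
        self.r_ = float(np.corrcoef(y, yhat)[0, 1]) if sy > 0 and np.std(yhat) > 0 else np.nan
        return self

    def predict(self, mz):
        x = np.asarray(mz, dtype=float)
        return self.a_ * np.power(x, self.b_)

    def predictive_interval(self, mz):
        """Half-width Δy(x) of the 99% predictive interval (Å²)."""
        ss_x = self.ss_x_ if self.ss_x_override is None else float(self.ss_x_override)
        if ss_x <= 0:
            raise ValueError("SS_x must be positive")
        x = np.asarray(mz, dtype=float)
        out = self.z * self.s_yx_ * np.sqrt(1.0 + 1.0 / self.n_ + (x - self.x_bar_) ** 2 / ss_x)
        return float(out) if out.ndim == 0 else out

    def contains(self, mz, ccs):
        """Whether (mz, ccs) lies inside the chemical space (|residual| ≤ Δy)."""
        mz = np.asarray(mz, dtype=float)
        ccs = np.asarray(ccs, dtype=float)
        inside = np.abs(ccs - self.predict(mz)) <= self.predictive_interval(mz)
        return bool(inside) if inside.ndim == 0 else inside


def fit_trendline(mz, ccs, a0: float = 1.0, b0: float = 0.05) -> CcsMzTrendline:
    """Functional wrapper over :class:`CcsMzTrendline`."""
    return CcsMzTrendline(a0=a0, b0=b0).fit(mz, ccs)
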