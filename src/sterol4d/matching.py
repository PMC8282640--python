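"""Four-dimensional identification: candidate scoring, MSI levels, RT
calibration and decoy-based FDR estimation.

A feature is matched against a library entry in four dimensions:

* MS1 m/z — a hard gate at 25 ppm;
* retention time — trapezoidal score on the absolute error in seconds
  (plateau inside ``rt_min``, zero beyond ``rt_max``);
* CCS — trapezoidal score on the percent error relative to the library CCS;
* MS/MS — reverse dot product against measured standard spectra, or the
  two-ion fragmentation-rule score against rule-predicted spectra.

The integrated score is the weighted sum 0.2·RT + 0.4·CCS + 0.4·MS/MS; an
identification is kept when the integrated score exceeds 0.6 (strictly) and
the MS/MS score reaches the tier cutoff.  Standard-library matches are MSI
level 1, extended-library matches level 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .features import Feature
from .fragments import predict_fragments
from .library import LibraryEntry, SterolLibrary
from .spectra import Spectrum

__all__ = [
    "MatchTolerances", "MatchWeights", "MatchResult",
    "STANDARD_TOLERANCES", "EXTENDED_TOLERANCES", "DEFAULT_WEIGHTS",
    "trapezoid_score", "reverse_dot_product", "rule_msms_score",
    "fragment_tolerance", "identify", "calibrate_rt",
    "DecoyConfig", "make_decoy_library", "estimate_fdr",
]


@dataclass(frozen=True)
class MatchTolerances:
    """Per-tier matching tolerances."""

    ms1_ppm: float = 25.0
    rt_min: float = 0.0       # s
    rt_max: float = 12.0      # s
    ccs_min: float = 1.0      # % of library CCS
    ccs_max: float = 1.5      # %
    msms_cutoff: float = 0.6
    fragment_ppm: float = 25.0
    fragment_mz_floor: float = 0.01  # Th

    def __post_init__(self) -> None:
        if not (0 <= self.rt_min <= self.rt_max) or not (0 <= self.ccs_min <= self.ccs_max):
            raise ValueError("tolerances must satisfy 0 <= min <= max")


#: Matching settings against the measured standard library (MSI level 1).
STANDARD_TOLERANCES = MatchTolerances(rt_max=12.0, ccs_max=1.5, msms_cutoff=0.6)
#: Matching settings against the predicted extended library (MSI level 2).
EXTENDED_TOLERANCES = MatchTolerances(rt_max=30.0, ccs_max=3.0, msms_cutoff=0.5)


@dataclass(frozen=True)
class MatchWeights:
    w_rt: float = 0.2
    w_ccs: float = 0.4
    w_msms: float = 0.4
    keep_threshold: float = 0.6

    def __post_init__(self) -> None:
        if abs(self.w_rt + self.w_ccs + self.w_msms - 1.0) > 1e-9:
            raise ValueError("match weights must sum to 1")

    def integrate(self, s_rt: float, s_ccs: float, s_msms: float) -> float:
        return self.w_rt * s_rt + self.w_ccs * s_ccs + self.w_msms * s_msms


DEFAULT_WEIGHTS = MatchWeights()


@dataclass(frozen=True)
class MatchResult:
    feature_id: str
    candidate: LibraryEntry
    ppm_error: float
    s_rt: float
    s_ccs: float
    s_msms: float
    integrated: float
    msi_level: int
    kept: bool
    best: bool = False

    def as_row(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "candidate": self.candidate.name,
            "adduct": self.candidate.adduct,
            "tier": self.candidate.tier,
            "ppm_error": self.ppm_error,
            "s_rt": self.s_rt, "s_ccs": self.s_ccs, "s_msms": self.s_msms,
            "integrated": self.integrated,
            "msi_level": self.msi_level,
            "kept": self.kept, "best": self.best,
        }


def trapezoid_score(error: float, tol_min: float, tol_max: float) -> float:
    """Trapezoidal match score: 1 on the plateau (error ≤ tol_min), a linear
    ramp down to 0 at tol_max, 0 beyond (strict at the degenerate
    tol_min == tol_max edge)."""
    if tol_min < 0 or tol_max < tol_min:
        raise ValueError("need 0 <= tol_min <= tol_max")
    error = abs(float(error))
    if error >= tol_max:  # checked first: the degenerate plateau edge scores 0
        return 0.0
    if error <= tol_min:
        return 1.0
    return (tol_max - error) / (tol_max - tol_min)


def fragment_tolerance(mz: float, ppm: float = 25.0, floor: float = 0.01) -> float:
    """Fragment m/z matching window: ppm-scaled with an absolute floor."""
    return max(floor, abs(mz) * ppm * 1e-6)


def _match_library_peaks(measured: Spectrum, library: Spectrum,
                         ppm: float, floor: float) -> np.ndarray:
    """Measured intensity aligned to each library peak (0 when unmatched);
    nearest-m/z measured peak within tolerance, greedily, each measured peak
    used at most once."""
    out = np.zeros(len(library.mz))
    if measured.is_empty:
        return out
    used = np.zeros(len(measured.mz), dtype=bool)
    # process library peaks in order of decreasing intensity so the strongest
    # reference peaks claim the nearest measured peaks first
    for i in np.argsort(-library.intensities, kind="stable"):
        tol = fragment_tolerance(library.mz[i], ppm, floor)
        d = np.abs(measured.mz - library.mz[i])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            out[i] = measured.intensities[j]
            used[j] = True
    return out


def reverse_dot_product(measured: Spectrum, library: Spectrum,
                        fragment_ppm: float = 25.0,
                        fragment_mz_floor: float = 0.01) -> float:
    """Reverse spectral match score in [0, 1].

    The score is the squared cosine between √-intensity vectors restricted
    to the library peaks: measured peaks that match no library peak are
    ignored, unmatched library peaks contribute zero measured intensity.
    Scale-invariant in both spectra.
    """
    if library is None or library.is_empty:
        raise ValueError("library spectrum must be non-empty")
    if measured is None or measured.is_empty:
        return 0.0
    lib_w = np.sqrt(library.intensities.astype(float))
    meas_w = np.sqrt(_match_library_peaks(measured, library, fragment_ppm, fragment_mz_floor))
    denom = float(np.sum(lib_w**2) * np.sum(meas_w**2))
    if denom == 0.0:
        return 0.0
    return float(np.dot(lib_w, meas_w) ** 2 / denom)


def rule_msms_score(measured: Spectrum, expected: Spectrum,
                    fragment_ppm: float = 25.0,
                    fragment_mz_floor: float = 0.01) -> float:
    """Two-ion fragmentation-rule score for extended-library matching:
    1.0 when both the skeleton ion and the [PA+Na]+ derivate ion are
    detected, 0.5 when exactly one is, 0 otherwise."""
    skeleton = expected.peak_role("skeleton")
    derivate = expected.peak_role("derivate")
    if len(skeleton) != 1 or len(derivate) != 1:
        raise ValueError("expected spectrum must carry exactly one skeleton and one derivate ion")
    if measured is None or measured.is_empty:
        return 0.0

    def found(target: float) -> bool:
        tol = fragment_tolerance(target, fragment_ppm, fragment_mz_floor)
        return bool(np.any(np.abs(measured.mz - target) <= tol))

    n = int(found(float(skeleton[0]))) + int(found(float(derivate[0])))
    return {0: 0.0, 1: 0.5, 2: 1.0}[n]


def _score_candidate(feature: Feature, entry: LibraryEntry,
                     tol: MatchTolerances, weights: MatchWeights) -> MatchResult:
    ppm = (feature.mz - entry.mz) / entry.mz * 1e6
    s_rt = trapezoid_score(feature.rt - entry.rt, tol.rt_min, tol.rt_max)
    ccs_err_pct = abs(feature.ccs - entry.ccs) / entry.ccs * 100.0
    s_ccs = trapezoid_score(ccs_err_pct, tol.ccs_min, tol.ccs_max)
    if feature.spectrum is None:
        s_msms = 0.0
    elif entry.tier == "standard" and entry.spectrum is not None:
        s_msms = reverse_dot_product(feature.spectrum, entry.spectrum,
                                     tol.fragment_ppm, tol.fragment_mz_floor)
    else:
        expected = entry.spectrum if (entry.spectrum is not None and entry.spectrum.annotations) \
            else predict_fragments(entry)
        s_msms = rule_msms_score(feature.spectrum, expected,
                                 tol.fragment_ppm, tol.fragment_mz_floor)
    integrated = weights.integrate(s_rt, s_ccs, s_msms)
    kept = (integrated > weights.keep_threshold) and (s_msms >= tol.msms_cutoff) \
        and (feature.spectrum is not None)
    return MatchResult(
        feature_id=feature.feature_id, candidate=entry, ppm_error=float(ppm),
        s_rt=s_rt, s_ccs=s_ccs, s_msms=s_msms, integrated=float(integrated),
        msi_level=1 if entry.tier == "standard" else 2, kept=bool(kept),
    )


def _rank_key(r: MatchResult):
    # highest integrated, then smallest |ppm|, then name — deterministic
    return (-r.integrated, abs(r.ppm_error), r.candidate.name)


def identify(features: Iterable[Feature],
             standard_library: SterolLibrary | None,
             extended_library: SterolLibrary | None,
             tolerances_standard: MatchTolerances = STANDARD_TOLERANCES,
             tolerances_extended: MatchTolerances = EXTENDED_TOLERANCES,
             weights: MatchWeights = DEFAULT_WEIGHTS,
             rt_calibration: Callable[[float], float] | None = None) -> list[MatchResult]:
    """Score every feature against both library tiers.

    All candidates passing the 25 ppm MS1 gate are scored.  Per feature, the
    best kept standard-library match (MSI level 1) takes precedence over any
    extended-library match (level 2); within a tier the highest integrated
    score wins, ties broken by smaller |ppm error| then name.  The winning
    kept result is flagged ``best``.
    """
    libs: list[tuple[SterolLibrary, MatchTolerances]] = []
    if standard_library is not None and len(standard_library):
        lib = standard_library.map_rt(rt_calibration) if rt_calibration else standard_library
        libs.append((lib, tolerances_standard))
    if extended_library is not None and len(extended_library):
        lib = extended_library.map_rt(rt_calibration) if rt_calibration else extended_library
        libs.append((lib, tolerances_extended))

    results: list[MatchResult] = []
    for feature in features:
        per_feature: list[MatchResult] = []
        for lib, tol in libs:
            gate = tol.ms1_ppm * 1e-6
            for entry in lib:
                if abs(feature.mz - entry.mz) <= gate * entry.mz:
                    per_feature.append(_score_candidate(feature, entry, tol, weights))
        kept = [r for r in per_feature if r.kept]
        best = None
        if kept:
            level1 = [r for r in kept if r.msi_level == 1]
            pool = level1 if level1 else kept
            best = min(pool, key=_rank_key)
        for r in sorted(per_feature, key=_rank_key):
            results.append(replace(r, best=(r is best)))
    return results


def results_to_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    cols = ["feature_id", "candidate", "adduct", "tier", "ppm_error",
            "s_rt", "s_ccs", "s_msms", "integrated", "msi_level", "kept", "best"]
    return pd.DataFrame([r.as_row() for r in results], columns=cols)


# --- RT calibration ---------------------------------------------------------

def calibrate_rt(reference_pairs: Sequence[tuple[float, float]]) -> Callable[[float], float]:
    """Build a monotone RT mapping from (observed, reference) RTQC pairs.

    Piecewise-linear interpolation between pairs with linear extrapolation
    using the terminal segment slopes.  Returns a vectorizable callable
    mapping library RT (reference scale) onto the observed run — applied to
    library RTs before matching.
    """
    pairs = sorted((float(o), float(r)) for o, r in reference_pairs)
    if len(pairs) < 2:
        raise ValueError("RT calibration needs at least 2 reference pairs")
    obs = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    bad = np.where(np.diff(obs) <= 0)[0]
    if bad.size:
        viol = [f"pairs {i} and {i + 1} (observed {obs[i]:g} >= {obs[i + 1]:g})" for i in bad]
        raise ValueError("observed RTs must be strictly increasing: " + "; ".join(viol))
    if np.any(np.diff(ref) <= 0):
        raise ValueError("reference RTs must be strictly increasing")

    def mapping(rt):
        rt = np.asarray(rt, dtype=float)
        out = np.interp(rt, ref, obs)
        lo = rt < ref[0]
        hi = rt > ref[-1]
        if np.any(lo):
            slope = (obs[1] - obs[0]) / (ref[1] - ref[0])
            out = np.where(lo, obs[0] + slope * (rt - ref[0]), out)
        if np.any(hi):
            slope = (obs[-1] - obs[-2]) / (ref[-1] - ref[-2])
            out = np.where(hi, obs[-1] + slope * (rt - ref[-1]), out)
        return float(out) if out.ndim == 0 else out

    return mapping


# --- decoy FDR --------------------------------------------------------------

@dataclass(frozen=True)
class DecoyConfig:
    """Decoy-library construction for identification FDR.

    ``ccs-shift`` (default) displaces each entry's CCS by ±magnitude·ccs_max
    percent (random sign per entry), relabeling identities; ``rt-shuffle``
    permutes RTs among entries; ``mass-shift`` displaces m/z by the
    magnitude in Th.
    """

    strategy: str = "ccs-shift"
    magnitude: float = 2.0
    seed: int = 0


def make_decoy_library(target: SterolLibrary, cfg: DecoyConfig,
                       ccs_max_pct: float = 3.0) -> SterolLibrary:
    rng = np.random.default_rng(cfg.seed)
    entries = []
    for e in target:
        if cfg.strategy == "ccs-shift":
            sign = rng.choice([-1.0, 1.0])
            shift = sign * cfg.magnitude * ccs_max_pct / 100.0 * e.ccs
            new = replace(e, ccs=e.ccs + shift)
        elif cfg.strategy == "rt-shuffle":
            new = e  # handled jointly below
        elif cfg.strategy == "mass-shift":
            sign = rng.choice([-1.0, 1.0])
            new = replace(e, mz=e.mz + sign * cfg.magnitude)
        else:
            raise ValueError(f"unknown decoy strategy {cfg.strategy!r}")
        comp = replace(e.compound, name=f"DECOY_{e.compound.name}")
        entries.append(replace(new, compound=comp))
    if cfg.strategy == "rt-shuffle":
        rts = np.array([e.rt for e in entries])
        entries = [replace(e, rt=float(r)) for e, r in zip(entries, rng.permutation(rts))]
    return SterolLibrary(entries)


def estimate_fdr(features: Iterable[Feature], target_library: SterolLibrary,
                 decoy_cfg: DecoyConfig = DecoyConfig(),
                 ccs_tolerances: Sequence[float] = (1.5, 2.0, 2.5, 3.0),
                 base_tolerances: MatchTolerances = EXTENDED_TOLERANCES,
                 weights: MatchWeights = DEFAULT_WEIGHTS,
                 decoy_library: SterolLibrary | None = None) -> pd.DataFrame:
    """Estimate identification FDR over a grid of CCS match tolerances.

    The decoy library (same size as the target, identities relabeled) is
    matched under identical settings; FDR% = 100 · decoy hits / target hits
    per tolerance.  The decoy scheme is a synthetic stand-in — rows carry a
    ``decoy_strategy`` column making that explicit.
    """
    features = list(features)
    decoy = decoy_library if decoy_library is not None \
        else make_decoy_library(target_library, decoy_cfg, base_tolerances.ccs_max)
    rows = []
    for ccs_max in ccs_tolerances:
        tol = replace(base_tolerances, ccs_max=float(ccs_max),
                      ccs_min=min(base_tolerances.ccs_min, float(ccs_max)))
        n_target = sum(r.best for r in identify(features, None, target_library,
                                                tolerances_extended=tol, weights=weights))
        n_decoy = sum(r.best for r in identify(features, None, decoy,
                                               tolerances_extended=tol, weights=weights))
        fdr = 100.0 * n_decoy / n_target if n_target else np.nan
        if n_target == 0:
            warnings.warn(f"no target hits at CCS tolerance {ccs_max}%; FDR undefined")
        rows.append({"ccs_max_pct": float(ccs_max), "target_hits": n_target,
                     "decoy_hits": n_decoy, "fdr_pct": fdr,
                     "decoy_strategy": decoy_cfg.strategy})
    return pd.DataFrame(rows)
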