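"""Synthetic data generation with planted ground truth.

Every generator is a pure function of its spec and seed, and returns the
ground truth alongside the data so downstream modules can be scored without
re-deriving it.  The defaults emulate the study conditions of the sterol
atlas workflow: a 97-compound measured standard library plus a
2068-compound predicted extended library on a CCS = 22.2·mz^0.38 trend
line, feature tables with sub-tolerance jitter, and brain concentration
matrices (10 regions × 2 ages × 6 replicates) spanning ~8 orders of
magnitude with planted region, age and coregulation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from .features import Feature, format_feature_id
from .fragments import predict_fragments
from .library import LibraryEntry, SterolCompound, SterolLibrary
from .regionstats import DEFAULT_REGIONS, make_concentration_matrix
from .spectra import Spectrum

__all__ = [
    "LibrarySpec", "FeatureSpec", "BrainSpec",
    "make_library", "make_feature_table", "make_brain_dataset",
]

SUBCLASSES = (
    "cholesterol and derivatives", "ergosterols and derivatives",
    "stigmasterols and derivatives", "oxysterols", "phytosterols",
    "bile acids", "steroid hormones",
)


@dataclass(frozen=True)
class LibrarySpec:
    """Library generator settings (defaults = study conditions)."""

    n_standard: int = 97
    n_extended: int = 2068
    trend_a: float = 22.2
    trend_b: float = 0.38
    ccs_noise_sd: float = 18.0       # Å²; class-level scatter about the trend
    rt_range: tuple[float, float] = (120.0, 1020.0)
    rt_noise_sd: float = 60.0        # s; scatter about the mz→RT ramp
    isomer_group_sizes: tuple[tuple[int, float], ...] = ((1, 0.55), (2, 0.30), (3, 0.15))
    n_oh_probs: tuple[tuple[int, float], ...] = ((1, 0.60), (2, 0.25), (3, 0.15))
    extra_peaks: int = 3             # noise peaks added to "measured" spectra
    seed: int = 0


def _draw_formula(rng: np.random.Generator, n_oh: int) -> str:
    # sterol-like elemental space: C18-C32 skeletons, 3-8 double-bond
    # equivalents, and 0-2 non-hydroxyl oxygens (keto/epoxide); wide enough
    # that isomer groups stay small, as in the LMSD sterol class where most
    # compounds have isomers but groups of >3 are rare
    n_c = int(rng.integers(18, 33))
    dbe = int(rng.integers(3, 9))
    extra_o = int(rng.integers(0, 3))
    n_h = 2 * n_c + 2 - 2 * dbe
    return f"C{n_c}H{n_h}O{n_oh + extra_o}"


def _make_compounds(rng: np.random.Generator, n: int, spec: LibrarySpec,
                    prefix: str) -> list[SterolCompound]:
    sizes, probs = zip(*spec.isomer_group_sizes)
    oh_vals, oh_probs = zip(*spec.n_oh_probs)
    compounds: list[SterolCompound] = []
    i = 0
    while len(compounds) < n:
        k = int(rng.choice(sizes, p=probs))
        n_oh = int(rng.choice(oh_vals, p=oh_probs))
        formula = _draw_formula(rng, n_oh)
        for _ in range(min(k, n - len(compounds))):
            i += 1
            compounds.append(SterolCompound(
                name=f"{prefix}{i:04d}", formula=formula, n_hydroxyl=n_oh,
                sterol_class="ST01",
                subclass=str(rng.choice(SUBCLASSES)),
                smiles="",
            ))
    return compounds


def _measured_spectrum(entry_mz: float, compound: SterolCompound,
                       rng: np.random.Generator, n_extra: int) -> Spectrum:
    """A measured-looking standard spectrum: the rule fragments at realistic
    intensities plus a few low-intensity unrelated peaks."""
    skeleton = entry_mz - chem.PICOLINIC_ACID
    derivate = chem.PICOLINIC_ACID + chem.SODIUM_CATION
    mzs = [skeleton, derivate]
    intens = [100.0, float(rng.uniform(20, 80))]
    for _ in range(n_extra):
        mzs.append(float(rng.uniform(150, max(200.0, skeleton - 20))))
        intens.append(float(rng.uniform(1, 15)))
    return Spectrum(np.array(mzs), np.array(intens)).normalized()


def _entry(compound: SterolCompound, spec: LibrarySpec, rng: np.random.Generator,
           tier: str) -> LibraryEntry:
    adduct = chem.primary_adduct(compound.n_hydroxyl)
    mz = chem.derivatized_mz(compound, adduct)
    ccs = spec.trend_a * mz ** spec.trend_b + rng.normal(0.0, spec.ccs_noise_sd)
    ccs = max(ccs, 50.0)
    lo, hi = spec.rt_range
    frac = np.clip((mz - 450.0) / 400.0, 0.0, 1.0)
    rt = lo + frac * (hi - lo) + rng.normal(0.0, spec.rt_noise_sd)
    rt = float(np.clip(rt, 30.0, 1200.0))
    if tier == "standard":
        spectrum = _measured_spectrum(mz, compound, rng, spec.extra_peaks)
        src = "measured"
    else:
        spectrum = None  # rule-predicted lazily by the matcher
        src = "predicted"
    entry = LibraryEntry(compound=compound, adduct=adduct, mz=mz, rt=rt, ccs=float(ccs),
                         spectrum=spectrum, tier=tier, rt_source=src, ccs_source=src)
    if tier == "extended":
        entry = replace(entry, spectrum=predict_fragments(entry))
    return entry


def make_library(spec: LibrarySpec = LibrarySpec(), seed: int | None = None
                 ) -> tuple[SterolLibrary, SterolLibrary, pd.DataFrame]:
    """Generate (standard, extended) libraries and a ground-truth table.

    Standard entries carry measured-style spectra and measured RT/CCS;
    extended entries carry rule-predicted spectra and predicted-source
    RT/CCS, both drawn around the same trend line.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    std_compounds = _make_compounds(rng, spec.n_standard, spec, "STD_")
    ext_compounds = _make_compounds(rng, spec.n_extended, spec, "EXT_")
    standard = SterolLibrary([_entry(c, spec, rng, "standard") for c in std_compounds])
    extended = SterolLibrary([_entry(c, spec, rng, "extended") for c in ext_compounds])
    truth = pd.concat([standard.to_frame(), extended.to_frame()], ignore_index=True)
    return standard, extended, truth


@dataclass(frozen=True)
class FeatureSpec:
    """Feature-table generator settings.

    True features jitter library coordinates within the match tolerances;
    decoy features are pushed beyond at least one maximum tolerance (CCS or
    RT) or have their spectrum stripped.
    """

    n_true: int = 80
    n_decoy: int = 20
    mz_jitter_ppm: float = 5.0
    rt_jitter_s: float = 3.0
    ccs_jitter_pct: float = 0.3
    intensity_cv: float = 0.2
    decoy_ccs_push_pct: float = 6.0
    decoy_rt_push_s: float = 60.0
    seed: int = 0


def _jittered_feature(entry: LibraryEntry, fs: FeatureSpec,
                      rng: np.random.Generator, decoy_kind: str | None) -> Feature:
    mz = entry.mz * (1.0 + rng.uniform(-fs.mz_jitter_ppm, fs.mz_jitter_ppm) * 1e-6)
    rt = entry.rt + rng.uniform(-fs.rt_jitter_s, fs.rt_jitter_s)
    ccs = entry.ccs * (1.0 + rng.uniform(-fs.ccs_jitter_pct, fs.ccs_jitter_pct) / 100.0)
    spectrum = entry.spectrum if entry.spectrum is not None else predict_fragments(entry)
    if decoy_kind == "ccs":
        sign = rng.choice([-1.0, 1.0])
        ccs = entry.ccs * (1.0 + sign * fs.decoy_ccs_push_pct / 100.0)
    elif decoy_kind == "rt_ccs":
        # RT alone cannot reject a match under the published weighting
        # (w_rt = 0.2), so coordinate decoys displace both RT and CCS
        sign = rng.choice([-1.0, 1.0])
        rt = entry.rt + sign * fs.decoy_rt_push_s
        ccs = entry.ccs * (1.0 + sign * fs.decoy_ccs_push_pct / 100.0)
    elif decoy_kind == "spectrum":
        spectrum = None
    if spectrum is not None:
        noisy = spectrum.intensities * np.exp(rng.normal(0.0, fs.intensity_cv, len(spectrum)))
        spectrum = Spectrum(spectrum.mz, noisy).normalized()
    return Feature.from_coordinates(mz, max(rt, 1.0), max(ccs, 40.0),
                                    spectrum=spectrum, abundance={"s1": 100.0})


def make_feature_table(library: SterolLibrary, fs: FeatureSpec = FeatureSpec(),
                       seed: int | None = None) -> tuple[list[Feature], pd.DataFrame]:
    """Generate features from library entries with a truth map.

    Truth columns: ``feature_id``, ``source`` (library entry name),
    ``is_true`` and ``decoy_kind``.
    """
    rng = np.random.default_rng(fs.seed if seed is None else seed)
    entries = list(library)
    if not entries:
        raise ValueError("library is empty")
    features: list[Feature] = []
    truth_rows = []
    idx_true = rng.choice(len(entries), size=fs.n_true, replace=fs.n_true > len(entries))
    for i in idx_true:
        f = _jittered_feature(entries[int(i)], fs, rng, None)
        features.append(f)
        truth_rows.append({"feature_id": f.feature_id, "source": entries[int(i)].name,
                           "is_true": True, "decoy_kind": ""})
    idx_decoy = rng.choice(len(entries), size=fs.n_decoy, replace=fs.n_decoy > len(entries))
    kinds = rng.choice(["ccs", "rt_ccs", "spectrum"], size=fs.n_decoy)
    for i, kind in zip(idx_decoy, kinds):
        f = _jittered_feature(entries[int(i)], fs, rng, str(kind))
        features.append(f)
        truth_rows.append({"feature_id": f.feature_id, "source": entries[int(i)].name,
                           "is_true": False, "decoy_kind": str(kind)})
    return features, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class BrainSpec:
    """Brain concentration-matrix generator settings (defaults = study
    shape: 197 sterols, 10 regions × 2 ages × 6 replicates)."""

    n_sterols: int = 197
    n_altered: int = 149             # region-structured sterols
    n_dysregulated: int = 102        # sterols with age effects somewhere
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_replicates: int = 6
    log10_conc_range: tuple[float, float] = (-4.0, 4.0)  # ~8 orders of magnitude
    region_effect_log2: float = 2.0  # amplitude of region archetype profiles
    age_effect_log2: float = 1.5     # amplitude of age fold-change profiles
    replicate_cv: float = 0.2
    coregulation_modules: tuple[int, ...] = (21, 5)  # planted positively coupled groups
    n_negative_pairs: int = 3
    profile_noise_sd: float = 0.05   # jitter on shared fold profiles (log2)
    seed: int = 0


def make_brain_dataset(spec: BrainSpec = BrainSpec(), seed: int | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Generate a concentration matrix with planted spatial/temporal truth.

    Returns (matrix, truth) where truth holds: ``altered`` (region-
    structured sterols), ``archetype`` labels, ``dysregulated`` sterols,
    ``fold_profiles`` (sterol × region log2 FC actually planted),
    ``positive_pairs`` and ``negative_pairs`` (planted coregulation).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, R = spec.n_sterols, len(spec.regions)
    sterols = [f"sterol_{i:03d}" for i in range(1, n + 1)]
    lo, hi = spec.log10_conc_range
    base = 10.0 ** rng.uniform(lo, hi, size=n)

    # region structure: three archetype profiles (oxysterol-like,
    # phytosterol-like, cholesterol-like) with per-sterol amplitude
    archetypes = rng.normal(0.0, 1.0, size=(3, R))
    archetypes -= archetypes.mean(axis=1, keepdims=True)
    # orthogonalize so the three spatial programs are mutually uncorrelated
    q, _ = np.linalg.qr(archetypes.T)
    archetypes = q.T * np.sqrt(R)
    altered_idx = rng.choice(n, size=min(spec.n_altered, n), replace=False)
    arch_label = np.full(n, -1)
    region_log2 = np.zeros((n, R))
    for i in altered_idx:
        k = int(rng.integers(0, 3))
        arch_label[i] = k
        region_log2[i] = spec.region_effect_log2 * archetypes[k]

    # age structure: dysregulated sterols carry per-region log2 fold changes;
    # coregulation modules share a profile (→ positive pairs), negative pairs
    # get sign-flipped partner profiles
    dys_idx = list(rng.choice(n, size=min(spec.n_dysregulated, n), replace=False))
    fold_log2 = np.zeros((n, R))
    pos_pairs: list[tuple[str, str]] = []
    neg_pairs: list[tuple[str, str]] = []
    cursor = 0
    for size in spec.coregulation_modules:
        members = dys_idx[cursor:cursor + size]
        cursor += size
        profile = rng.normal(0.0, 1.0, size=R)
        profile = spec.age_effect_log2 * (profile - profile.mean()) / max(profile.std(), 1e-9)
        for i in members:
            fold_log2[i] = profile + rng.normal(0.0, spec.profile_noise_sd, R)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pos_pairs.append((sterols[members[a]], sterols[members[b]]))
    for _ in range(spec.n_negative_pairs):
        if cursor + 2 > len(dys_idx):
            break
        i, j = dys_idx[cursor], dys_idx[cursor + 1]
        cursor += 2
        profile = rng.normal(0.0, 1.0, size=R)
        profile = spec.age_effect_log2 * (profile - profile.mean()) / max(profile.std(), 1e-9)
        fold_log2[i] = profile + rng.normal(0.0, spec.profile_noise_sd, R)
        fold_log2[j] = -profile + rng.normal(0.0, spec.profile_noise_sd, R)
        neg_pairs.append((sterols[i], sterols[j]))
    for i in dys_idx[cursor:]:  # independent dysregulated sterols
        fold_log2[i] = rng.normal(0.0, spec.age_effect_log2, size=R)

    # assemble: conc = base · 2^region · (2^fold for old age) · lognormal noise
    sigma = np.sqrt(np.log(1.0 + spec.replicate_cv**2))
    cols = []
    data = []
    for r, region in enumerate(spec.regions):
        for age_i, age in enumerate(("6wk", "68wk")):
            mean = base * 2.0 ** region_log2[:, r] * (2.0 ** fold_log2[:, r]) ** age_i
            for rep in range(spec.n_replicates):
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
                data.append(mean * noise)
                cols.append((region, age, rep + 1))
    values = np.column_stack(data)
    # reorder to the canonical region-major (region, age, replicate) product
    frame = pd.DataFrame(values, index=sterols,
                         columns=pd.MultiIndex.from_tuples(cols, names=["region", "age", "replicate"]))
    order = pd.MultiIndex.from_product([list(spec.regions), ["6wk", "68wk"],
                                        range(1, spec.n_replicates + 1)],
                                       names=["region", "age", "replicate"])
    matrix = make_concentration_matrix(frame[order].values, sterols,
                                       spec.regions, ("6wk", "68wk"), spec.n_replicates)
    truth = {
        "altered": [sterols[i] for i in sorted(altered_idx)],
        "archetype": pd.Series(arch_label, index=sterols, name="archetype"),
        "dysregulated": [sterols[i] for i in sorted(dys_idx)],
        "fold_profiles": pd.DataFrame(fold_log2, index=sterols, columns=list(spec.regions)),
        "positive_pairs": pos_pairs,
        "negative_pairs": neg_pairs,
    }
    return matrix, truth
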