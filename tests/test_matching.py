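"""Trapezoid/spectral/rule scores, four-dimensional identification,
RT calibration and decoy FDR."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sterol4d.features import Feature
from sterol4d.fragments import predict_fragments
from sterol4d.library import SterolLibrary
from sterol4d.matching import (DEFAULT_WEIGHTS, EXTENDED_TOLERANCES,
                               STANDARD_TOLERANCES, DecoyConfig, MatchWeights,
                               calibrate_rt, estimate_fdr, identify,
                               make_decoy_library, results_to_frame,
                               reverse_dot_product, rule_msms_score,
                               trapezoid_score)
from sterol4d.simulate import FeatureSpec, LibrarySpec, make_feature_table, make_library
from sterol4d.spectra import Spectrum
from conftest import make_entry


class TestTrapezoidScore:
    @pytest.mark.parametrize("error,tmin,tmax,expected", [
        (0.0, 0.0, 12.0, 1.0),
        (6.0, 0.0, 12.0, 0.5),
        (1.25, 1.0, 1.5, 0.5),
        (12.0, 0.0, 12.0, 0.0),
        (30.0, 0.0, 12.0, 0.0),
        (0.9, 1.0, 1.5, 1.0),
    ])
    def test_closed_form_examples(self, error, tmin, tmax, expected):
        assert trapezoid_score(error, tmin, tmax) == pytest.approx(expected)

    def test_degenerate_equal_tolerances_strict(self):
        assert trapezoid_score(5.0, 5.0, 5.0) == 0.0
        assert trapezoid_score(4.999, 5.0, 5.0) == 1.0

    def test_matches_piecewise_closed_form_on_dense_grid(self):
        tmin, tmax = 1.0, 3.0
        for e in np.linspace(0, 5, 2001):
            expected = 1.0 if e <= tmin else 0.0 if e >= tmax else (tmax - e) / (tmax - tmin)
            assert trapezoid_score(e, tmin, tmax) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 100), st.floats(0.001, 50))
    @settings(derandomize=True, max_examples=100)
    def test_non_increasing_in_error(self, error, step):
        assert trapezoid_score(error + step, 1.0, 10.0) <= trapezoid_score(error, 1.0, 10.0)


def brute_force_reverse_dot(measured: Spectrum, library: Spectrum, tol: float) -> float:
    """Independent oracle: explicit vector construction over library peaks
    with nearest-within-tolerance pairing, squared cosine of √ intensities."""
    lib_vec, meas_vec = [], []
    used = set()
    for lm, li in sorted(zip(library.mz, library.intensities), key=lambda p: -p[1]):
        best_j, best_d = None, tol
        for j, (mm, mi) in enumerate(zip(measured.mz, measured.intensities)):
            if j not in used and abs(mm - lm) <= best_d:
                best_j, best_d = j, abs(mm - lm)
        lib_vec.append(np.sqrt(li))
        if best_j is None:
            meas_vec.append(0.0)
        else:
            used.add(best_j)
            meas_vec.append(np.sqrt(measured.intensities[best_j]))
    lib_vec, meas_vec = np.array(lib_vec), np.array(meas_vec)
    denom = np.sum(lib_vec**2) * np.sum(meas_vec**2)
    return float(np.dot(lib_vec, meas_vec) ** 2 / denom) if denom else 0.0


class TestReverseDotProduct:
    def test_proportional_spectra_score_one(self, two_peak_spectrum):
        scaled = Spectrum(two_peak_spectrum.mz, two_peak_spectrum.intensities * 7.3)
        assert reverse_dot_product(scaled, two_peak_spectrum) == pytest.approx(1.0)

    def test_disjoint_peak_sets_score_zero(self, two_peak_spectrum):
        other = Spectrum(np.array([150.0, 250.0]), np.array([10.0, 10.0]))
        assert reverse_dot_product(other, two_peak_spectrum) == 0.0

    def test_worked_example(self, two_peak_spectrum):
        measured = Spectrum(np.array([100.0, 200.0, 300.0]), np.array([50.0, 100.0, 999.0]))
        # reverse restriction ignores the unmatched 300 Th peak
        assert reverse_dot_product(measured, two_peak_spectrum) == pytest.approx(0.8889, abs=1e-4)

    def test_empty_measured_scores_zero(self, two_peak_spectrum):
        empty = Spectrum(np.array([]), np.array([]))
        assert reverse_dot_product(empty, two_peak_spectrum) == 0.0

    def test_empty_library_rejected(self, two_peak_spectrum):
        with pytest.raises(ValueError):
            reverse_dot_product(two_peak_spectrum, Spectrum(np.array([]), np.array([])))

    @given(scale_m=st.floats(0.01, 100), scale_l=st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, scale_m, scale_l):
        lib = Spectrum(np.array([100.0, 200.0]), np.array([80.0, 40.0]))
        mea = Spectrum(np.array([100.0, 200.0, 250.0]), np.array([30.0, 60.0, 5.0]))
        base = reverse_dot_product(mea, lib)
        scaled = reverse_dot_product(
            Spectrum(mea.mz, mea.intensities * scale_m),
            Spectrum(lib.mz, lib.intensities * scale_l))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_agrees_with_brute_force_oracle_on_small_spectra(self):
        rng = np.random.default_rng(77)
        tol = 0.02
        for _ in range(200):
            n_l = int(rng.integers(1, 6))
            n_m = int(rng.integers(0, 6))
            # peak grid spaced well beyond tolerance → unambiguous pairing
            grid = np.arange(100, 400, 1.0)
            lib = Spectrum(rng.choice(grid, n_l, replace=False) + rng.uniform(-0.005, 0.005, n_l),
                           rng.uniform(1, 100, n_l))
            mea = Spectrum(rng.choice(grid, n_m, replace=False) + rng.uniform(-0.005, 0.005, n_m),
                           rng.uniform(1, 100, n_m)) if n_m else Spectrum(np.array([]), np.array([]))
            ours = reverse_dot_product(mea, lib, fragment_ppm=0.0, fragment_mz_floor=tol)
            oracle = brute_force_reverse_dot(mea, lib, tol)
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestRuleMsmsScore:
    @pytest.fixture
    def expected(self):
        return predict_fragments(make_entry(mz=506.3993))

    def test_both_ions_full_score(self, expected):
        measured = Spectrum(np.array([146.0212, 383.3673]), np.array([50.0, 100.0]))
        assert rule_msms_score(measured, expected) == 1.0

    def test_single_ion_half_score(self, expected):
        only_derivate = Spectrum(np.array([146.0212]), np.array([50.0]))
        only_skeleton = Spectrum(np.array([383.3673]), np.array([100.0]))
        assert rule_msms_score(only_derivate, expected) == 0.5
        assert rule_msms_score(only_skeleton, expected) == 0.5

    def test_neither_ion_zero(self, expected):
        assert rule_msms_score(Spectrum(np.array([250.0]), np.array([9.0])), expected) == 0.0
        assert rule_msms_score(Spectrum(np.array([]), np.array([])), expected) == 0.0


class TestWeights:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MatchWeights(w_rt=0.3, w_ccs=0.4, w_msms=0.4)

    def test_integrated_is_convex_combination(self, rng):
        for _ in range(1000):
            s = rng.uniform(0, 1, 3)
            integrated = DEFAULT_WEIGHTS.integrate(*s)
            assert s.min() - 1e-12 <= integrated <= s.max() + 1e-12


class TestIdentify:
    def test_exact_roundtrip_feature_scores_one(self):
        entry = make_entry(spectrum=Spectrum(np.array([146.0212, 383.3673]),
                                             np.array([50.0, 100.0])))
        feature = Feature.from_coordinates(entry.mz, entry.rt, entry.ccs,
                                           spectrum=entry.spectrum)
        results = identify([feature], SterolLibrary([entry]), None)
        assert len(results) == 1
        r = results[0]
        assert r.best and r.kept and r.msi_level == 1
        assert r.integrated == pytest.approx(1.0)

    def test_six_isobaric_candidates_reduce_to_one(self):
        """Six same-m/z candidates; only one lies within RT+CCS+MS/MS
        tolerance of the feature (the campesterol scenario)."""
        spec = Spectrum(np.array([146.0212, 383.3673]), np.array([50.0, 100.0]))
        true = make_entry(name="campesterol_like", rt=849.0, ccs=269.0, spectrum=spec)
        others = [make_entry(name=f"isomer_{i}", mz=true.mz, rt=849.0 + 100 * (i + 1),
                             ccs=269.0 * (1 + 0.04 * (i + 1)), spectrum=spec)
                  for i in range(5)]
        lib = SterolLibrary([true] + others)
        feature = Feature.from_coordinates(true.mz, 850.0, 269.1, spectrum=spec)
        df = results_to_frame(identify([feature], lib, None))
        assert len(df) == 6          # all pass the MS1 gate
        kept = df[df.kept]
        assert list(kept.candidate) == ["campesterol_like"]
        assert df[df.best].candidate.iloc[0] == "campesterol_like"

    def test_keep_threshold_is_strict(self):
        # s_rt=1, s_ccs=1, s_msms=0 -> integrated exactly 0.6 -> not kept
        entry = make_entry(spectrum=Spectrum(np.array([146.0212, 383.3673]),
                                             np.array([50.0, 100.0])))
        off_spectrum = Spectrum(np.array([500.0]), np.array([10.0]))
        feature = Feature.from_coordinates(entry.mz, entry.rt, entry.ccs,
                                           spectrum=off_spectrum)
        r = identify([feature], SterolLibrary([entry]), None)[0]
        assert r.integrated == pytest.approx(0.6)
        assert not r.kept

    def test_feature_without_spectrum_never_kept(self):
        entry = make_entry(spectrum=Spectrum(np.array([146.0212, 383.3673]),
                                             np.array([50.0, 100.0])))
        feature = Feature.from_coordinates(entry.mz, entry.rt, entry.ccs, spectrum=None)
        r = identify([feature], SterolLibrary([entry]), None)[0]
        assert r.s_msms == 0.0 and not r.kept

    def test_standard_precedes_extended_for_same_feature(self):
        spec = Spectrum(np.array([146.0212, 383.3673]), np.array([50.0, 100.0]))
        std = make_entry(name="std_compound", spectrum=spec)
        ext = make_entry(name="ext_compound", mz=std.mz, rt=std.rt, ccs=std.ccs,
                         tier="extended")
        feature = Feature.from_coordinates(std.mz, std.rt, std.ccs, spectrum=spec)
        df = results_to_frame(identify([feature], SterolLibrary([std]), SterolLibrary([ext])))
        best = df[df.best]
        assert best.msi_level.iloc[0] == 1 and best.candidate.iloc[0] == "std_compound"

    def test_planted_truth_precision_and_invariants(self, study_libraries):
        std, ext, _ = study_libraries
        feats, truth = make_feature_table(std, FeatureSpec())
        df = results_to_frame(identify(feats, std, ext))
        # MatchResult invariants on every kept row
        kept = df[df.kept]
        w = DEFAULT_WEIGHTS
        recomputed = w.w_rt * kept.s_rt + w.w_ccs * kept.s_ccs + w.w_msms * kept.s_msms
        assert np.allclose(kept.integrated, recomputed)
        assert (kept.integrated > w.keep_threshold).all()
        best = df[df.best].merge(truth, on="feature_id")
        precision = (best.is_true & (best.candidate == best.source)).mean()
        recall = (best.is_true & (best.candidate == best.source)).sum() / truth.is_true.sum()
        assert precision >= 0.95
        assert recall >= 0.95


class TestRtCalibration:
    def test_identity_pairs_identity_mapping(self):
        m = calibrate_rt([(100, 100), (500, 500), (900, 900)])
        for rt in (50, 100, 432.5, 900, 1200):
            assert m(rt) == pytest.approx(rt)

    def test_uniform_shift(self):
        m = calibrate_rt([(110, 100), (510, 500), (910, 900)])
        assert m(300) == pytest.approx(310)
        assert m(1000) == pytest.approx(1010)  # extrapolation keeps the shift
        assert m(50) == pytest.approx(60)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rt([(100, 100)])

    def test_non_monotone_pairs_listed(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            calibrate_rt([(100, 100), (90, 200), (300, 300)])

    def test_mapping_applied_to_library_shifts_match_window(self):
        spec = Spectrum(np.array([146.0212, 383.3673]), np.array([50.0, 100.0]))
        entry = make_entry(rt=600.0, spectrum=spec)
        feature = Feature.from_coordinates(entry.mz, 650.0, entry.ccs, spectrum=spec)
        no_cal = identify([feature], SterolLibrary([entry]), None)[0]
        assert no_cal.s_rt == 0.0
        mapping = calibrate_rt([(150, 100), (650, 600), (1050, 1000)])
        cal = identify([feature], SterolLibrary([entry]), None, rt_calibration=mapping)[0]
        assert cal.s_rt == pytest.approx(1.0)


class TestFdr:
    def test_empty_decoy_library_gives_zero_fdr(self, small_libraries):
        std, ext, _ = small_libraries
        feats, _ = make_feature_table(ext, FeatureSpec(n_true=30, n_decoy=0, seed=3))
        table = estimate_fdr(feats, ext, ccs_tolerances=[1.5, 3.0],
                             decoy_library=SterolLibrary([]))
        assert (table.fdr_pct == 0.0).all()
        assert (table.target_hits > 0).all()

    def test_fdr_non_decreasing_with_ccs_tolerance(self, small_libraries):
        std, ext, _ = small_libraries
        feats, _ = make_feature_table(ext, FeatureSpec(n_true=60, n_decoy=20, seed=5))
        table = estimate_fdr(feats, ext, DecoyConfig(seed=9),
                             ccs_tolerances=[1.5, 3.0, 6.0, 10.0])
        vals = table.fdr_pct.dropna().values
        assert np.all(np.diff(vals) >= -1e-9)

    def test_decoy_library_disjoint_identities(self, small_libraries):
        std, ext, _ = small_libraries
        decoy = make_decoy_library(ext, DecoyConfig(seed=1))
        target_names = {e.name for e in ext}
        assert all(e.name not in target_names for e in decoy)
        assert len(decoy) == len(ext)

    def test_estimated_fdr_tracks_planted_contamination(self, small_libraries):
        """More planted false features -> larger estimated FDR."""
        std, ext, _ = small_libraries
        clean, _ = make_feature_table(ext, FeatureSpec(n_true=60, n_decoy=0, seed=21))
        dirty, _ = make_feature_table(ext, FeatureSpec(n_true=30, n_decoy=60, seed=21))
        fdr_clean = estimate_fdr(clean, ext, DecoyConfig(seed=2), ccs_tolerances=[3.0])
        fdr_dirty = estimate_fdr(dirty, ext, DecoyConfig(seed=2), ccs_tolerances=[3.0])
        assert fdr_dirty.fdr_pct.iloc[0] >= fdr_clean.fdr_pct.iloc[0]
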