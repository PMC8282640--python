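"""CCS differences, peak resolutions, isomer pairing and the trend line."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sterol4d.library import SterolLibrary
from sterol4d.separation import (CcsMzTrendline, ChromPeak, assign_isomer_pairs,
                                 ccs_difference, fit_trendline, pair_ccs_difference,
                                 resolution_1d, resolution_2d,
                                 summarize_separability)
from conftest import make_entry


class TestCcsDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (200.0, 210.0, 5.0),
        (250.0, 250.0, 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert ccs_difference(a, b) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ccs_difference(0.0, 200.0)

    def test_pair_convention_is_order_free_and_conservative(self):
        # denominators differ by the ratio; the pair convention uses the
        # smaller CCS, giving the larger percentage either way
        assert ccs_difference(200, 210) / ccs_difference(210, 200) == pytest.approx(210 / 200)
        assert pair_ccs_difference(200, 210) == pair_ccs_difference(210, 200)
        assert pair_ccs_difference(200, 210) == pytest.approx(5.0)


class TestResolution:
    def test_identical_positions_zero(self):
        assert resolution_1d(ChromPeak(100, 4), ChromPeak(100, 6)) == 0.0

    def test_arithmetic_example(self):
        # 2·|104-100| / (4+4) = 1.0
        assert resolution_1d(ChromPeak(100, 4), ChromPeak(104, 4)) == pytest.approx(1.0)
        assert resolution_1d(ChromPeak(100, 2), ChromPeak(104, 2)) == pytest.approx(2.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            ChromPeak(100, 0.0)

    @pytest.mark.parametrize("lc,im,expected", [
        (0.8, 0.9, 1.2),    # aldosterone/cortisone: LC 0.8, IM 0.9 -> 2-D 1.2
        (0.0, 0.0, 0.0),
        (3.0, 4.0, 5.0),
    ])
    def test_two_dimensional_examples(self, lc, im, expected):
        assert round(resolution_2d(lc, im), 1) == pytest.approx(expected)

    def test_two_dimensional_norm_properties(self, rng):
        for _ in range(100):
            a, b = rng.uniform(0, 5, 2)
            r = resolution_2d(a, b)
            assert r == resolution_2d(b, a)
            assert r >= max(a, b) - 1e-12
            if min(a, b) > 0:
                assert r > max(a, b)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            resolution_2d(-0.1, 1.0)

    def test_gaussian_sigma_width_convention(self):
        assert ChromPeak.from_sigma(100.0, 2.5).width == pytest.approx(10.0)


class TestIsomerPairs:
    def test_three_identical_masses_three_pairs(self):
        lib = SterolLibrary([make_entry(name=f"iso{i}", formula="C27H46O", rt=100 + i,
                                        ccs=250 + i) for i in range(3)])
        assert len(assign_isomer_pairs(lib, "derivatized")) == 3

    def test_all_distinct_masses_no_pairs(self):
        lib = SterolLibrary([make_entry(name=f"c{i}", formula=f"C{20 + i}H{2 * (20 + i) - 8}O")
                             for i in range(4)])
        assert assign_isomer_pairs(lib, "derivatized") == []

    def test_count_matches_exhaustive_group_oracle(self, rng):
        """Pair count equals sum of C(k,2) over exact-mass groups for random
        small libraries."""
        formulas = ["C27H46O", "C28H48O", "C27H46O2", "C29H50O", "C27H44O"]
        for _ in range(50):
            n = int(rng.integers(2, 20))
            chosen = [formulas[i] for i in rng.integers(0, len(formulas), n)]
            lib = SterolLibrary([make_entry(name=f"e{i}", formula=f, rt=float(100 + i),
                                            ccs=float(200 + i))
                                 for i, f in enumerate(chosen)])
            from collections import Counter
            counts = Counter(chosen)
            expected = sum(k * (k - 1) // 2 for k in counts.values())
            assert len(assign_isomer_pairs(lib, "derivatized")) == expected

    def test_water_loss_creates_extra_underivatized_pairs(self):
        # C27H46O2 [M+H-H2O]+ coincides with C27H44O [M+H]+: an isomer pair
        # only in the underivatized mode
        a = make_entry(name="diol_like", formula="C27H46O2", n_oh=2, adduct="[M+Na]+")
        b = make_entry(name="enone_like", formula="C27H44O", n_oh=1)
        lib = SterolLibrary([a, b])
        assert len(assign_isomer_pairs(lib, "derivatized")) == 0
        assert len(assign_isomer_pairs(lib, "underivatized")) == 1

    def test_fixture_underivatized_exceed_derivatized(self, study_libraries):
        std, _, _ = study_libraries
        n_deriv = len(assign_isomer_pairs(std, "derivatized"))
        n_underiv = len(assign_isomer_pairs(std, "underivatized"))
        assert n_underiv > n_deriv > 0

    def test_resolution_metrics_from_width_table(self):
        a = make_entry(name="iso1", formula="C27H46O", rt=100.0, ccs=250.0)
        b = make_entry(name="iso2", formula="C27H46O", rt=104.0, ccs=260.0)
        widths = pd.DataFrame({"name": ["iso1", "iso2"],
                               "w_rt_s": [4.0, 4.0], "w_ccs_A2": [5.0, 5.0]})
        (pair,) = assign_isomer_pairs(SterolLibrary([a, b]), "derivatized", widths=widths)
        assert pair.rs_lc == pytest.approx(2 * 4 / (4 + 4))
        assert pair.rs_im == pytest.approx(2 * 10 / (5 + 5))
        assert pair.rs_2d == pytest.approx(np.hypot(pair.rs_lc, pair.rs_im))
        assert pair.rs_2d >= max(pair.rs_lc, pair.rs_im)


class TestSummarize:
    def _pairs(self, ccs_diffs):
        entries = [make_entry(name=f"p{i}", formula="C27H46O", ccs=200.0) for i in range(2)]
        from sterol4d.separation import IsomerPair
        return [IsomerPair(entries[0], entries[1], "derivatized", 500.0, d) for d in ccs_diffs]

    def test_counting_fractions(self):
        summary = summarize_separability(self._pairs([0.5, 2.5, 3.0, 4.0]))
        assert summary["pct_ccs_diff_ge_threshold"] == pytest.approx(75.0)

    def test_all_zero_diffs(self):
        summary = summarize_separability(self._pairs([0.0, 0.0]))
        assert summary["pct_ccs_diff_ge_threshold"] == 0.0

    def test_empty_pairs_empty_summary(self):
        assert summarize_separability([]) == {}


class TestTrendline:
    def test_noiseless_power_law_recovery(self, rng):
        mz = rng.uniform(400, 700, 97)
        fit = fit_trendline(mz, 22.2 * mz**0.38)
        assert fit.a_ == pytest.approx(22.2, abs=1e-6)
        assert fit.b_ == pytest.approx(0.38, abs=1e-6)
        assert fit.r_ == pytest.approx(1.0, abs=1e-9)

    def test_constant_ccs_degenerate(self, rng):
        mz = rng.uniform(400, 700, 50)
        fit = fit_trendline(mz, np.full(50, 250.0))
        assert fit.b_ == pytest.approx(0.0, abs=1e-6)
        assert fit.a_ == pytest.approx(250.0, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trendline([500.0, 600.0], [240.0, 250.0])

    def test_interval_halfwidth_matches_plugin_formula(self, rng):
        mz = rng.uniform(400, 700, 60)
        fit = fit_trendline(mz, 22.2 * mz**0.38 + rng.normal(0, 15, 60))
        for x in (fit.x_bar_, 420.0, 690.0):
            expected = fit.z * fit.s_yx_ * np.sqrt(
                1 + 1 / fit.n_ + (x - fit.x_bar_) ** 2 / fit.ss_x_)
            assert fit.predictive_interval(x) == pytest.approx(expected, abs=1e-12)

    def test_interval_symmetric_and_increasing_from_mean(self, rng):
        mz = rng.uniform(400, 700, 60)
        fit = fit_trendline(mz, 22.2 * mz**0.38 + rng.normal(0, 15, 60))
        deltas = np.array([1.0, 10.0, 50.0, 120.0])
        up = fit.predictive_interval(fit.x_bar_ + deltas)
        down = fit.predictive_interval(fit.x_bar_ - deltas)
        assert np.allclose(up, down)
        assert np.all(np.diff(up) > 0)
        assert fit.predictive_interval(fit.x_bar_) < up.min()

    def test_chemical_space_membership(self, rng):
        mz = rng.uniform(400, 700, 80)
        fit = fit_trendline(mz, 22.2 * mz**0.38 + rng.normal(0, 10, 80))
        x = 550.0
        on_line = fit.predict(x)
        delta = fit.predictive_interval(x)
        assert fit.contains(x, on_line)
        assert fit.contains(x, on_line + 0.99 * delta)
        assert not fit.contains(x, on_line + 2.0 * delta)

    def test_printed_ssx_override_honoured(self, rng):
        mz = rng.uniform(400, 700, 30)
        y = 22.2 * mz**0.38 + rng.normal(0, 10, 30)
        base = CcsMzTrendline().fit(mz, y)
        override = CcsMzTrendline(ss_x_override=98.71926).fit(mz, y)
        x = base.x_bar_ + 5.0
        assert override.predictive_interval(x) > base.predictive_interval(x)
        assert override.predictive_interval(base.x_bar_) == pytest.approx(
            base.predictive_interval(base.x_bar_))
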