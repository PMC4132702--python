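"""STO/burst fitting, titration, fold changes and the group t-test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpgkin import (
    NoiseSpec,
    active_site_titration,
    compare_groups,
    fit_burst,
    fit_sto,
    fold_change,
    generate_mto_curve,
    generate_sto_curve,
    generate_titration_series,
)
from ._oracles import burst_grid_oracle, pooled_t_test, sto_grid_oracle


class TestFitSto:
    def test_all_zero_trace_is_degenerate(self, burst_times):
        c = generate_sto_curve(0.0, 0.5, burst_times)
        f = fit_sto(c)
        assert f.degenerate and f.A0_hat == 0.0 and math.isnan(f.k_obs_hat)

    def test_noise_free_round_trip(self, burst_times):
        c = generate_sto_curve(1.0, 0.5, burst_times)
        f = fit_sto(c)
        assert f.A0_hat == pytest.approx(1.0, rel=1e-6)
        assert f.k_obs_hat == pytest.approx(0.5, rel=1e-6)

    def test_optimizer_rss_dominates_grid_oracle(self, burst_times):
        c = generate_sto_curve(1.3, 0.7, burst_times,
                               NoiseSpec(cv=0.05, seed=11))
        f = fit_sto(c)
        _, _, oracle_rss = sto_grid_oracle(c.times, c.product)
        assert f.rss <= oracle_rss + 1e-12

    def test_equal_kchem_across_codon_contexts(self, burst_times):
        # All five sequence contexts share one k_chem: fitted k_obs equal.
        k_fits = []
        for codon in ("246", "247", "249", "179", "255"):
            c = generate_sto_curve(1.0, 1.2, burst_times, label=f"{codon}eA")
            k_fits.append(fit_sto(c).k_obs_hat)
        assert np.ptp(k_fits) == pytest.approx(0.0, abs=1e-8)

    def test_warns_on_mto_regime(self, burst_times):
        c = generate_mto_curve(1.0, 1.0, 0.2, burst_times)
        with pytest.warns(UserWarning, match="MTO"):
            fit_sto(c)

    def test_requires_four_points(self):
        c = generate_sto_curve(1.0, 0.5, [0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            fit_sto(c)


class TestFitBurst:
    def test_zero_slope_gives_zero_turnover(self, burst_times):
        c = generate_mto_curve(2.0, 1.0, 0.0, burst_times)
        assert fit_burst(c).k_pd_hat == pytest.approx(0.0, abs=1e-7)

    def test_noise_free_round_trip_kpd(self, burst_times):
        c = generate_mto_curve(2.0, 1.0, 0.5, burst_times)
        f = fit_burst(c)
        assert f.k_pd_hat == pytest.approx(0.25, rel=1e-6)

    def test_fixture_246eA_recovers_printed_turnover(self, catalog,
                                                     burst_times):
        p = catalog.mechanism("eA", "246")
        a0 = p.active_fraction * 7.0
        c = generate_mto_curve(a0, 1.2, p.k_pd * a0, burst_times,
                               enzyme_total=7.0, substrate_total=75.0)
        assert fit_burst(c).k_pd_hat == pytest.approx(0.24, rel=1e-4)

    def test_kpd_identity_holds_exactly(self, burst_times):
        c = generate_mto_curve(1.7, 1.1, 0.3, burst_times,
                               NoiseSpec(cv=0.05, seed=3))
        f = fit_burst(c)
        assert f.k_pd_hat == f.k_ss_hat / f.A0_hat

    def test_amplitude_bounded_by_total_enzyme(self, burst_times):
        c = generate_mto_curve(1.54, 1.2, 0.37, burst_times,
                               NoiseSpec(cv=0.1, seed=9),
                               enzyme_total=7.0, substrate_total=75.0)
        f = fit_burst(c)
        assert f.A0_hat <= 7.0

    def test_optimizer_rss_dominates_grid_oracle(self, burst_times):
        c = generate_mto_curve(1.54, 1.2, 0.37, burst_times,
                               NoiseSpec(cv=0.05, seed=21))
        f = fit_burst(c)
        _, _, _, oracle_rss = burst_grid_oracle(c.times, c.product)
        assert f.rss <= oracle_rss + 1e-12

    def test_consistent_with_sto_fit_when_no_turnover(self, burst_times):
        c_mto = generate_mto_curve(1.5, 0.8, 0.0, burst_times)
        c_sto = generate_sto_curve(1.5, 0.8, burst_times)
        fb, fs = fit_burst(c_mto), fit_sto(c_sto)
        assert fb.A0_hat == pytest.approx(fs.A0_hat, rel=1e-6)
        assert fb.k_obs_hat == pytest.approx(fs.k_obs_hat, rel=1e-6)

    def test_all_zero_curve_flagged_degenerate(self, burst_times):
        c = generate_mto_curve(0.0, 1.0, 0.0, burst_times)
        assert fit_burst(c).degenerate

    @given(
        a0=st.floats(0.5, 20.0),
        k_obs=st.floats(0.3, 5.0),
        k_pd=st.floats(1e-3, 1.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_recovery_property_noise_free(self, a0, k_obs, k_pd):
        """Fitted parameters match generating parameters on exact data."""
        t = np.unique(np.concatenate([np.geomspace(0.05, 10, 25),
                                      np.linspace(0, 10, 21)]))
        c = generate_mto_curve(a0, k_obs, k_pd * a0, t)
        f = fit_burst(c)
        assert f.A0_hat == pytest.approx(a0, rel=1e-6)
        assert f.k_obs_hat == pytest.approx(k_obs, rel=1e-6)
        assert f.k_pd_hat == pytest.approx(k_pd, rel=1e-6)


class TestActiveSiteTitration:
    @pytest.mark.parametrize("af,expected", [(1.0, 100.0), (0.22, 22.0),
                                             (0.83, 83.0)])
    def test_recovers_active_percent(self, af, expected, burst_times):
        curves = generate_titration_series([3.5, 7.0, 10.0, 20.0], af, 1.2,
                                           0.24, burst_times)
        res = active_site_titration(curves)
        assert res.active_percent == pytest.approx(expected, abs=0.5)

    def test_amplitudes_ascend_with_enzyme(self, burst_times):
        curves = generate_titration_series([3.5, 7.0, 10.0, 20.0], 0.22, 1.2,
                                           0.24, burst_times)
        res = active_site_titration(curves)
        a0 = [f.A0_hat for f in res.fits]
        assert a0 == sorted(a0)

    def test_too_few_usable_fits_is_an_error(self, burst_times):
        curves = generate_titration_series([7.0], 0.22, 1.2, 0.24, burst_times)
        with pytest.raises(ValueError):
            active_site_titration(curves)


class TestFoldChange:
    @pytest.mark.parametrize("num,den,expected",
                             [(0.24, 0.02, 12.0), (0.24, 0.24, 1.0),
                              (0.26, 0.01, 26.0)])
    def test_plain_ratio(self, num, den, expected):
        assert fold_change(num, den) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(0.24, 0.0)


class TestCompareGroups:
    def test_identical_groups_carry_no_evidence(self):
        r = compare_groups([1.0, 2.0], [1.0, 2.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_formula(self):
        r = compare_groups([1, 2, 3], [4, 5, 6])
        assert r.t_statistic == pytest.approx(-3.674, abs=5e-4)
        assert r.p_value == pytest.approx(0.02131, abs=5e-6)
        assert r.df == 4
        t_hand, p_hand, df_hand = pooled_t_test([1, 2, 3], [4, 5, 6])
        assert r.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.p_value == pytest.approx(p_hand, rel=1e-10)

    def test_agrees_with_scipy_reference(self):
        a, b = [3.0, 16.5], [18.5, 19.5, 20.5]
        r = compare_groups(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_hepg2_half_life_groups_differ_significantly(self):
        # Replicate-level comparison (N = 3 per codon, as assayed): all
        # non-hotspot t1/2 values against all hotspot t1/2 values.
        non = [3.0, 16.5] * 3
        hot = [18.5, 19.5, 20.5] * 3
        r = compare_groups(non, hot)
        assert r.p_value < 0.05

    def test_degenerate_zero_variance_equal_means(self):
        r = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert r.t_statistic == 0.0 and r.p_value == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
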