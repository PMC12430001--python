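import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cosolvency.io import SolubilityRecord
from cosolvency.solution import (
    GAS_CONSTANT,
    SolutionThermodynamics,
    fit_vant_hoff_krug,
    harmonic_mean_temperature,
    solution_functions,
    zeta_contributions,
)

NINE_TEMPS = [278.15 + 5 * i for i in range(9)]


class TestHarmonicMeanTemperature:
    def test_nine_study_temperatures(self):
        assert harmonic_mean_temperature(NINE_TEMPS) == pytest.approx(297.59, abs=0.05)

    def test_equal_temperatures_identity(self):
        assert harmonic_mean_temperature([300.0] * 5) == pytest.approx(300.0)

    def test_closed_form_two_values(self):
        # 2 / (1/250 + 1/375) = 300 exactly
        assert harmonic_mean_temperature([250.0, 375.0]) == pytest.approx(300.0, abs=1e-12)

    @pytest.mark.parametrize("temps", [[], [300.0, -1.0]])
    def test_invalid_inputs(self, temps):
        with pytest.raises(ValueError):
            harmonic_mean_temperature(temps)


def _records(temps, lnx, w1=0.0):
    return [
        SolubilityRecord(w1=w1, T=T, x3=math.exp(v)) for T, v in zip(temps, lnx)
    ]


class TestVantHoffKrugFit:
    def test_noise_free_line_recovered_exactly(self):
        Thm = harmonic_mean_temperature(NINE_TEMPS)
        lnx = [-3500.0 * (1 / T - 1 / Thm) - 7.0 for T in NINE_TEMPS]
        fit = fit_vant_hoff_krug(_records(NINE_TEMPS, lnx), Thm)
        assert fit.m == pytest.approx(-3500.0, abs=1e-8)
        assert fit.a == pytest.approx(-7.0, abs=1e-12)
        assert fit.se_m == pytest.approx(0.0, abs=1e-6)
        assert fit.se_a == pytest.approx(0.0, abs=1e-10)

    def test_ols_matches_brute_force_grid_search(self):
        """The analytic OLS minimiser agrees with a dense 2-D grid search of
        the sum of squared residuals on a small noisy instance."""
        temps = [280.0, 290.0, 300.0, 310.0, 320.0]
        Thm = harmonic_mean_temperature(temps)
        rng = np.random.default_rng(7)
        lnx = [-3000.0 * (1 / T - 1 / Thm) - 6.5 + rng.normal(0, 0.05) for T in temps]
        fit = fit_vant_hoff_krug(_records(temps, lnx), Thm)

        u = np.array([1 / T - 1 / Thm for T in temps])
        y = np.array(lnx)
        ms = np.linspace(fit.m - 200, fit.m + 200, 401)
        as_ = np.linspace(fit.a - 0.02, fit.a + 0.02, 401)
        M, A = np.meshgrid(ms, as_)
        sse = ((y[None, None, :] - (M[..., None] * u + A[..., None])) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert M[i, j] == pytest.approx(fit.m, abs=(ms[1] - ms[0]))
        assert A[i, j] == pytest.approx(fit.a, abs=(as_[1] - as_[0]))

    def test_standard_errors_match_scipy_linregress(self):
        temps = NINE_TEMPS
        Thm = harmonic_mean_temperature(temps)
        rng = np.random.default_rng(3)
        lnx = [-3400.0 * (1 / T - 1 / Thm) - 7.0 + rng.normal(0, 0.02) for T in temps]
        fit = fit_vant_hoff_krug(_records(temps, lnx), Thm)
        u = [1 / T - 1 / Thm for T in temps]
        lr = stats.linregress(u, lnx)
        assert fit.m == pytest.approx(lr.slope, rel=1e-12)
        assert fit.a == pytest.approx(lr.intercept, rel=1e-12)
        assert fit.se_m == pytest.approx(lr.stderr, rel=1e-9)
        assert fit.se_a == pytest.approx(lr.intercept_stderr, rel=1e-9)

    def test_intercept_equals_mean_ln_solubility(self, smt_table, smt_solution):
        """Centering at the harmonic mean makes the intercept the mean of
        ln x3 — holds at machine precision on every fitted composition."""
        for fit in smt_solution.fits:
            recs = smt_table.at_composition(fit.w1)
            mean_ln = np.mean([math.log(r.x3) for r in recs])
            assert fit.a == pytest.approx(mean_ln, rel=1e-12)

    def test_too_few_points_and_degenerate_predictor(self):
        Thm = 300.0
        with pytest.raises(ValueError, match="3 point"):
            fit_vant_hoff_krug(_records([280, 300], [-7, -7]), Thm)
        recs = [SolubilityRecord(0.0, 300.0, 1e-4)] * 1
        with pytest.raises(ValueError):
            fit_vant_hoff_krug(
                [SolubilityRecord(0.0, 300.0, x) for x in (1e-4, 2e-4, 3e-4)], Thm
            )


class TestSolutionFunctions:
    def test_table_values_pure_ethanol(self, smt_solution):
        """w1 = 0: ΔG=17.39, ΔH=29.21 kJ/mol, ΔS=39.7 J/mol/K, TΔS=11.82."""
        t = smt_solution.thermo[0]
        assert t.w1 == 0.0
        assert t.dG == pytest.approx(17.39, rel=0.01)
        assert t.dH == pytest.approx(29.21, rel=0.01)
        assert t.dS == pytest.approx(39.7, rel=0.01)
        assert t.TdS == pytest.approx(11.82, rel=0.01)
        assert t.zeta_H == pytest.approx(0.712, abs=0.005)

    def test_table_values_pure_acetonitrile(self, smt_solution):
        t = smt_solution.thermo[-1]
        assert t.w1 == 1.0
        assert t.dG == pytest.approx(13.66, rel=0.01)
        assert t.dH == pytest.approx(28.5, rel=0.01)
        assert t.zeta_H == pytest.approx(0.658, abs=0.005)

    def test_gibbs_energy_decreases_with_cosolvent(self, smt_solution):
        dG = [t.dG for t in smt_solution.thermo]
        assert all(a > b for a, b in zip(dG, dG[1:]))

    def test_zero_fit_gives_zero_functions(self):
        from cosolvency.solution import VantHoffFit
        fit = VantHoffFit(w1=0.0, m=0.0, a=0.0, se_m=0.0, se_a=0.0,
                          Thm=297.6, n_points=9, residual_variance=0.0)
        t = solution_functions(fit)
        assert t.dH == 0.0 and t.dG == 0.0 and t.dS == 0.0

    def test_definitional_identities_machine_precision(self, smt_solution):
        for t in smt_solution.thermo:
            assert t.dG == pytest.approx(t.dH - t.Thm * t.dS / 1000.0, abs=1e-12)
            assert t.zeta_H + t.zeta_TS == 1.0
            assert 0.0 <= t.zeta_H <= 1.0

    def test_uncertainty_propagation_formulas(self, smt_solution):
        R = GAS_CONSTANT
        for fit, t in zip(smt_solution.fits, smt_solution.thermo):
            assert t.sd_dH == pytest.approx(R * fit.se_m / 1000.0, rel=1e-12)
            assert t.sd_dG == pytest.approx(R * fit.Thm * fit.se_a / 1000.0, rel=1e-12)
            assert t.sd_TdS == pytest.approx(math.hypot(t.sd_dH, t.sd_dG), rel=1e-12)


class TestZetaContributions:
    @pytest.mark.parametrize(
        "dH,TdS,expected",
        [(29.21, 11.82, 0.712), (28.5, 14.8, 0.658), (5.0, 0.0, 1.0)],
    )
    def test_reference_values(self, dH, TdS, expected):
        zh, zts = zeta_contributions(dH, TdS)
        assert zh == pytest.approx(expected, abs=0.0005)
        assert zh + zts == 1.0

    def test_origin_undefined(self):
        with pytest.raises(ValueError):
            zeta_contributions(0.0, 0.0)

    @given(
        dH=st.floats(-100, 100),
        TdS=st.floats(-100, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity(self, dH, TdS):
        if abs(dH) + abs(TdS) == 0:
            return
        zh, zts = zeta_contributions(dH, TdS)
        assert zh + zts == 1.0
        assert 0.0 <= zh <= 1.0


class TestModelInterface:
    def test_from_dataframe_equivalent_to_table(self, smt_table, smt_solution):
        res2 = SolutionThermodynamics.from_dataframe(smt_table.to_frame()).fit()
        for a, b in zip(smt_solution.thermo, res2.thermo):
            assert a.dG == pytest.approx(b.dG, rel=1e-14)
            assert a.dH == pytest.approx(b.dH, rel=1e-14)

    def test_summary_contains_headline_numbers(self, smt_solution):
        s = smt_solution.summary()
        assert "297.6" in s
        assert "17.39" in s and "29.2" in s

    def test_weighted_fit_runs_and_differs(self, smt_table):
        res_w = SolutionThermodynamics(smt_table).fit(weighted=True)
        res_u = SolutionThermodynamics(smt_table).fit(weighted=False)
        # weighting changes estimates slightly but not the physics
        assert res_w.thermo[0].dH == pytest.approx(res_u.thermo[0].dH, rel=0.05)
        assert res_w.thermo[0].dH != res_u.thermo[0].dH
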