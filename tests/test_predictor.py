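import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosolvency.io import SolubilityRecord
from cosolvency.predictor import (
    PredictorModel,
    YalkowskyRosemanVantHoff,
    fit_pure_solvent,
    mean_relative_deviation,
    predict_solubility,
    regression_diagnostics,
)

# published four-point coefficients for SMT in MeCN (1) / EtOH (2)
PUBLISHED = PredictorModel(A1=-3408.7, B1=5.9236, A2=-3531.1, B2=4.8307)


class TestFitPureSolvent:
    def test_two_point_reproduces_published_coefficients(self, smt_table):
        A1, B1 = fit_pure_solvent(smt_table.at_composition(1.0))
        A2, B2 = fit_pure_solvent(smt_table.at_composition(0.0))
        assert A1 == pytest.approx(-3408.7, rel=1e-3)
        assert B1 == pytest.approx(5.9236, rel=1e-2)
        assert A2 == pytest.approx(-3531.1, rel=1e-3)
        assert B2 == pytest.approx(4.8307, rel=1e-2)

    @pytest.mark.parametrize("mode", ["two_point", "ols_all"])
    def test_exact_line_recovered_in_both_modes(self, mode):
        recs = [
            SolubilityRecord(0.0, T, math.exp(-3000.0 / T + 4.0))
            for T in (280.0, 290.0, 300.0, 310.0)
        ]
        A, B = fit_pure_solvent(recs, mode=mode)
        assert A == pytest.approx(-3000.0, rel=1e-10)
        assert B == pytest.approx(4.0, rel=1e-10)

    def test_two_point_anchors_have_zero_residual(self, smt_table):
        recs = sorted(smt_table.at_composition(1.0), key=lambda r: r.T)
        A, B = fit_pure_solvent(recs)
        for r in (recs[0], recs[-1]):
            assert A / r.T + B == pytest.approx(math.log(r.x3), abs=1e-12)

    def test_identical_temperatures_rejected(self):
        recs = [SolubilityRecord(0.0, 300.0, 1e-4)]
        with pytest.raises(ValueError):
            fit_pure_solvent(recs * 1 + [], mode="two_point")


class TestPredictSolubility:
    def test_direct_evaluation_at_midpoint(self):
        # mean of the two pure ln-solubilities at 298.15 K
        x = predict_solubility(PUBLISHED, 0.5, 298.15)
        assert x == pytest.approx(1.91e-3, rel=0.01)

    def test_pure_solvent_degenerate_cases(self):
        for w1, A, B in [(1.0, PUBLISHED.A1, PUBLISHED.B1),
                         (0.0, PUBLISHED.A2, PUBLISHED.B2)]:
            assert predict_solubility(PUBLISHED, w1, 300.0) == pytest.approx(
                math.exp(A / 300.0 + B), rel=1e-14
            )

    def test_log_prediction_linear_in_w1_and_inverse_T(self):
        T = 300.0
        ln = lambda w1, T: math.log(predict_solubility(PUBLISHED, w1, T))
        assert ln(0.5, T) == pytest.approx((ln(0.0, T) + ln(1.0, T)) / 2, abs=1e-12)
        # linear in 1/T at fixed w1
        lnT = lambda T: math.log(predict_solubility(PUBLISHED, 0.3, T))
        T1, T2 = 280.0, 320.0
        Tm = 2 / (1 / T1 + 1 / T2)  # midpoint in 1/T
        assert lnT(Tm) == pytest.approx((lnT(T1) + lnT(T2)) / 2, abs=1e-12)

    def test_composition_out_of_range(self):
        with pytest.raises(ValueError):
            predict_solubility(PUBLISHED, 1.2, 300.0)


class TestMeanRelativeDeviation:
    def test_hand_computed_example(self):
        assert mean_relative_deviation([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0)

    def test_perfect_prediction_is_zero(self):
        x = [1e-4, 2e-4, 3e-4]
        assert mean_relative_deviation(x, x) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(1, 2, 20)
        c = e * rng.uniform(0.9, 1.1, 20)
        assert mean_relative_deviation(e, c) == pytest.approx(
            mean_relative_deviation(10 * e, 10 * c), rel=1e-12
        )

    @pytest.mark.parametrize(
        "e,c", [([], []), ([1.0, 2.0], [1.0]), ([0.0, 1.0], [1.0, 1.0])]
    )
    def test_invalid_inputs(self, e, c):
        with pytest.raises(ValueError):
            mean_relative_deviation(e, c)


class TestValidationOnStudyGrid:
    def test_mrd_matches_published_value(self, smt_table):
        """Two-point fit evaluated over all 189 points: MRD ≈ 1.31%."""
        res = YalkowskyRosemanVantHoff(smt_table).fit()
        assert res.diagnostics.mrd_percent == pytest.approx(1.31, abs=0.15)

    def test_mrd_with_literal_published_coefficients(self, smt_table):
        calc = [predict_solubility(PUBLISHED, r.w1, r.T) for r in smt_table.records]
        exp = [r.x3 for r in smt_table.records]
        mrd = mean_relative_deviation(exp, calc)
        assert mrd == pytest.approx(1.31, abs=0.15)
        # refit-vs-literal difference is only printed-coefficient rounding
        refit = YalkowskyRosemanVantHoff(smt_table).fit().diagnostics.mrd_percent
        assert abs(refit - mrd) < 0.15

    def test_adjusted_r2_matches_published_value(self, smt_table):
        res = YalkowskyRosemanVantHoff(smt_table).fit()
        d = res.diagnostics
        assert d.n_points == 189
        assert d.adj_r2 == pytest.approx(0.99919, abs=0.0005)
        assert d.adj_r2 <= d.r2 <= 1.0

    def test_f_and_r2_algebraically_consistent(self, smt_table):
        d = YalkowskyRosemanVantHoff(smt_table).fit().diagnostics
        r2_from_f = d.f_stat / (d.f_stat + d.n_points - 2)
        assert r2_from_f == pytest.approx(d.r2, abs=1e-6)

    def test_identical_series_give_perfect_fit(self):
        x = np.linspace(1e-4, 1e-2, 30)
        d = regression_diagnostics(x, x)
        assert d.r2 == pytest.approx(1.0)
        assert d.mrd_percent == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regression_diagnostics([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_extrapolation_warns(self, smt_table):
        res = YalkowskyRosemanVantHoff(smt_table).fit()
        with pytest.warns(UserWarning, match="outside"):
            res.predict(0.5, 350.0)

    def test_model_serialization_roundtrip(self, tmp_path, smt_table):
        res = YalkowskyRosemanVantHoff(smt_table).fit()
        p = tmp_path / "model.json"
        res.params.to_json(p)
        back = PredictorModel.from_json(p)
        assert back == res.params


@given(w1=st.floats(0, 1), T=st.floats(250, 350))
@settings(max_examples=100, deadline=None)
def test_prediction_positive_and_finite(w1, T):
    x = predict_solubility(PUBLISHED, w1, T)
    assert 0 < x < 1
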