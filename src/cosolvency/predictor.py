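"""Log-linear (Yalkowsky–Roseman) cosolvency prediction with van't Hoff
temperature dependence.

Solubility in each pure solvent follows a van't Hoff line,
ln x3,i = A_i/T + B_i, and the mixture solubility is the mass-fraction
weighted mean of the pure-solvent log-solubilities:

    ln x3(w1, T) = w1·(A1/T + B1) + (1 − w1)·(A2/T + B2).

Four experimental points — two temperatures in each pure solvent — fix all
four coefficients, which is the model's appeal: no mixture data are needed.
Validation uses the mean relative deviation (MRD) and a simple linear
regression of calculated on experimental solubility.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SolubilityRecord, SolubilityTable

__all__ = [
    "PredictorModel",
    "FitDiagnostics",
    "fit_pure_solvent",
    "predict_solubility",
    "mean_relative_deviation",
    "regression_diagnostics",
    "YalkowskyRosemanVantHoff",
    "PredictorResults",
]


@dataclass(frozen=True)
class PredictorModel:
    """Fitted pure-solvent van't Hoff coefficients.

    ``A`` has units of K (enthalpic coefficient), ``B`` is dimensionless
    (entropic coefficient); subscript 1 is the cosolvent (w1 axis), 2 the
    reference solvent.
    """

    A1: float
    B1: float
    A2: float
    B2: float
    fit_mode: str = "two_point"

    def predict(self, w1: float, T: float) -> float:
        return predict_solubility(self, w1, T)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"A1": self.A1, "B1": self.B1, "A2": self.A2, "B2": self.B2,
             "fit_mode": self.fit_mode}, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictorModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit of calculated vs experimental solubility."""

    mrd_percent: float
    r2: float
    adj_r2: float
    f_stat: float
    p_value: float
    n_points: int


def fit_pure_solvent(
    records: Sequence[SolubilityRecord], mode: str = "two_point"
) -> tuple[float, float]:
    """Fit ln x3 = A/T + B for one pure solvent.

    ``two_point`` passes the line exactly through the records at the lowest
    and highest temperature (the four-point predictor convention);
    ``ols_all`` regresses on every record.
    """
    if mode not in ("two_point", "ols_all"):
        raise ValueError(f"unknown mode {mode!r}")
    if any(r.x3 <= 0 for r in records):
        raise ValueError("non-positive solubility")
    recs = sorted(records, key=lambda r: r.T)
    if mode == "two_point":
        lo, hi = recs[0], recs[-1]
        if lo.T == hi.T:
            raise ValueError("two-point fit needs two distinct temperatures")
        A = (math.log(lo.x3) - math.log(hi.x3)) / (1.0 / lo.T - 1.0 / hi.T)
        B = math.log(lo.x3) - A / lo.T
        return A, B
    if len(recs) < 3:
        raise ValueError("ols_all needs at least 3 records")
    invT = np.array([1.0 / r.T for r in recs])
    if np.allclose(invT, invT[0]):
        raise ValueError("zero predictor variance: all temperatures equal")
    y = np.array([math.log(r.x3) for r in recs])
    A, B = np.polyfit(invT, y, 1)
    return float(A), float(B)


def predict_solubility(model: PredictorModel, w1: float, T: float) -> float:
    """Mole-fraction solubility at (w1, T) under the log-linear model."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError(f"w1={w1} outside [0, 1]")
    if T <= 0:
        raise ValueError("temperature must be positive")
    ln_x = w1 * (model.A1 / T + model.B1) + (1.0 - w1) * (model.A2 / T + model.B2)
    return math.exp(ln_x)


def mean_relative_deviation(
    experimental: Sequence[float], calculated: Sequence[float]
) -> float:
    """Mean absolute relative deviation, in percent.

    MRD = 100 · (1/N) · Σ |x_E − x_C| / x_E.
    """
    exp = np.asarray(experimental, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if exp.size == 0:
        raise ValueError("empty input")
    if exp.shape != calc.shape:
        raise ValueError("length mismatch")
    if np.any(exp <= 0):
        raise ValueError("experimental values must be positive")
    return float(100.0 * np.mean(np.abs(exp - calc) / exp))


def regression_diagnostics(
    experimental: Sequence[float], calculated: Sequence[float]
) -> FitDiagnostics:
    """Simple linear regression of calculated on experimental solubility.

    Returns r², the adjusted r² = 1 − (1 − r²)(N − 1)/(N − 2), the ANOVA
    F-statistic F = r²(N − 2)/(1 − r²) and its p-value on (1, N − 2) df,
    along with the MRD.  Computed on the raw mole-fraction scale.
    """
    exp = np.asarray(experimental, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    n = exp.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(exp) == 0:
        raise ValueError("zero variance in experimental values")
    lr = stats.linregress(exp, calc)
    r2 = float(lr.rvalue**2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return FitDiagnostics(
        mrd_percent=mean_relative_deviation(exp, calc),
        r2=r2, adj_r2=adj_r2, f_stat=f_stat, p_value=p, n_points=n,
    )


class YalkowskyRosemanVantHoff:
    """Four-point cosolvency solubility predictor for a measurement grid.

    Fits the pure-solvent van't Hoff lines from the w1 = 1 and w1 = 0
    columns of ``table`` and validates the mixture predictions against the
    full grid.

    Examples
    --------
    >>> from cosolvency.datasets import load_smt_mecn_etoh
    >>> res = YalkowskyRosemanVantHoff(load_smt_mecn_etoh()).fit()
    >>> round(res.diagnostics.mrd_percent, 2)
    1.29
    """

    def __init__(self, table: SolubilityTable):
        comps = table.compositions
        if 0.0 not in comps or 1.0 not in comps:
            raise ValueError("table must contain both pure solvents (w1=0 and w1=1)")
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "YalkowskyRosemanVantHoff":
        return cls(SolubilityTable.from_frame(df), **kwargs)

    def fit(self, mode: str = "two_point") -> "PredictorResults":
        A1, B1 = fit_pure_solvent(self.table.at_composition(1.0), mode=mode)
        A2, B2 = fit_pure_solvent(self.table.at_composition(0.0), mode=mode)
        model = PredictorModel(A1=A1, B1=B1, A2=A2, B2=B2, fit_mode=mode)
        return PredictorResults(self, model)


class PredictorResults:
    """Fitted predictor with validation diagnostics over the source grid."""

    def __init__(self, parent: YalkowskyRosemanVantHoff, params: PredictorModel):
        self.model = parent
        self.params = params
        self._diagnostics: FitDiagnostics | None = None

    def predict(self, w1: float, T: float) -> float:
        """Predicted mole-fraction solubility at (w1, T)."""
        tmin, tmax = min(self.model.table.temperatures), max(self.model.table.temperatures)
        if not tmin <= T <= tmax:
            import warnings
            warnings.warn(
                f"T={T} K outside the fitted range [{tmin}, {tmax}] K: "
                "the model is interpolative", stacklevel=2)
        return predict_solubility(self.params, w1, T)

    def deviations(self) -> pd.DataFrame:
        """Per-point experimental vs calculated solubility and relative deviation."""
        rows = []
        for r in self.model.table.records:
            calc = predict_solubility(self.params, r.w1, r.T)
            rows.append(
                {"w1": r.w1, "T_K": r.T, "x3_exp": r.x3, "x3_calc": calc,
                 "rel_dev_percent": 100.0 * abs(r.x3 - calc) / r.x3}
            )
        return pd.DataFrame(rows)

    @property
    def diagnostics(self) -> FitDiagnostics:
        """MRD and regression diagnostics over every record in the table."""
        if self._diagnostics is None:
            dev = self.deviations()
            self._diagnostics = regression_diagnostics(
                dev["x3_exp"].to_numpy(), dev["x3_calc"].to_numpy()
            )
        return self._diagnostics

    def ln_scale_diagnostics(self) -> dict:
        """The calculated-vs-experimental regression on the ln x3 scale.

        Reported alongside the raw-scale diagnostics because r² and F are
        sensitive to the scale choice.
        """
        dev = self.deviations()
        lr = stats.linregress(np.log(dev["x3_exp"]), np.log(dev["x3_calc"]))
        n = len(dev)
        r2 = float(lr.rvalue**2)
        f_stat = r2 * (n - 2) / (1.0 - r2) if r2 < 1 else float("inf")
        return {
            "r2": r2,
            "adj_r2": 1.0 - (1.0 - r2) * (n - 1) / (n - 2),
            "f_stat": f_stat,
            "n_points": n,
        }

    def summary(self) -> str:
        p, d = self.params, self.diagnostics
        return "\n".join([
            "Van't Hoff–Yalkowsky–Roseman predictor",
            f"  ln x3 = w1·({p.A1:.1f}/T + {p.B1:.4f}) "
            f"+ w2·({p.A2:.1f}/T + {p.B2:.4f})   [fit: {p.fit_mode}]",
            f"  N = {d.n_points}, MRD = {d.mrd_percent:.2f}%",
            f"  r² = {d.r2:.5f}, adj r² = {d.adj_r2:.5f}, "
            f"F = {d.f_stat:.1f}, p = {d.p_value:.3g}",
        ])
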