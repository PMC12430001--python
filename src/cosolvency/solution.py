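"""Van't Hoff–Krug regression and apparent thermodynamic solution functions.

For each solvent composition the logarithm of the mole-fraction solubility is
regressed on the centred reciprocal temperature,

    ln x3 = m · (1/T − 1/Thm) + a,

where Thm = n / Σ(1/T) is the harmonic mean of the study temperatures.
Centring at 1/Thm (the Krug correction) makes the slope and intercept
estimates uncorrelated, so their standard errors propagate independently
into the apparent thermodynamic functions:

    ΔsolnH° = −R·m            (enthalpy of solution)
    ΔsolnG° = −R·Thm·a        (Gibbs energy of solution, at Thm)
    ΔsolnS° = (ΔH − ΔG)/Thm   (entropy of solution)

The relative contributions of the energetic and organisational terms to the
Gibbs energy are ζH = |ΔH|/(|ΔH| + |Thm·ΔS|) and ζTS = 1 − ζH.

The module exposes both the elementary operations and a statsmodels-style
model/results pair: build :class:`SolutionThermodynamics` from a
:class:`~cosolvency.io.SolubilityTable` and call :meth:`fit`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SolubilityRecord, SolubilityTable

__all__ = [
    "GAS_CONSTANT",
    "harmonic_mean_temperature",
    "fit_vant_hoff_krug",
    "solution_functions",
    "zeta_contributions",
    "VantHoffFit",
    "SolutionThermo",
    "SolutionThermodynamics",
    "SolutionThermoResults",
]

#: CODATA molar gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314462618


def harmonic_mean_temperature(temps: Sequence[float]) -> float:
    """Harmonic mean n/Σ(1/T) of a set of absolute temperatures (K)."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("empty temperature list")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    return temps.size / float(np.sum(1.0 / temps))


@dataclass(frozen=True)
class VantHoffFit:
    """Per-composition van't Hoff–Krug regression result.

    ``m`` (K) and ``a`` (dimensionless) are the slope and intercept of
    ln x3 on (1/T − 1/Thm); ``se_m``/``se_a`` their OLS standard errors with
    n − 2 degrees of freedom.  Because the predictor is centred, ``a`` equals
    the mean of ln x3 and cov(m, a) = 0.
    """

    w1: float
    m: float
    a: float
    se_m: float
    se_a: float
    Thm: float
    n_points: int
    residual_variance: float


def fit_vant_hoff_krug(
    records: Sequence[SolubilityRecord],
    Thm: float,
    weighted: bool = False,
) -> VantHoffFit:
    """Fit ln x3 = m·(1/T − 1/Thm) + a at one composition by least squares.

    Parameters
    ----------
    records : sequence of SolubilityRecord
        Measurements at a single composition, ≥3 distinct temperatures.
    Thm : float
        Harmonic mean temperature used to centre the predictor, K.
    weighted : bool
        If True, weight points by 1/sd_lnx² where sd_lnx ≈ sd/x3 (delta
        method).  The default, unweighted OLS, is the conventional treatment
        of printed solubility tables.
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 points, got {len(records)}")
    w1s = {r.w1 for r in records}
    if len(w1s) != 1:
        raise ValueError(f"records span multiple compositions: {sorted(w1s)}")
    (w1,) = w1s
    T = np.array([r.T for r in records], dtype=float)
    if len(np.unique(T)) < 3:
        raise ValueError("need at least 3 distinct temperatures")
    x3 = np.array([r.x3 for r in records], dtype=float)
    if np.any(x3 <= 0):
        raise ValueError("non-positive solubility")

    u = 1.0 / T - 1.0 / Thm
    y = np.log(x3)
    if np.allclose(u, u[0]):
        raise ValueError("zero predictor variance: all temperatures equal")

    if weighted:
        sd_ln = np.array([r.sd / r.x3 if r.sd > 0 else np.nan for r in records])
        if np.any(np.isnan(sd_ln)):
            raise ValueError("weighted fit requires positive sd on every record")
        w = 1.0 / sd_ln**2
    else:
        w = np.ones_like(y)

    W = np.sum(w)
    ubar = np.sum(w * u) / W
    ybar = np.sum(w * y) / W
    Suu = np.sum(w * (u - ubar) ** 2)
    m = float(np.sum(w * (u - ubar) * (y - ybar)) / Suu)
    a = float(ybar - m * ubar)

    n = len(records)
    resid = y - (m * u + a)
    s2 = float(np.sum(w * resid**2) / (n - 2))
    se_m = math.sqrt(s2 / Suu)
    se_a = math.sqrt(s2 * (1.0 / W + ubar**2 / Suu))
    return VantHoffFit(
        w1=w1, m=m, a=a, se_m=se_m, se_a=se_a,
        Thm=Thm, n_points=n, residual_variance=s2,
    )


@dataclass(frozen=True)
class SolutionThermo:
    """Apparent thermodynamic solution functions at one composition.

    Units: ``dG``, ``dH``, ``TdS`` in kJ·mol⁻¹; ``dS`` in J·mol⁻¹·K⁻¹.
    ``zeta_H``/``zeta_TS`` are the dimensionless enthalpic/entropic shares of
    the Gibbs-energy magnitude; sd_* are first-order propagated standard
    deviations.
    """

    w1: float
    Thm: float
    dG: float
    dH: float
    dS: float
    TdS: float
    zeta_H: float
    zeta_TS: float
    sd_dG: float
    sd_dH: float
    sd_dS: float
    sd_TdS: float


def zeta_contributions(dH: float, TdS: float) -> tuple[float, float]:
    """Fractional enthalpic and entropic contributions to the Gibbs energy.

    ζH = |ΔH| / (|ΔH| + |TΔS|), ζTS = 1 − ζH.  Both arguments must be on the
    same energy scale (kJ·mol⁻¹): the entropic term is T·ΔS, not bare ΔS.
    """
    denom = abs(dH) + abs(TdS)
    if denom == 0:
        raise ValueError("zeta undefined: dH and TdS both zero")
    zeta_H = abs(dH) / denom
    return zeta_H, 1.0 - zeta_H


def solution_functions(fit: VantHoffFit, R: float = GAS_CONSTANT) -> SolutionThermo:
    """Apparent solution functions and propagated uncertainties from a fit.

    ΔH = −R·m/1000, ΔG = −R·Thm·a/1000 (kJ·mol⁻¹), ΔS = (ΔH − ΔG)·1000/Thm
    (J·mol⁻¹·K⁻¹).  With the centred predictor cov(m, a) = 0, so
    sd(TΔS) = sqrt(sd(ΔH)² + sd(ΔG)²).
    """
    dH = -R * fit.m / 1000.0
    dG = -R * fit.Thm * fit.a / 1000.0
    TdS = dH - dG
    dS = TdS * 1000.0 / fit.Thm
    sd_dH = R * fit.se_m / 1000.0
    sd_dG = R * fit.Thm * fit.se_a / 1000.0
    sd_TdS = math.hypot(sd_dH, sd_dG)
    sd_dS = sd_TdS * 1000.0 / fit.Thm
    if dH == 0 and TdS == 0:
        zeta_H, zeta_TS = float("nan"), float("nan")
    else:
        zeta_H, zeta_TS = zeta_contributions(dH, TdS)
    return SolutionThermo(
        w1=fit.w1, Thm=fit.Thm, dG=dG, dH=dH, dS=dS, TdS=TdS,
        zeta_H=zeta_H, zeta_TS=zeta_TS,
        sd_dG=sd_dG, sd_dH=sd_dH, sd_dS=sd_dS, sd_TdS=sd_TdS,
    )


class SolutionThermodynamics:
    """Van't Hoff–Krug model of a temperature–composition solubility grid.

    Parameters
    ----------
    table : SolubilityTable
        Measurement grid; every composition needs ≥3 temperatures.
    gas_constant : float
        Molar gas constant, J·mol⁻¹·K⁻¹.

    Examples
    --------
    >>> from cosolvency.datasets import load_smt_mecn_etoh
    >>> res = SolutionThermodynamics(load_smt_mecn_etoh()).fit()
    >>> round(res.thermo[0].dG, 2)
    17.39
    """

    def __init__(self, table: SolubilityTable, gas_constant: float = GAS_CONSTANT):
        table.require_fittable()
        self.table = table
        self.gas_constant = gas_constant
        #: harmonic mean of the (pooled) study temperatures
        self.Thm = harmonic_mean_temperature(table.temperatures)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SolutionThermodynamics":
        """Build from a long-format DataFrame with columns w1, T_K, x3[, sd]."""
        return cls(SolubilityTable.from_frame(df), **kwargs)

    def fit(self, weighted: bool = False) -> "SolutionThermoResults":
        """Fit every composition and return the results object."""
        fits = [
            fit_vant_hoff_krug(self.table.at_composition(w1), self.Thm, weighted=weighted)
            for w1 in self.table.compositions
        ]
        thermo = [solution_functions(f, self.gas_constant) for f in fits]
        return SolutionThermoResults(self, fits, thermo)


class SolutionThermoResults:
    """Fitted apparent solution functions across the composition grid.

    Attributes
    ----------
    fits : list of VantHoffFit
        Per-composition regression results, ascending in w1.
    thermo : list of SolutionThermo
        Per-composition thermodynamic functions.
    """

    def __init__(self, model: SolutionThermodynamics, fits, thermo):
        self.model = model
        self.fits: list[VantHoffFit] = fits
        self.thermo: list[SolutionThermo] = thermo

    @property
    def Thm(self) -> float:
        return self.model.Thm

    def to_frame(self) -> pd.DataFrame:
        """Solution-function table (one row per composition)."""
        return pd.DataFrame(
            {
                "w1": [t.w1 for t in self.thermo],
                "dG": [t.dG for t in self.thermo],
                "sd_dG": [t.sd_dG for t in self.thermo],
                "dH": [t.dH for t in self.thermo],
                "sd_dH": [t.sd_dH for t in self.thermo],
                "dS": [t.dS for t in self.thermo],
                "sd_dS": [t.sd_dS for t in self.thermo],
                "TdS": [t.TdS for t in self.thermo],
                "sd_TdS": [t.sd_TdS for t in self.thermo],
                "zeta_H": [t.zeta_H for t in self.thermo],
                "zeta_TS": [t.zeta_TS for t in self.thermo],
            }
        )

    def mixing(self, ideal=None):
        """Decompose into mixing functions; see :mod:`cosolvency.mixing`."""
        from .mixing import MixingResults
        return MixingResults.from_solution(self, ideal)

    def perlovich(self, eps: float = 1e-9):
        """Sector classification of the (ΔH, TΔS) points; see :mod:`cosolvency.perlovich`."""
        from .perlovich import classify_points
        return classify_points(
            [(t.w1, t.dH, t.TdS) for t in self.thermo], eps=eps
        )

    def compensation(self):
        """Enthalpy–entropy compensation analysis along the composition grid."""
        from .perlovich import compensation_analysis
        return compensation_analysis(self.thermo)

    def summary(self) -> str:
        """Human-readable table in the conventional rounding (kJ to 2 dp,
        J·K⁻¹ to 1 dp, ζ to 3 dp)."""
        lines = [
            f"Apparent thermodynamic solution functions at Thm = {self.Thm:.1f} K",
            f"{'w1':>5} {'dG/kJ·mol⁻¹':>14} {'dH/kJ·mol⁻¹':>14} "
            f"{'dS/J·mol⁻¹K⁻¹':>15} {'TdS/kJ·mol⁻¹':>14} {'ζH':>6} {'ζTS':>6}",
        ]
        for t in self.thermo:
            lines.append(
                f"{t.w1:>5.2f} {t.dG:>7.2f} ± {t.sd_dG:<4.2f} {t.dH:>7.2f} ± {t.sd_dH:<4.2f} "
                f"{t.dS:>8.1f} ± {t.sd_dS:<4.1f} {t.TdS:>7.2f} ± {t.sd_TdS:<4.2f} "
                f"{t.zeta_H:>6.3f} {t.zeta_TS:>6.3f}"
            )
        return "\n".join(lines)
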