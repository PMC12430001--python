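"""Synthetic solubility surfaces for validating the analysis chain.

The generator produces tables with the statistical structure the analysis
assumes: van't Hoff-linear in 1/T, log-linear in composition (with an
optional symmetric non-ideality term δ·w1·w2 that breaks the log-linear
assumption on purpose), and multiplicative lognormal measurement noise
parameterised by a coefficient of variation.  The defaults mirror the study
conditions of the packaged dataset: the published pure-solvent coefficients,
a 21 × 9 grid, and a noise CV of 1.5% (the mid-range of the replicate
standard deviations of the printed table, which run ≈1–2% of x3).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SolubilityRecord, SolubilityTable
from .solution import (
    GAS_CONSTANT,
    SolutionThermodynamics,
    harmonic_mean_temperature,
)

__all__ = ["SyntheticSpec", "generate_table", "recovery_study"]

_DEFAULT_W1 = tuple(round(0.05 * i, 2) for i in range(21))
_DEFAULT_T = tuple(278.15 + 5.0 * i for i in range(9))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a synthetic solubility surface.

    ``A1``/``B1`` and ``A2``/``B2`` are the pure-solvent van't Hoff
    coefficients (A in K, B dimensionless); ``curvature`` is the amplitude δ
    of the non-ideality term δ·w1·(1−w1) added to ln x3; ``noise_cv`` the
    coefficient of variation of the multiplicative lognormal noise on each
    replicate.  Defaults reproduce the published SMT/MeCN+EtOH surface.
    """

    A1: float = -3408.7
    B1: float = 5.9236
    A2: float = -3531.1
    B2: float = 4.8307
    curvature: float = 0.0
    noise_cv: float = 0.015
    w1_grid: tuple = _DEFAULT_W1
    T_grid: tuple = _DEFAULT_T
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.w1_grid or not self.T_grid:
            raise ValueError("grids must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def mean_ln_x3(self, w1: float, T: float) -> float:
        """Noise-free ln x3 at a grid point."""
        return (
            w1 * (self.A1 / T + self.B1)
            + (1.0 - w1) * (self.A2 / T + self.B2)
            + self.curvature * w1 * (1.0 - w1)
        )

    def true_solution_functions(self, w1: float) -> tuple[float, float]:
        """Exact (dG, dH) in kJ·mol⁻¹ implied by the generative surface.

        The slope of ln x3 in 1/T is w1·A1 + (1−w1)·A2 (the curvature term
        is temperature-independent), so dH is closed-form; dG follows from
        the mean of ln x3 over the temperature grid evaluated at Thm.
        """
        slope = w1 * self.A1 + (1.0 - w1) * self.A2
        dH = -GAS_CONSTANT * slope / 1000.0
        Thm = harmonic_mean_temperature(self.T_grid)
        a = float(np.mean([self.mean_ln_x3(w1, T) for T in self.T_grid]))
        dG = -GAS_CONSTANT * Thm * a / 1000.0
        return dG, dH


def generate_table(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SolubilityTable:
    """Draw one synthetic solubility table under ``spec``.

    At each grid point the mean solubility is μ = exp(ln μ) from the
    generative surface; ``n_replicates`` lognormal replicates with mean μ and
    CV ``noise_cv`` are drawn, and their sample mean and standard deviation
    are recorded — the same reduction an experimental table reports.  With
    ``noise_cv = 0`` the table is exactly the noise-free surface (sd = 0).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    records = []
    for w1 in spec.w1_grid:
        for T in spec.T_grid:
            mu = float(np.exp(spec.mean_ln_x3(w1, T)))
            if not 0.0 < mu < 1.0:
                raise ValueError(
                    f"generative mean solubility {mu:.3g} outside (0, 1) "
                    f"at (w1={w1}, T={T})"
                )
            if spec.noise_cv == 0:
                x3, sd = mu, 0.0
            else:
                # lognormal with mean mu: ln-scale location ln(mu) - sigma^2/2
                reps = mu * np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=spec.n_replicates)
                )
                x3 = float(np.mean(reps))
                sd = float(np.std(reps, ddof=1)) if spec.n_replicates > 1 else 0.0
            records.append(
                SolubilityRecord(w1=float(w1), T=float(T), x3=x3, sd=sd,
                                 n_replicates=spec.n_replicates)
            )
    return SolubilityTable(
        records=records,
        solute="synthetic",
        meta={"seed": spec.seed, "noise_cv": spec.noise_cv,
              "curvature": spec.curvature},
    )


def recovery_study(spec: SyntheticSpec, n_sims: int) -> pd.DataFrame:
    """Monte-Carlo calibration of the van't Hoff–Krug fits under ``spec``.

    Simulates ``n_sims`` tables, refits each, and summarises per composition:
    mean bias of the recovered dH and dG against the generative truth, the
    empirical SD of the estimates across simulations, the mean propagated
    standard error, and the empirical coverage of the 95% confidence
    intervals (t, n − 2 df).
    """
    if n_sims < 2:
        raise ValueError("need at least 2 simulations")
    if len(spec.T_grid) < 3:
        raise ValueError("degenerate spec: need at least 3 temperatures")
    from scipy import stats

    rng = np.random.default_rng(spec.seed)
    tcrit = stats.t.ppf(0.975, len(spec.T_grid) - 2)
    truth = {w1: spec.true_solution_functions(w1) for w1 in spec.w1_grid}

    acc: dict[float, dict[str, list]] = {
        w1: {"dH": [], "dG": [], "se_dH": [], "se_dG": [],
             "cover_dH": [], "cover_dG": []}
        for w1 in spec.w1_grid
    }
    for _ in range(n_sims):
        table = generate_table(spec, rng=rng)
        res = SolutionThermodynamics(table).fit()
        for t in res.thermo:
            dG_true, dH_true = truth[t.w1]
            a = acc[t.w1]
            a["dH"].append(t.dH)
            a["dG"].append(t.dG)
            a["se_dH"].append(t.sd_dH)
            a["se_dG"].append(t.sd_dG)
            a["cover_dH"].append(abs(t.dH - dH_true) <= tcrit * t.sd_dH)
            a["cover_dG"].append(abs(t.dG - dG_true) <= tcrit * t.sd_dG)

    rows = []
    for w1 in spec.w1_grid:
        a = acc[w1]
        dG_true, dH_true = truth[w1]
        rows.append(
            {
                "w1": w1,
                "dH_true": dH_true,
                "dG_true": dG_true,
                "bias_dH": float(np.mean(a["dH"]) - dH_true),
                "bias_dG": float(np.mean(a["dG"]) - dG_true),
                "sd_dH_empirical": float(np.std(a["dH"], ddof=1)),
                "sd_dG_empirical": float(np.std(a["dG"], ddof=1)),
                "se_dH_mean": float(np.mean(a["se_dH"])),
                "se_dG_mean": float(np.mean(a["se_dG"])),
                "coverage_dH": float(np.mean(a["cover_dH"])),
                "coverage_dG": float(np.mean(a["cover_dG"])),
            }
        )
    return pd.DataFrame(rows)
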