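"""Ideal/mixing decomposition of the apparent solution functions.

Dissolution can be staged as (i) hypothetical fusion of the solute into a
supercooled liquid at the working temperature and (ii) mixing of that liquid
into the solvent.  The apparent solution functions therefore split as

    ΔsolnH° = ΔmixH° + ΔH_id,      ΔsolnS° = ΔmixS° + ΔS_id,

where the ideal-dissolution functions (ΔH_id, ΔS_id at the harmonic mean
temperature) are supplied as configuration — typically literature values of
the ideal dissolution process.  The mixing functions isolate cavity
formation and solute–solvent interaction energetics from the lattice term.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solution import SolutionThermo, SolutionThermoResults

__all__ = [
    "IdealSolutionFunctions",
    "MixingThermo",
    "mixing_functions",
    "derive_ideal_from_tables",
    "MixingResults",
]


@dataclass(frozen=True)
class IdealSolutionFunctions:
    """Ideal-dissolution enthalpy/entropy at the harmonic mean temperature.

    ``dH_id`` in kJ·mol⁻¹, ``dS_id`` in J·mol⁻¹·K⁻¹; ``dG_id`` follows as
    dH_id − Thm·dS_id/1000.  ``source`` records where the numbers came from.
    """

    dH_id: float
    dS_id: float
    Thm: float
    sd_dH_id: float = 0.0
    sd_dS_id: float = 0.0
    source: str = ""

    @property
    def TdS_id(self) -> float:
        return self.Thm * self.dS_id / 1000.0

    @property
    def dG_id(self) -> float:
        return self.dH_id - self.TdS_id


@dataclass(frozen=True)
class MixingThermo:
    """Thermodynamic mixing functions at one composition (units as SolutionThermo)."""

    w1: float
    Thm: float
    dG_mix: float
    dH_mix: float
    dS_mix: float
    TdS_mix: float
    sd_dG_mix: float
    sd_dH_mix: float
    sd_dS_mix: float
    sd_TdS_mix: float


def mixing_functions(
    sol: SolutionThermo,
    ideal: IdealSolutionFunctions,
    Thm_tol: float = 0.5,
) -> MixingThermo:
    """Subtract the ideal-dissolution contribution from the solution functions.

    The two inputs must refer to the same harmonic mean temperature (within
    ``Thm_tol`` K, to absorb the rounding of printed Thm values).  Ideal
    uncertainties, when provided, propagate in quadrature; otherwise the
    solution-function uncertainties carry over unchanged.
    """
    if abs(sol.Thm - ideal.Thm) > Thm_tol:
        raise ValueError(
            f"harmonic mean temperature mismatch: solution {sol.Thm:.2f} K vs "
            f"ideal {ideal.Thm:.2f} K"
        )
    dH_mix = sol.dH - ideal.dH_id
    dS_mix = sol.dS - ideal.dS_id
    TdS_mix = sol.TdS - ideal.TdS_id
    dG_mix = dH_mix - TdS_mix
    sd_dH = math.hypot(sol.sd_dH, ideal.sd_dH_id)
    sd_dS = math.hypot(sol.sd_dS, ideal.sd_dS_id)
    sd_TdS = math.hypot(sol.sd_TdS, ideal.sd_dS_id * sol.Thm / 1000.0)
    sd_dG_id = math.hypot(ideal.sd_dH_id, ideal.sd_dS_id * sol.Thm / 1000.0)
    sd_dG = math.hypot(sol.sd_dG, sd_dG_id)
    return MixingThermo(
        w1=sol.w1, Thm=sol.Thm,
        dG_mix=dG_mix, dH_mix=dH_mix, dS_mix=dS_mix, TdS_mix=TdS_mix,
        sd_dG_mix=sd_dG, sd_dH_mix=sd_dH, sd_dS_mix=sd_dS, sd_TdS_mix=sd_TdS,
    )


def derive_ideal_from_tables(
    sol_df: pd.DataFrame,
    mix_df: pd.DataFrame,
    Thm: float,
    tol: float = 0.3,
) -> tuple[IdealSolutionFunctions, dict]:
    """Back-derive the ideal functions as the mean of (solution − mixing) rows.

    Inverse bookkeeping of the decomposition, for calibrating a default
    configuration from a published pair of tables.  Expects columns ``w1``,
    ``dH``/``dH_mix`` and ``dS``/``dS_mix``.  Returns the composition-averaged
    differences and a spread report; warns (in the report) when the spread
    exceeds ``tol``, which indicates the two tables are not consistent with a
    composition-independent ideal term.
    """
    sol_df = sol_df.sort_values("w1").reset_index(drop=True)
    mix_df = mix_df.sort_values("w1").reset_index(drop=True)
    if not np.allclose(sol_df["w1"].to_numpy(), mix_df["w1"].to_numpy()):
        raise ValueError("unmatched compositions between solution and mixing tables")
    dH_diff = sol_df["dH"].to_numpy() - mix_df["dH_mix"].to_numpy()
    dS_diff = sol_df["dS"].to_numpy() - mix_df["dS_mix"].to_numpy()
    spread = {
        "dH_spread": float(np.ptp(dH_diff)),
        "dS_spread": float(np.ptp(dS_diff)),
        "dH_sd": float(np.std(dH_diff)),
        "dS_sd": float(np.std(dS_diff)),
        "exceeds_tol": bool(np.ptp(dH_diff) > tol or np.ptp(dS_diff) > tol * 10),
    }
    ideal = IdealSolutionFunctions(
        dH_id=float(np.mean(dH_diff)),
        dS_id=float(np.mean(dS_diff)),
        Thm=Thm,
        source="derived: composition-averaged (solution − mixing) differences",
    )
    return ideal, spread


class MixingResults:
    """Mixing functions across the composition grid, derived from a
    :class:`~cosolvency.solution.SolutionThermoResults`."""

    def __init__(self, solution: SolutionThermoResults,
                 ideal: IdealSolutionFunctions, mixing: list[MixingThermo]):
        self.solution = solution
        self.ideal = ideal
        self.mixing = mixing

    @classmethod
    def from_solution(cls, solution: SolutionThermoResults,
                      ideal: IdealSolutionFunctions | None = None) -> "MixingResults":
        if ideal is None:
            from .datasets import default_ideal_solution
            ideal = default_ideal_solution()
        rows = [mixing_functions(t, ideal) for t in solution.thermo]
        return cls(solution, ideal, rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w1": [m.w1 for m in self.mixing],
                "dG_mix": [m.dG_mix for m in self.mixing],
                "sd_dG_mix": [m.sd_dG_mix for m in self.mixing],
                "dH_mix": [m.dH_mix for m in self.mixing],
                "sd_dH_mix": [m.sd_dH_mix for m in self.mixing],
                "dS_mix": [m.dS_mix for m in self.mixing],
                "sd_dS_mix": [m.sd_dS_mix for m in self.mixing],
                "TdS_mix": [m.TdS_mix for m in self.mixing],
                "sd_TdS_mix": [m.sd_TdS_mix for m in self.mixing],
            }
        )

    def perlovich(self, eps: float = 1e-9):
        """Sector classification of the (ΔH_mix, TΔS_mix) points."""
        from .perlovich import classify_points
        return classify_points(
            [(m.w1, m.dH_mix, m.TdS_mix) for m in self.mixing], eps=eps
        )

    def summary(self) -> str:
        lines = [
            f"Thermodynamic mixing functions at Thm = {self.solution.Thm:.1f} K "
            f"(ideal: dH_id={self.ideal.dH_id:.2f} kJ·mol⁻¹, "
            f"dS_id={self.ideal.dS_id:.1f} J·mol⁻¹K⁻¹)",
            f"{'w1':>5} {'dG_mix':>12} {'dH_mix':>12} {'dS_mix':>12} {'TdS_mix':>12}",
        ]
        for m in self.mixing:
            lines.append(
                f"{m.w1:>5.2f} {m.dG_mix:>12.2f} {m.dH_mix:>12.2f} "
                f"{m.dS_mix:>12.1f} {m.TdS_mix:>12.2f}"
            )
        return "\n".join(lines)
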