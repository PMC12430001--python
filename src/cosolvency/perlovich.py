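"""Perlovich driving-force diagram and enthalpy–entropy compensation.

A Perlovich diagram plots the entropic term TΔS against the enthalpy ΔH of a
process and partitions the plane into eight sectors.  Sectors I, IV, V and
VIII mark enthalpy-dominated processes (|ΔH| > |TΔS|); II, III, VI and VII
entropy-dominated ones.  Classification here is quadrant-first so the
sectors are disjoint and exhaustive:

    quadrant (+,+): I  if ΔH > TΔS   else II
    quadrant (−,+): IV if |ΔH| > |TΔS| else III
    quadrant (−,−): V  if |ΔH| > |TΔS| else VI
    quadrant (+,−): VIII if |ΔH| > |TΔS| else VII

Compensation analysis follows the trajectory of (ΔG, ΔH) along the
composition grid: the composition of minimum ΔH splits the grid into an
enthalpy-driven and an entropy-driven segment (Bustamante's criterion).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .solution import SolutionThermo

__all__ = [
    "ENTHALPIC_SECTORS",
    "SectorPoint",
    "classify_sector",
    "classify_points",
    "PerlovichResults",
    "CompensationResult",
    "compensation_analysis",
]

#: Sectors where the process is driven by enthalpy.
ENTHALPIC_SECTORS = frozenset({"I", "IV", "V", "VIII"})


@dataclass(frozen=True)
class SectorPoint:
    """A classified (ΔH, TΔS) point."""

    w1: float | None
    dH: float
    TdS: float
    sector: str
    driver: str  # "enthalpic" | "entropic"
    boundary: bool  # within eps of a sector boundary


def classify_sector(dH: float, TdS: float, eps: float = 1e-9) -> SectorPoint:
    """Assign a (ΔH, TΔS) point (kJ·mol⁻¹) to one of the eight sectors.

    Values within ``eps`` of zero (or of the |ΔH| = |TΔS| diagonal) are
    classified by the non-strict convention but flagged ``boundary=True``.
    A point with both coordinates within ``eps`` of the origin is
    unclassifiable and raises ``ValueError``.
    """
    if not (np.isfinite(dH) and np.isfinite(TdS)):
        raise ValueError("non-finite input")
    if abs(dH) < eps and abs(TdS) < eps:
        raise ValueError("origin point unclassifiable")
    boundary = abs(dH) < eps or abs(TdS) < eps or abs(abs(dH) - abs(TdS)) < eps
    h_pos = dH >= 0
    s_pos = TdS >= 0
    if h_pos and s_pos:
        sector = "I" if dH > TdS else "II"
    elif not h_pos and s_pos:
        sector = "IV" if abs(dH) > abs(TdS) else "III"
    elif not h_pos and not s_pos:
        sector = "V" if abs(dH) > abs(TdS) else "VI"
    else:
        sector = "VIII" if abs(dH) > abs(TdS) else "VII"
    driver = "enthalpic" if sector in ENTHALPIC_SECTORS else "entropic"
    return SectorPoint(w1=None, dH=dH, TdS=TdS, sector=sector,
                       driver=driver, boundary=boundary)


def classify_points(
    points: Sequence[tuple[float, float, float]], eps: float = 1e-9
) -> "PerlovichResults":
    """Classify a sequence of (w1, dH, TdS) points."""
    classified = []
    for w1, dH, TdS in points:
        p = classify_sector(dH, TdS, eps=eps)
        classified.append(SectorPoint(w1=w1, dH=dH, TdS=TdS, sector=p.sector,
                                      driver=p.driver, boundary=p.boundary))
    return PerlovichResults(classified)


class PerlovichResults:
    """Sector classification of a set of process points."""

    def __init__(self, points: list[SectorPoint]):
        self.points = points

    @property
    def sectors(self) -> list[str]:
        return [p.sector for p in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w1": [p.w1 for p in self.points],
                "dH": [p.dH for p in self.points],
                "TdS": [p.TdS for p in self.points],
                "sector": [p.sector for p in self.points],
                "driver": [p.driver for p in self.points],
                "boundary": [p.boundary for p in self.points],
            }
        )

    def summary(self) -> str:
        counts = pd.Series(self.sectors).value_counts().to_dict()
        lines = ["Perlovich sector classification",
                 f"sector counts: {counts}"]
        for p in self.points:
            flag = " (boundary)" if p.boundary else ""
            lines.append(
                f"  w1={p.w1}: dH={p.dH:.2f}, TdS={p.TdS:.2f} → "
                f"sector {p.sector} [{p.driver}]{flag}"
            )
        return "\n".join(lines)


@dataclass
class CompensationResult:
    """Enthalpy–entropy compensation along the composition grid.

    ``w1_at_min_dH`` is the grid composition at which the apparent solution
    enthalpy is minimal; ``segments`` label the sub-trajectories on either
    side of it.  ``trajectory`` holds the ordered (w1, dG, dH, TdS) points;
    ``slopes`` the finite-difference dΔH/dΔG between consecutive
    compositions (a slope > 1 implies enthalpy-driven behaviour, < 1
    entropy-driven — reported as a diagnostic alongside the minimum-based
    segmentation).
    """

    trajectory: pd.DataFrame
    w1_at_min_dH: float
    segments: list[dict]
    slopes: pd.DataFrame

    def summary(self) -> str:
        seg = "; ".join(
            f"w1∈[{s['w1_start']:.2f}, {s['w1_end']:.2f}]: {s['driver']}-driven"
            for s in self.segments
        )
        return (
            f"Enthalpy–entropy compensation: minimum dH at w1 = "
            f"{self.w1_at_min_dH:.2f}\nsegments: {seg}"
        )


def compensation_analysis(thermo: Sequence[SolutionThermo]) -> CompensationResult:
    """Locate the enthalpy minimum and segment the composition grid by driver.

    Expects ≥3 compositions ordered (strictly increasing) in w1.  The grid
    composition with the smallest ΔH divides the trajectory: from the start
    to the minimum the process is labelled enthalpy-driven, from the minimum
    to the end entropy-driven.  Degenerate minima at an endpoint yield a
    single segment.
    """
    if len(thermo) < 3:
        raise ValueError("need at least 3 compositions")
    w1 = np.array([t.w1 for t in thermo], dtype=float)
    if np.any(np.diff(w1) <= 0):
        raise ValueError("compositions must be strictly increasing in w1")
    dH = np.array([t.dH for t in thermo], dtype=float)
    dG = np.array([t.dG for t in thermo], dtype=float)
    TdS = np.array([t.TdS for t in thermo], dtype=float)

    imin = int(np.argmin(dH))
    w1_min = float(w1[imin])

    segments: list[dict] = []
    if imin > 0:
        segments.append(
            {"w1_start": float(w1[0]), "w1_end": w1_min, "driver": "enthalpy"}
        )
    if imin < len(w1) - 1:
        segments.append(
            {"w1_start": w1_min, "w1_end": float(w1[-1]), "driver": "entropy"}
        )

    trajectory = pd.DataFrame({"w1": w1, "dG": dG, "dH": dH, "TdS": TdS})
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.diff(dH) / np.diff(dG)
    slopes = pd.DataFrame(
        {"w1_from": w1[:-1], "w1_to": w1[1:], "dH_dG_slope": slope}
    )
    return CompensationResult(
        trajectory=trajectory, w1_at_min_dH=w1_min,
        segments=segments, slopes=slopes,
    )
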