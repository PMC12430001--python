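"""Packaged study datasets.

The package ships the published measurement grid for sulfamethazine (SMT)
in acetonitrile–ethanol cosolvent mixtures: 21 compositions (w1 = 0.00 to
1.00 in steps of 0.05) × 9 temperatures (278.15 to 318.15 K in steps of 5 K),
189 equilibrium mole-fraction solubilities with replicate standard
deviations, plus the fusion calorimetry of the solid phases and a default
ideal-dissolution configuration for the mixing decomposition.
"""
from __future__ import annotations

import csv
import json
from importlib import resources

from .io import FusionRecord, SolubilityTable, read_solubility_table
from .mixing import IdealSolutionFunctions

__all__ = ["load_smt_mecn_etoh", "load_smt_fusion", "default_ideal_solution"]

_DATA = resources.files("cosolvency") / "data"


def load_smt_mecn_etoh() -> SolubilityTable:
    """The SMT in {MeCN (1) + EtOH (2)} solubility grid (189 records)."""
    with resources.as_file(_DATA / "smt_mecn_etoh.csv") as path:
        return read_solubility_table(
            path,
            scale_hint="e4",
            pressure_MPa=0.096,
            temperature_uncertainty_K=0.05,
            solute="sulfamethazine",
            solvent1="acetonitrile",
            solvent2="ethanol",
        )


def load_smt_fusion() -> list[FusionRecord]:
    """Fusion enthalpies/temperatures of SMT solid phases (DSC)."""
    text = (_DATA / "smt_fusion.csv").read_text()
    records = []
    for row in csv.DictReader(text.splitlines()):
        records.append(
            FusionRecord(
                sample_label=row["sample_label"],
                dHfus=float(row["dHfus_kJ_mol"]),
                Tfus=float(row["Tfus_K"]),
                sd_dHfus=float(row["sd_dHfus"]),
                sd_Tfus=float(row["sd_Tfus"]),
            )
        )
    return records


def default_ideal_solution() -> IdealSolutionFunctions:
    """Default ideal-dissolution functions for the SMT mixing decomposition.

    These are back-derived (solution minus mixing, averaged over the
    composition grid) rather than taken from calorimetric literature; see the
    ``source`` field.  Supply literature values to override.
    """
    payload = json.loads((_DATA / "ideal_solution.json").read_text())
    return IdealSolutionFunctions(
        dH_id=payload["dH_id_kJ"],
        dS_id=payload["dS_id_J_per_K"],
        Thm=payload["Thm_K"],
        source=payload.get("source", ""),
    )
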