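"""Reading, validation and writing of solubility and thermodynamic tables.

The central container is :class:`SolubilityTable`, a validated collection of
``(w1, T, x3, sd)`` equilibrium solubility measurements on a composition ×
temperature grid.  ``w1`` is the mass fraction of cosolvent 1 in the
solute-free solvent mixture, ``T`` the absolute temperature in kelvin and
``x3`` the mole-fraction solubility of the solute.

Published tables in this field conventionally print ``10^4·x3``; the reader
accepts either that scaled convention (column ``x3_e4``) or raw mole
fractions (column ``x3`` with ``scale_hint="raw"``).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SolubilityRecord",
    "SolubilityTable",
    "FusionRecord",
    "read_solubility_table",
    "write_thermo_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolubilityRecord:
    """One saturation measurement: composition, temperature, solubility.

    Parameters
    ----------
    w1 : float
        Mass fraction of cosolvent 1 in the solute-free mixture, in [0, 1].
    T : float
        Absolute temperature, K.
    x3 : float
        Mole-fraction solubility of the solute, in (0, 1).
    sd : float
        Standard deviation of ``x3`` over replicates (same scale as ``x3``).
    n_replicates : int, optional
        Replicate count behind ``x3`` and ``sd``, when known.
    """

    w1: float
    T: float
    x3: float
    sd: float = 0.0
    n_replicates: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError(f"w1={self.w1} outside [0, 1]")
        if not self.T > 0:
            raise ValueError(f"T={self.T} K must be positive")
        if not 0.0 < self.x3 < 1.0:
            raise ValueError(f"x3={self.x3} outside (0, 1) at w1={self.w1}, T={self.T}")
        if self.sd < 0:
            raise ValueError(f"sd={self.sd} must be non-negative")


@dataclass(frozen=True)
class FusionRecord:
    """Melting temperature and enthalpy of fusion of one solid sample."""

    sample_label: str
    dHfus: float  # kJ/mol
    Tfus: float  # K
    sd_dHfus: float = 0.0
    sd_Tfus: float = 0.0

    def __post_init__(self) -> None:
        if self.dHfus <= 0:
            raise ValueError("enthalpy of fusion must be positive")
        if self.Tfus <= 0:
            raise ValueError("melting temperature must be positive")


@dataclass
class SolubilityTable:
    """A validated grid of solubility measurements with study metadata."""

    records: list[SolubilityRecord]
    pressure_MPa: float | None = None
    temperature_uncertainty_K: float | None = None
    solute: str = ""
    solvent1: str = ""
    solvent2: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        seen: set[tuple[float, float]] = set()
        for rec in self.records:
            key = (rec.w1, rec.T)
            if key in seen:
                raise ValueError(f"duplicate (w1, T) pair {key}")
            seen.add(key)
        self.records = sorted(self.records, key=lambda r: (r.w1, r.T))

    # -- accessors ---------------------------------------------------------

    @property
    def compositions(self) -> list[float]:
        """Distinct ``w1`` values, ascending."""
        return sorted({r.w1 for r in self.records})

    @property
    def temperatures(self) -> list[float]:
        """Distinct temperatures, ascending."""
        return sorted({r.T for r in self.records})

    def at_composition(self, w1: float) -> list[SolubilityRecord]:
        recs = [r for r in self.records if r.w1 == w1]
        if not recs:
            raise KeyError(f"no records at w1={w1}")
        return recs

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns w1, T_K, x3, sd, n."""
        return pd.DataFrame(
            {
                "w1": [r.w1 for r in self.records],
                "T_K": [r.T for r in self.records],
                "x3": [r.x3 for r in self.records],
                "sd": [r.sd for r in self.records],
                "n": [r.n_replicates for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **metadata) -> "SolubilityTable":
        """Build a table from a DataFrame with columns w1, T_K, x3[, sd, n]."""
        records = [
            SolubilityRecord(
                w1=float(row.w1),
                T=float(row.T_K),
                x3=float(row.x3),
                sd=float(getattr(row, "sd", 0.0) or 0.0),
                n_replicates=(int(row.n) if "n" in df.columns and pd.notna(row.n) else None),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, **metadata)

    def require_fittable(self, min_temperatures: int = 3) -> None:
        """Raise if any composition has too few temperatures for regression."""
        short = [
            w1
            for w1 in self.compositions
            if len(self.at_composition(w1)) < min_temperatures
        ]
        if short:
            raise ValueError(
                f"compositions with fewer than {min_temperatures} temperatures: {short}"
            )


def read_solubility_table(
    path: str | Path,
    scale_hint: str | None = None,
    **metadata,
) -> SolubilityTable:
    """Read a long-format solubility CSV into a :class:`SolubilityTable`.

    Expected columns: ``w1``, ``T_K`` and either ``x3_e4`` (solubility times
    10^4, the printed-table convention) or ``x3`` (raw mole fraction);
    optional ``sd``/``sd_e4`` and ``n``.

    Parameters
    ----------
    path : path-like
        CSV file.
    scale_hint : {"e4", "raw", None}
        Force the interpretation of the solubility column.  By default the
        column name decides: ``x3_e4`` is scaled, ``x3`` is raw.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no records in {path}")
    required = {"w1", "T_K"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns {sorted(required - set(df.columns))} in {path}")

    if "x3_e4" in df.columns:
        col, col_scaled = "x3_e4", True
    elif "x3" in df.columns:
        col, col_scaled = "x3", False
    else:
        raise ValueError(f"no solubility column (x3 or x3_e4) in {path}")
    if scale_hint == "raw":
        col_scaled = False
    elif scale_hint == "e4":
        col_scaled = True
    elif scale_hint is not None:
        raise ValueError(f"unknown scale_hint {scale_hint!r}")

    if df[col].isna().any():
        raise ValueError(f"missing solubility values in {path}")
    scale = 1e-4 if col_scaled else 1.0

    sd_col = next((c for c in ("sd_e4", "sd") if c in df.columns), None)
    if sd_col is None:
        logger.warning("no sd column in %s; standard deviations set to 0", path)
        sds = [0.0] * len(df)
    else:
        # sd_e4 is always on the 10^4 scale; a plain sd column shares x3's scale
        sd_scale = 1e-4 if sd_col == "sd_e4" else scale
        sds = [0.0 if pd.isna(v) else float(v) * sd_scale for v in df[sd_col]]

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        x3 = float(getattr(row, col)) * scale
        if x3 <= 0:
            raise ValueError(f"non-positive solubility in row {i} (w1={row.w1}, T={row.T_K})")
        records.append(
            SolubilityRecord(
                w1=float(row.w1),
                T=float(row.T_K),
                x3=x3,
                sd=sds[i],
                n_replicates=(int(row.n) if "n" in df.columns and pd.notna(row.n) else None),
            )
        )
    table = SolubilityTable(records=records, **metadata)
    table.require_fittable()
    return table


def _format_pm(value: float, sd: float | None, decimals: int) -> str:
    if sd is None or (isinstance(sd, float) and (math.isnan(sd) or sd == 0)):
        return f"{value:.{decimals}f}"
    return f"{value:.{decimals}f} ± {sd:.{decimals}f}"


def write_thermo_table(
    df: pd.DataFrame,
    path: str | Path,
    value_columns: Sequence[tuple[str, str | None, int]] | None = None,
) -> None:
    """Write a thermodynamic result table as display TSV + full-precision sidecar.

    The TSV renders each value column as ``value ± sd`` rounded to the stated
    number of decimals (the convention of printed thermodynamic tables); the
    JSON sidecar at ``<path>.json`` keeps every number at machine precision so
    a read-back is value-identical.

    Parameters
    ----------
    df : DataFrame
        Homogeneous result rows.
    path : path-like
        Output TSV path; the sidecar is written next to it.
    value_columns : sequence of (column, sd_column or None, decimals)
        Formatting plan.  Defaults to every non-sd column at 4 decimals,
        paired with ``sd_<column>`` when present.
    """
    path = Path(path)
    if df.empty:
        logger.warning("writing header-only thermo table to %s", path)
    if value_columns is None:
        value_columns = [
            (c, f"sd_{c}" if f"sd_{c}" in df.columns else None, 4)
            for c in df.columns
            if not c.startswith("sd_")
        ]
    out = pd.DataFrame(index=df.index)
    for col, sd_col, dec in value_columns:
        if sd_col is not None and sd_col in df.columns:
            out[col] = [
                _format_pm(v, s, dec) for v, s in zip(df[col], df[sd_col])
            ]
        else:
            out[col] = [f"{v:.{dec}f}" if isinstance(v, float) else v for v in df[col]]
    out.to_csv(path, sep="\t", index=False)
    sidecar = {c: [None if pd.isna(v) else v for v in df[c]] for c in df.columns}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_thermo_sidecar(path: str | Path) -> pd.DataFrame:
    """Read back the machine-precision sidecar written by :func:`write_thermo_table`."""
    payload = json.loads(Path(path).read_text())
    return pd.DataFrame(payload)
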