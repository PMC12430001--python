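"""End-to-end analysis pipeline: read → solution → mixing → driving force →
predictor validation, with structured file outputs.

Everything the pipeline writes is deterministic for fixed inputs and config:
machine-readable JSON carries full precision, display TSVs follow the
conventional rounding of printed thermodynamic tables so they can be diffed
visually against published tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .io import SolubilityTable, read_solubility_table, write_thermo_table
from .mixing import IdealSolutionFunctions
from .predictor import YalkowskyRosemanVantHoff
from .solution import GAS_CONSTANT, SolutionThermodynamics

__all__ = ["AnalysisConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Options controlling a full analysis run."""

    gas_constant: float = GAS_CONSTANT
    weighted: bool = False
    fit_mode: str = "two_point"  # predictor: two_point | ols_all
    ideal_solution: dict | None = None  # {dH_id_kJ, dS_id_J_per_K, source}
    scale_hint: str | None = None
    output_dir: str = "cosolvency_report"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_full_analysis(
    table: SolubilityTable | str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run every analysis stage on a solubility table and write the report.

    Returns a manifest dict naming the written artifacts.  The mixing stage
    is skipped (with a logged notice) when no ideal-dissolution functions are
    configured and the packaged default does not apply; every other stage
    always runs.  Raises with a stage-named message on failure.
    """
    config = config or AnalysisConfig()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    checksum = None
    if not isinstance(table, SolubilityTable):
        raw = Path(table).read_bytes()
        checksum = hashlib.sha256(raw).hexdigest()
        table = read_solubility_table(table, scale_hint=config.scale_hint)

    artifacts: dict[str, str] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return wrap

    # solution stage
    def _solution():
        model = SolutionThermodynamics(table, gas_constant=config.gas_constant)
        return model.fit(weighted=config.weighted)
    sol = _stage("solution")(_solution)

    sol_path = outdir / "solution_functions.tsv"
    write_thermo_table(
        sol.to_frame(), sol_path,
        value_columns=[("w1", None, 2), ("dG", "sd_dG", 2), ("dH", "sd_dH", 2),
                       ("dS", "sd_dS", 1), ("TdS", "sd_TdS", 2),
                       ("zeta_H", None, 3), ("zeta_TS", None, 3)],
    )
    artifacts["solution_tsv"] = str(sol_path)

    # mixing stage (optional)
    ideal = None
    if config.ideal_solution is not None:
        blk = config.ideal_solution
        ideal = IdealSolutionFunctions(
            dH_id=blk["dH_id_kJ"], dS_id=blk["dS_id_J_per_K"],
            Thm=blk.get("Thm_K", sol.Thm),
            sd_dH_id=blk.get("sd_dH_id", 0.0), sd_dS_id=blk.get("sd_dS_id", 0.0),
            source=blk.get("source", "config"),
        )
    if ideal is None:
        logger.info("no ideal_solution block configured: mixing stage skipped")
    else:
        mix = _stage("mixing")(lambda: sol.mixing(ideal))
        mix_path = outdir / "mixing_functions.tsv"
        write_thermo_table(
            mix.to_frame(), mix_path,
            value_columns=[("w1", None, 2), ("dG_mix", "sd_dG_mix", 2),
                           ("dH_mix", "sd_dH_mix", 2), ("dS_mix", "sd_dS_mix", 1),
                           ("TdS_mix", "sd_TdS_mix", 2)],
        )
        artifacts["mixing_tsv"] = str(mix_path)
        perl_mix = mix.perlovich()
        perl_mix.to_frame().to_csv(outdir / "perlovich_mixing.tsv", sep="\t", index=False)
        artifacts["perlovich_mixing_tsv"] = str(outdir / "perlovich_mixing.tsv")

    # driving-force stage
    perl = _stage("perlovich")(sol.perlovich)
    perl.to_frame().to_csv(outdir / "perlovich_solution.tsv", sep="\t", index=False)
    artifacts["perlovich_solution_tsv"] = str(outdir / "perlovich_solution.tsv")

    comp = _stage("compensation")(sol.compensation)
    _dump_json(
        {"w1_at_min_dH": comp.w1_at_min_dH, "segments": comp.segments},
        outdir / "compensation.json",
    )
    comp.trajectory.to_csv(outdir / "compensation_trajectory.csv", index=False)
    artifacts["compensation_json"] = str(outdir / "compensation.json")
    artifacts["compensation_trajectory_csv"] = str(outdir / "compensation_trajectory.csv")

    # predictor stage
    def _predictor():
        return YalkowskyRosemanVantHoff(table).fit(mode=config.fit_mode)
    pred = _stage("predictor")(_predictor)
    d = pred.diagnostics
    _dump_json(
        {
            "A1": pred.params.A1, "B1": pred.params.B1,
            "A2": pred.params.A2, "B2": pred.params.B2,
            "fit_mode": pred.params.fit_mode,
            "mrd_percent": d.mrd_percent, "r2": d.r2, "adj_r2": d.adj_r2,
            "f_stat": d.f_stat, "p_value": d.p_value, "n_points": d.n_points,
            "ln_scale": pred.ln_scale_diagnostics(),
        },
        outdir / "predictor.json",
    )
    pred.deviations().to_csv(outdir / "predictor_deviations.tsv", sep="\t", index=False)
    artifacts["predictor_json"] = str(outdir / "predictor.json")
    artifacts["predictor_deviations_tsv"] = str(outdir / "predictor_deviations.tsv")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": checksum,
        "n_records": len(table.records),
        "Thm_K": sol.Thm,
        "artifacts": artifacts,
        "stages_run": sorted(
            {"solution", "perlovich", "compensation", "predictor"}
            | ({"mixing"} if ideal is not None else set())
        ),
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
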