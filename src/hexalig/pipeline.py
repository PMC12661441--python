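"""End-to-end pipeline: simulate -> extract -> fit -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .assembly import AssemblyParameters
from .config import RunConfig
from .extraction import (
    PopulationMatrix,
    build_grid,
    integrate_windows,
    normalize_within_oligomer,
)
from .fitting import TitrationPoint, bootstrap_ci, fit_binding
from .io import write_fit_report, write_population_csv
from .lattice import BindingParameters, build_topology
from .nms import SpectrumModel
from .scenarios import make_scenario, generate

__all__ = ["PipelineError", "run_pipeline", "spectrum_model_from_config", "extract_spectra"]

log = logging.getLogger("hexalig")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def spectrum_model_from_config(cfg: RunConfig) -> SpectrumModel:
    return SpectrumModel(**cfg.spectrum.model_dump())


def topologies_from_config(cfg: RunConfig):
    return {
        j: build_topology(j, cfg.topology.mode, cfg.topology.n_override)
        for j in range(1, cfg.topology.max_order + 1)
    }


def assembly_from_config(cfg: RunConfig) -> AssemblyParameters:
    if cfg.assembly.betas is not None:
        return AssemblyParameters(cfg.assembly.betas)
    return AssemblyParameters.nucleated(cfg.assembly.K_step, cfg.assembly.sigma)


def extract_spectra(spectra, atp_grid, model, topologies, extraction_cfg) -> list[PopulationMatrix]:
    grid = build_grid(
        model, topologies,
        charges=extraction_cfg.charges,
        window_halfwidth=extraction_cfg.window_halfwidth,
    )
    matrices = []
    for i, spec in enumerate(spectra):
        raw = integrate_windows(
            spec, grid,
            detection_sigmas=extraction_cfg.detection_sigmas,
            baseline=extraction_cfg.baseline,
        )
        matrices.append(
            normalize_within_oligomer(
                raw, meta={"titration_point": i, "l_tot": atp_grid[i]}
            )
        )
    return matrices


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> extract -> fit and write a self-contained report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.model_dump(), "seed": cfg.seed}

    # --- simulate -----------------------------------------------------------
    try:
        scenario = make_scenario(
            cfg.scenario.name,
            seed=cfg.seed,
            protomer_total=cfg.scenario.protomer_total,
            atp_grid=tuple(cfg.scenario.atp_grid),
            Kd_full=cfg.binding.Kd_full,
            Kd_partial=cfg.binding.Kd_partial,
            omega=cfg.binding.omega,
            K_step=cfg.assembly.K_step,
            sigma=cfg.assembly.sigma,
            **cfg.spectrum.model_dump(),
        )
        sim_dir = out / "simulated"
        manifest = generate(scenario, sim_dir)
        report["simulate"] = {"manifest": manifest, "dir": str(sim_dir)}
        log.info("simulated %d files into %s", len(manifest["files"]), sim_dir)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- extract ------------------------------------------------------------
    try:
        from .io import read_spectrum_csv

        model = spectrum_model_from_config(cfg)
        topologies = topologies_from_config(cfg)
        spectra = [
            read_spectrum_csv(p) for p in sorted(sim_dir.glob("spectrum_*.csv"))
        ]
        matrices = extract_spectra(
            spectra, cfg.scenario.atp_grid, model, topologies, cfg.extraction
        )
        pop_path = out / "populations.csv"
        write_population_csv(pop_path, matrices)
        report["extract"] = {"populations": str(pop_path)}
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc

    # --- fit ----------------------------------------------------------------
    try:
        points = []
        for i, m in enumerate(matrices):
            rows = {
                j: m.fractions[j]
                for j in cfg.fitting.fit_oligomers
                if j in m.fractions and not m.missing[j]
            }
            points.append(
                TitrationPoint(cfg.scenario.atp_grid[i], cfg.scenario.protomer_total, rows)
            )
        fixed = (
            {"log10_omega": cfg.fitting.fix_omega}
            if cfg.fitting.fix_omega is not None
            else None
        )
        fit = fit_binding(
            points,
            topologies,
            n_starts=cfg.fitting.n_starts,
            seed=cfg.seed,
            n_eff=cfg.fitting.n_eff,
            ligand_mode=cfg.fitting.ligand_mode,
            assembly=assembly_from_config(cfg),
            fixed=fixed,
        )
        if cfg.fitting.n_boot:
            bootstrap_ci(
                points, topologies, fit,
                n_boot=cfg.fitting.n_boot, seed=cfg.seed,
                assembly=assembly_from_config(cfg),
            )
        write_fit_report(out / "fit.json", fit, out / "fit.txt")
        report["fit"] = {
            "params": fit.params,
            "ci": {k: list(v) for k, v in fit.ci.items()},
            "nll": fit.nll,
            "omega_identified": fit.extra.get("omega_identified"),
        }
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
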