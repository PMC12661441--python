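"""Seeded scenario generator composing the forward models into test datasets.

Three named scenarios emulate the study conditions:

``fig2_titration``
    nMS titration at 10 uM protomer over a 0-100 uM total-ATP grid with
    Kd(full) = 10 uM, Kd(partial) = 100 uM, omega = 0.5 and a
    nucleated-cooperative assembly whose apparent dissociation constant is
    ~0.1 uM.  Writes one spectrum CSV per point plus the ground truth.
``fig1_apo_spectrum``
    a single ligand-free spectrum at 10 uM protomer.
``mp_dilution_series``
    mass-photometry particle lists at 0.05 / 0.1 / 0.2 uM protomer.

Every scenario is fully serializable and replays byte-identically under the
same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import AssemblyParameters, SolutionConditions, speciate
from .lattice import BindingParameters, default_topologies
from .mp import MPExperiment, simulate_particles
from .nms import SpectrumModel, simulate_titration

__all__ = ["ScenarioConfig", "make_scenario", "generate", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("fig2_titration", "fig1_apo_spectrum", "mp_dilution_series", "custom")

# study-condition defaults: 10 uM protomer titrated with 0-100 uM ATP,
# strong/weak site Kd of 10 / 100 uM, negative nearest-neighbor coupling
DEFAULT_TITRATION = dict(
    protomer_total=10e-6,
    atp_grid=(0.0, 2.5e-6, 5e-6, 10e-6, 20e-6, 40e-6, 100e-6),
    Kd_full=10e-6,
    Kd_partial=100e-6,
    omega=0.5,
    K_step=2e8,  # with sigma=0.1 the apo monomer/hexamer crossover sits near 0.1 uM
    sigma=0.1,
)
DEFAULT_MP = dict(protomer_grid=(0.05e-6, 0.1e-6, 0.2e-6), n_particles=5000, mass_sigma=6000.0)


@dataclass
class ScenarioConfig:
    name: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    spectrum_model: SpectrumModel = field(default_factory=lambda: SpectrumModel(
        noise_model="gaussian", noise_scale=0.002
    ))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "params": self.params,
            "spectrum_model": dataclasses.asdict(self.spectrum_model),
        }


def make_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if name in ("fig2_titration", "fig1_apo_spectrum", "custom"):
        params = dict(DEFAULT_TITRATION)
        if name == "fig1_apo_spectrum":
            params["atp_grid"] = (0.0,)
    else:
        params = {**DEFAULT_TITRATION, **DEFAULT_MP}
    model_overrides = {
        k: overrides.pop(k) for k in list(overrides) if hasattr(SpectrumModel, k) and k in SpectrumModel.__dataclass_fields__
    }
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")
    params.update(overrides)
    model_kwargs = {"noise_model": "gaussian", "noise_scale": 0.002, **model_overrides}
    model = SpectrumModel(**model_kwargs)
    return ScenarioConfig(name=name, seed=seed, params=params, spectrum_model=model)


def _binding(params: dict) -> BindingParameters:
    return BindingParameters.with_shared_partial(
        1.0 / params["Kd_full"], 1.0 / params["Kd_partial"], params["omega"]
    )


def _assembly(params: dict) -> AssemblyParameters:
    return AssemblyParameters.nucleated(params["K_step"], params["sigma"])


def _write_spectrum_csv(path: Path, mz: np.ndarray, intensity: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for x, y in zip(mz, intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate(scenario: ScenarioConfig, output_dir: str | Path) -> dict:
    """Write the scenario's data files plus a JSON manifest with hashes."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = scenario.params
    files: list[Path] = []
    truth: dict = {"scenario": scenario.to_dict()}

    if scenario.name in ("fig2_titration", "fig1_apo_spectrum", "custom"):
        topologies = default_topologies()
        result = simulate_titration(
            scenario.spectrum_model,
            _binding(params),
            _assembly(params),
            topologies,
            list(params["atp_grid"]),
            params["protomer_total"],
            seed=scenario.seed,
        )
        truth_rows = []
        for i, (spec, fr, table) in enumerate(
            zip(result.spectra, result.truth_fractions, result.tables)
        ):
            path = out / f"spectrum_{i:02d}.csv"
            _write_spectrum_csv(path, spec.mz, spec.intensity)
            files.append(path)
            for j in sorted(fr):
                for k, f in enumerate(fr[j]):
                    truth_rows.append(
                        dict(titration_point=i, L_tot=result.atp_grid[i], j=j, k=k,
                             fraction=float(f),
                             concentration=float(table.concentrations[j][k]))
                    )
            truth.setdefault("points", []).append(
                dict(titration_point=i, L_tot=result.atp_grid[i],
                     free_ligand=table.free_ligand, free_monomer=table.free_monomer)
            )
        truth["population_rows"] = truth_rows
    elif scenario.name == "mp_dilution_series":
        topologies = default_topologies()
        binding, assembly = _binding(params), _assembly(params)
        seeds = np.random.SeedSequence(scenario.seed).generate_state(
            len(params["protomer_grid"])
        ) % (2**31)
        truth["points"] = []
        for i, (p_tot, s) in enumerate(zip(params["protomer_grid"], seeds)):
            table = speciate(assembly, binding, topologies, SolutionConditions(p_tot, 0.0))
            exp = MPExperiment(
                protomer_total=p_tot,
                n_particles=params["n_particles"],
                mass_sigma=params["mass_sigma"],
                seed=int(s),
            )
            masses = simulate_particles(table, exp)
            path = out / f"particles_{i:02d}.csv"
            with open(path, "w") as fh:
                fh.write("mass\n")
                for m in masses:
                    fh.write(f"{m:.6f}\n")
            files.append(path)
            from .assembly import oligomer_particle_fractions

            truth["points"].append(
                dict(protomer_total=p_tot, seed=int(s),
                     particle_fractions=oligomer_particle_fractions(table).tolist())
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {scenario.name!r}")

    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    files.append(truth_path)
    manifest = {
        "scenario": scenario.to_dict(),
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
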