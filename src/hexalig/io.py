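"""File I/O: two-column CSV spectra, particle lists, population matrices, reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import PopulationMatrix
from .nms import Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_particles_csv",
    "write_population_csv",
    "read_population_csv",
    "write_fit_report",
]


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Two-column (m/z, intensity) CSV, with or without a header line."""
    df = pd.read_csv(path, header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):
        df = df.iloc[1:].reset_index(drop=True)
    arr = df.iloc[:, :2].to_numpy(dtype=float)
    return Spectrum(arr[:, 0], arr[:, 1], metadata={"path": str(path)})


def write_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for x, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{x:.10g},{y:.10g}\n")


def read_particles_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    col = df.columns[0]
    return df[col].to_numpy(dtype=float)


def write_population_csv(path: str | Path, matrices: list[PopulationMatrix]) -> None:
    pd.concat([m.to_frame() for m in matrices], ignore_index=True).to_csv(
        path, index=False
    )


def read_population_csv(path: str | Path) -> list[PopulationMatrix]:
    df = pd.read_csv(path)
    return [
        PopulationMatrix.from_frame(sub)
        for _, sub in df.groupby("titration_point", sort=True)
    ]


def write_fit_report(path: str | Path, fit, text_path: str | Path | None = None) -> None:
    """Fit report as JSON (machine) and optionally a short human-readable text."""
    payload = {
        "params": fit.params,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "nll": fit.nll,
        "success": fit.success,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "extra": {k: v for k, v in fit.extra.items() if _jsonable(v)},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    if text_path is not None:
        lines = ["binding/assembly fit", "--------------------"]
        for k, v in sorted(fit.params.items()):
            ci = fit.ci.get(k)
            span = f"  (95% CI {ci[0]:.3f} .. {ci[1]:.3f})" if ci else ""
            lines.append(f"{k:>18s} = {v: .4f}{span}")
        lines.append(f"{'NLL':>18s} = {fit.nll:.3f}   converged={fit.success}")
        Path(text_path).write_text("\n".join(lines) + "\n")


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
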