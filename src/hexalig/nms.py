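"""Forward model of native electrospray mass spectra of Rho-ATP complexes.

Each (oligomer j, bound ATP k) species is placed on the m/z axis through a
narrow charge-state envelope centered at ``a * sqrt(M)`` (empirical
native-ESI scaling), with per-ATP sodium adduction (binomial), Gaussian peak
shapes, and optional noise.  Relative ion response across different oligomers
is deliberately decoupled from solution populations (cross-oligomer ion
counts are not a reliable population metric in native MS); within-oligomer
intensity ratios faithfully track the input abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom

from .assembly import (
    AssemblyParameters,
    SolutionConditions,
    SpeciesTable,
    speciate,
)
from .lattice import BindingParameters, SiteLattice

__all__ = [
    "SpectrumModel",
    "Spectrum",
    "TitrationResult",
    "species_mass",
    "charge_envelope",
    "peak_mz",
    "simulate_spectrum",
    "simulate_titration",
]

PROTOMER_MASS_DA = 47_198.40  # ProtParam average mass after N-Met processing
ATP_MASS_DA = 507.18  # average mass of ATP (free acid)
SODIUM_INCREMENT_DA = 22.99  # Na replacing H
PROTON_MASS_DA = 1.00728


@dataclass
class SpectrumModel:
    """Parameters of the spectral forward model (masses in Da, m/z grid in Th)."""

    protomer_mass: float = PROTOMER_MASS_DA
    ligand_mass: float = ATP_MASS_DA
    sodium_increment: float = SODIUM_INCREMENT_DA
    proton_mass: float = PROTON_MASS_DA
    charge_center_coefficient: float = 0.0778  # z_bar = a * sqrt(M)
    charge_width: float = 0.9  # sigma_z, charges
    peak_sigma_mz: float = 0.15  # Gaussian peak sigma on the m/z axis
    sodiation_prob: float = 0.15  # per bound ATP, probability of carrying one Na
    noise_model: str = "none"  # none | gaussian | poisson
    noise_scale: float = 0.0  # gaussian: sigma relative to max intensity; poisson: counts at max
    mass_offset: float = 0.0  # uniform noncovalent-adduct offset, Da
    mz_min: float = 2200.0
    mz_max: float = 7900.0
    mz_step: float = 0.05
    envelope_halfwidth_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if min(self.protomer_mass, self.ligand_mass, self.sodium_increment) <= 0:
            raise ValueError("masses must be > 0")
        if not 0.0 <= self.sodiation_prob <= 1.0:
            raise ValueError("sodiation_prob must be in [0, 1]")
        if self.mz_step <= 0 or self.mz_max <= self.mz_min:
            raise ValueError("m/z grid must be strictly increasing")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def mz_grid(self) -> np.ndarray:
        n = int(np.floor((self.mz_max - self.mz_min) / self.mz_step)) + 1
        return self.mz_min + self.mz_step * np.arange(n)

    def sigma_at(self, mz: float) -> float:
        """Peak sigma in m/z; constant by default, hook for m/z-dependent widths."""
        return self.peak_sigma_mz


@dataclass
class Spectrum:
    """An (m/z, intensity) trace with generation metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be >= 0")


@dataclass
class TitrationResult:
    """Simulated titration: spectra plus per-point ground truth."""

    spectra: list[Spectrum]
    truth_fractions: list[dict[int, np.ndarray]]  # per point: j -> P(k) in solution
    tables: list[SpeciesTable]
    atp_grid: list[float]


def species_mass(model: SpectrumModel, j: int, k: int, n_na: int = 0) -> float:
    """Average mass of the j-mer with k ATP and n_na sodium adducts (Da)."""
    if j < 1 or k < 0 or n_na < 0:
        raise ValueError("require j >= 1, k >= 0, n_na >= 0")
    return j * model.protomer_mass + k * model.ligand_mass + n_na * model.sodium_increment


def charge_envelope(model: SpectrumModel, mass: float) -> tuple[np.ndarray, np.ndarray]:
    """Discretized Gaussian charge-state distribution, truncated to z >= 1."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    center = model.charge_center_coefficient * np.sqrt(mass)
    half = max(model.envelope_halfwidth_sigmas * model.charge_width, 0.5)
    z_lo = max(1, int(np.ceil(center - half)))
    z_hi = max(z_lo, int(np.floor(center + half)))
    z = np.arange(z_lo, z_hi + 1)
    if model.charge_width <= 0:
        z = np.array([max(1, round(center))])
        return z, np.array([1.0])
    w = np.exp(-0.5 * ((z - center) / model.charge_width) ** 2)
    return z, w / w.sum()


def peak_mz(model: SpectrumModel, mass: float, z: int) -> float:
    """Positive-mode m/z of a species of the given mass at charge z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * model.proton_mass) / z


def _sodiation_pmf(model: SpectrumModel, k: int) -> np.ndarray:
    """Binomial(n=k, p=sodiation_prob) over the sodium count 0..k."""
    if k == 0:
        return np.array([1.0])
    return binom.pmf(np.arange(k + 1), k, model.sodiation_prob)


def simulate_spectrum(
    model: SpectrumModel,
    species_abundances: dict[tuple[int, int], float],
    seed: int | None = None,
) -> Spectrum:
    """Render a spectrum from relative (j, k) abundances.

    Peak area of each (j, k, n_na, z) component is
    abundance * P(z | envelope) * P(n_na | binomial); the noiseless spectrum
    is deterministic and linear in the abundances.
    """
    mz = model.mz_grid()
    intensity = np.zeros_like(mz)
    any_peak = False
    for (j, k), ab in species_abundances.items():
        if ab < 0:
            raise ValueError("abundances must be >= 0")
        if ab == 0.0:
            continue
        base = species_mass(model, j, k) + model.mass_offset
        # charging scales with the surface area of the complex, which bound
        # nucleotide barely changes: envelope taken at the apo oligomer mass
        z_arr, pz = charge_envelope(model, species_mass(model, j, 0) + model.mass_offset)
        p_na = _sodiation_pmf(model, k)
        for z, pzi in zip(z_arr, pz):
            for n_na, pna in enumerate(p_na):
                center = peak_mz(model, base + n_na * model.sodium_increment, int(z))
                if not (mz[0] <= center <= mz[-1]):
                    continue
                sig = model.sigma_at(center)
                lo = np.searchsorted(mz, center - 6 * sig)
                hi = np.searchsorted(mz, center + 6 * sig)
                if hi <= lo:
                    continue
                seg = mz[lo:hi]
                area = ab * pzi * pna
                intensity[lo:hi] += (
                    area / (sig * np.sqrt(2 * np.pi))
                ) * np.exp(-0.5 * ((seg - center) / sig) ** 2)
                any_peak = True
    if species_abundances and not any_peak and any(
        v > 0 for v in species_abundances.values()
    ):
        warnings.warn("no peaks fall inside the m/z grid; spectrum is empty")

    if model.noise_model != "none" and model.noise_scale > 0:
        rng = np.random.default_rng(seed)
        if model.noise_model == "gaussian":
            scale = model.noise_scale * (intensity.max() if intensity.max() > 0 else 1.0)
            intensity = np.maximum(intensity + rng.normal(0.0, scale, intensity.size), 0.0)
        elif model.noise_model == "poisson":
            # noise_scale = expected counts at the maximum intensity
            top = intensity.max()
            if top > 0:
                lam = intensity / top * model.noise_scale
                intensity = rng.poisson(lam).astype(float) * top / model.noise_scale
    return Spectrum(mz, intensity, metadata={"seed": seed})


def titration_abundances(
    table: SpeciesTable, response_mode: str = "equalized",
    response_factors: dict[int, float] | None = None,
) -> dict[tuple[int, int], float]:
    """Map a species table to relative ion abundances per (j, k).

    ``equalized`` gives every oligomer the same total ion count (the
    cross-oligomer response of native MS is arbitrary); ``proportional``
    keeps solution concentrations; explicit per-j factors override both.
    """
    out: dict[tuple[int, int], float] = {}
    for j, conc in table.concentrations.items():
        tot = conc.sum()
        if tot <= 0:
            continue
        if response_factors is not None:
            scale = response_factors.get(j, 0.0) / tot
        elif response_mode == "equalized":
            scale = 1.0 / tot
        elif response_mode == "proportional":
            scale = 1.0 / table.protomer_total
        else:
            raise ValueError(f"unknown response mode {response_mode!r}")
        for k, c in enumerate(conc):
            if c > 0:
                out[(j, k)] = float(c * scale)
    return out


def simulate_titration(
    model: SpectrumModel,
    binding: BindingParameters,
    assembly: AssemblyParameters,
    topologies: dict[int, SiteLattice],
    atp_grid: list[float],
    protomer_total: float,
    seed: int | None = None,
    response_mode: str = "equalized",
) -> TitrationResult:
    """Simulate one spectrum per total-ATP point with stored ground truth."""
    seeds = (
        np.random.SeedSequence(seed).generate_state(len(atp_grid)) % (2**31)
        if seed is not None
        else [None] * len(atp_grid)
    )
    spectra, truths, tables = [], [], []
    for l_tot, s in zip(atp_grid, seeds):
        table = speciate(
            assembly, binding, topologies, SolutionConditions(protomer_total, l_tot)
        )
        ab = titration_abundances(table, response_mode=response_mode)
        spec = simulate_spectrum(model, ab, seed=None if s is None else int(s))
        spec.metadata.update({"l_tot": l_tot, "p_tot": protomer_total})
        spectra.append(spec)
        truths.append(table.within_oligomer_fractions())
        tables.append(table)
    return TitrationResult(spectra, truths, tables, list(atp_grid))
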