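"""Monomer-hexamer assembly equilibria thermodynamically linked to ATP binding.

Oligomers j = 1..6 form with overall association constants beta_j
(c_j = beta_j * m^j at free monomer m, beta_1 = 1), and every oligomer binds
ligand according to its site lattice, so the concentration of the j-mer with
k ligands bound is

    c(j, k) = beta_j * m^j * a_k^{(j)} * l^k

with a_k^{(j)} the lattice coefficients and l the free-ligand concentration.
``speciate`` solves the two coupled mass balances (total protomer, total
ligand) for (m, l) by nested scalar bracketing: both balances are strictly
monotone in their own variable, so the nested solve is globally convergent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .lattice import BindingParameters, SiteLattice, partition_coefficients

__all__ = [
    "AssemblyParameters",
    "SolutionConditions",
    "SpeciesTable",
    "SpeciationError",
    "speciate",
    "oligomer_particle_fractions",
    "apparent_kd",
]

MAX_ORDER = 6


class SpeciationError(RuntimeError):
    """Mass-balance solve failed to converge."""


@dataclass
class AssemblyParameters:
    """Overall association constants beta_j (M^-(j-1)) for j = 1..6, beta_1 = 1."""

    betas: dict[int, float]

    def __post_init__(self) -> None:
        betas = {1: 1.0}
        for j in range(2, MAX_ORDER + 1):
            b = float(self.betas.get(j, 0.0))
            if b < 0:
                raise ValueError(f"beta_{j} must be >= 0")
            betas[j] = b
        self.betas = betas

    @classmethod
    def isodesmic(cls, K_step: float) -> "AssemblyParameters":
        """Equal stepwise constant for every addition: beta_j = K_step^(j-1)."""
        return cls({j: K_step ** (j - 1) for j in range(2, MAX_ORDER + 1)})

    @classmethod
    def nucleated(cls, K_step: float, sigma: float) -> "AssemblyParameters":
        """Nucleated-cooperative ladder: the first step is penalized by sigma.

        beta_j = sigma * K_step^(j-1) for j >= 2; sigma < 1 disfavors the
        nucleating dimer relative to elongation, producing monomer/hexamer
        dominant (U-shaped) distributions near the crossover concentration.
        """
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        return cls({j: sigma * K_step ** (j - 1) for j in range(2, MAX_ORDER + 1)})

    def beta_array(self) -> np.ndarray:
        return np.array([self.betas[j] for j in range(1, MAX_ORDER + 1)])


@dataclass
class SolutionConditions:
    protomer_total: float  # M
    ligand_total: float = 0.0  # M
    temperature: str | None = None  # metadata only

    def __post_init__(self) -> None:
        if self.protomer_total < 0 or self.ligand_total < 0:
            raise ValueError("totals must be >= 0")


@dataclass
class SpeciesTable:
    """Equilibrium concentrations c(j, k) plus the free monomer and ligand."""

    concentrations: dict[int, np.ndarray]  # j -> array over k = 0..n_sites(j)
    free_monomer: float
    free_ligand: float
    protomer_total: float
    ligand_total: float

    def oligomer_totals(self) -> dict[int, float]:
        return {j: float(c.sum()) for j, c in self.concentrations.items()}

    def bound_ligand(self) -> float:
        return float(
            sum(np.arange(c.size) @ c for c in self.concentrations.values())
        )

    def protomer_in_species(self) -> float:
        return float(sum(j * c.sum() for j, c in self.concentrations.items()))

    def residuals(self) -> tuple[float, float]:
        """Relative mass-balance residuals (protomer, ligand)."""
        rp = self.protomer_in_species() - self.protomer_total
        rl = self.free_ligand + self.bound_ligand() - self.ligand_total
        sp = self.protomer_total or 1.0
        sl = self.ligand_total or 1.0
        return rp / sp, rl / sl

    def within_oligomer_fractions(self) -> dict[int, np.ndarray]:
        out = {}
        for j, c in self.concentrations.items():
            tot = c.sum()
            out[j] = c / tot if tot > 0 else np.full_like(c, np.nan)
        return out


def _lattice_coeffs(
    binding: BindingParameters, topologies: dict[int, SiteLattice]
) -> dict[int, np.ndarray]:
    return {j: partition_coefficients(lat, binding) for j, lat in topologies.items()}


def _free_ligand_given_monomer(
    m: float,
    l_tot: float,
    betas: dict[int, float],
    coeffs: dict[int, np.ndarray],
) -> float:
    """Solve l + sum_j beta_j m^j * sum_k k a_k l^k = l_tot (monotone in l)."""
    if l_tot == 0.0:
        return 0.0

    def g(l: float) -> float:
        bound = 0.0
        for j, a in coeffs.items():
            k = np.arange(a.size)
            bound += betas[j] * m ** j * float((k * a) @ np.power(l, k))
        return l + bound - l_tot

    if g(l_tot) <= 0:  # no binding: free ligand is the total
        return l_tot
    return brentq(g, 0.0, l_tot, xtol=1e-30, rtol=8.9e-16, maxiter=200)


def speciate(
    assembly: AssemblyParameters,
    binding: BindingParameters,
    topologies: dict[int, SiteLattice],
    conditions: SolutionConditions,
) -> SpeciesTable:
    """Solve the coupled assembly + binding mass balances for all species.

    Outer bracketed solve on the free monomer m in [0, P_tot] with an inner
    solve for the free ligand l at each trial m.
    """
    p_tot, l_tot = conditions.protomer_total, conditions.ligand_total
    betas = assembly.betas
    coeffs = _lattice_coeffs(binding, topologies)
    orders = sorted(topologies)

    if p_tot == 0.0:
        conc = {j: np.zeros(coeffs[j].size) for j in orders}
        return SpeciesTable(conc, 0.0, l_tot, p_tot, l_tot)

    def protomer_residual(m: float) -> float:
        l = _free_ligand_given_monomer(m, l_tot, betas, coeffs)
        tot = 0.0
        for j in orders:
            a = coeffs[j]
            Z = float(a @ np.power(l, np.arange(a.size)))
            tot += j * betas[j] * m ** j * Z
        return tot - p_tot

    try:
        m = brentq(
            protomer_residual, 0.0, p_tot, xtol=1e-300, rtol=8.9e-16, maxiter=300
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics path
        raise SpeciationError(
            f"monomer solve failed for P_tot={p_tot:g}, L_tot={l_tot:g}: {exc}"
        ) from exc
    l = _free_ligand_given_monomer(m, l_tot, betas, coeffs)

    conc = {}
    for j in orders:
        a = coeffs[j]
        conc[j] = betas[j] * m ** j * a * np.power(l, np.arange(a.size))
    table = SpeciesTable(conc, m, l, p_tot, l_tot)
    rp, rl = table.residuals()
    if abs(rp) > 1e-8 or abs(rl) > 1e-8:  # pragma: no cover - solver guard
        raise SpeciationError(
            f"mass balance residuals too large: protomer {rp:.2e}, ligand {rl:.2e}"
        )
    return table


def oligomer_particle_fractions(table: SpeciesTable) -> np.ndarray:
    """Fraction of particles (not protomers) in each oligomer order 1..6."""
    totals = np.array([table.concentrations.get(j, np.zeros(1)).sum() for j in range(1, MAX_ORDER + 1)])
    s = totals.sum()
    if s <= 0:
        raise ValueError("all species concentrations are zero; fractions undefined")
    return totals / s


def apparent_kd(
    assembly: AssemblyParameters,
    binding: BindingParameters,
    topologies: dict[int, SiteLattice],
    l_total: float = 0.0,
    p_range: tuple[float, float] = (1e-12, 1e-3),
    n_scan: int = 61,
) -> float:
    """Protomer concentration at which monomer and hexamer particle counts cross.

    This is the operational apparent dissociation constant of the multi-step
    assembly: below it monomers dominate the particle count, above it
    hexamers do.  Found by bisection on log10 P_tot.
    """
    if assembly.betas[MAX_ORDER] <= 0:
        raise ValueError("assembly does not support hexamer formation")

    def diff(log_p: float) -> float:
        table = speciate(
            assembly, binding, topologies, SolutionConditions(10.0 ** log_p, l_total)
        )
        f = oligomer_particle_fractions(table)
        return f[MAX_ORDER - 1] - f[0]

    lo, hi = np.log10(p_range[0]), np.log10(p_range[1])
    grid = np.linspace(lo, hi, n_scan)
    vals = [diff(g) for g in grid]
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(10.0 ** grid[i])
        if vals[i] < 0 <= vals[i + 1]:
            root = brentq(diff, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
            return float(10.0 ** root)
    raise ValueError(
        f"no monomer/hexamer crossover in P_tot range [{p_range[0]:g}, {p_range[1]:g}] M"
    )
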