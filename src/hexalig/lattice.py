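"""Partition functions and occupancy statistics for 1-D lattices of ligand sites.

Oligomers of the Rho termination factor are modeled as short one-dimensional
lattices of ATP-binding sites.  A site is either fully formed (enclosed at a
complete subunit-subunit interface) or partially formed (exposed at an edge of
the open washer).  Each occupied site contributes a statistical weight
``K_class * L`` (association constant times free-ligand concentration) and
every adjacent pair of occupied sites contributes one factor of the
nearest-neighbor coupling ``omega``; ``omega < 1`` is anti-cooperative.

The configuration sum is small (at most ``2**n_sites`` terms for n <= 24), so
the canonical evaluation is exact enumeration; an independent transfer-matrix
evaluation is provided as a cross-check and for cyclic (closed-ring)
topologies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np

__all__ = [
    "SiteClass",
    "Adjacency",
    "SiteLattice",
    "BindingParameters",
    "OccupancyDistribution",
    "TopologyError",
    "ConfigurationError",
    "LatticeSizeError",
    "build_topology",
    "default_topologies",
    "configuration_weight",
    "partition_coefficients",
    "partition_function_enum",
    "partition_function_tm",
    "occupancy_distribution",
    "mean_occupancy",
]

ENUMERATION_GUARD = 24


class TopologyError(ValueError):
    """Invalid lattice topology request."""


class ConfigurationError(ValueError):
    """Occupancy vector incompatible with the lattice."""


class LatticeSizeError(ValueError):
    """Lattice too large for exact enumeration."""


class SiteClass(str, Enum):
    FULL = "full"
    PARTIAL_A = "partial_a"  # edge subunit contributing ~20% of the ligand surface
    PARTIAL_B = "partial_b"  # edge subunit contributing ~80% of the ligand surface


class Adjacency(str, Enum):
    LINEAR = "linear"
    CYCLIC = "cyclic"


@dataclass(frozen=True)
class SiteLattice:
    """Ordered sites of one oligomer with linear or cyclic adjacency."""

    oligomer_order: int
    sites: tuple[SiteClass, ...]
    adjacency: Adjacency = Adjacency.LINEAR

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        n = self.n_sites
        if n < 2:
            if self.adjacency is Adjacency.CYCLIC:
                raise TopologyError("cyclic adjacency needs at least 3 sites")
            return ()
        pairs = [(i, i + 1) for i in range(n - 1)]
        if self.adjacency is Adjacency.CYCLIC:
            pairs.append((n - 1, 0))
        return tuple(pairs)

    def reversed(self) -> "SiteLattice":
        return SiteLattice(self.oligomer_order, tuple(reversed(self.sites)), self.adjacency)


@dataclass
class BindingParameters:
    """Intrinsic association constants (M^-1) per site class and the coupling omega.

    ``omega`` multiplies the weight of every adjacent pair of occupied sites;
    ``omega = 1`` is independent binding, ``omega < 1`` negative coupling.
    """

    K_full: float
    K_partial_a: float
    K_partial_b: float
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("K_full", "K_partial_a", "K_partial_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")

    @classmethod
    def with_shared_partial(
        cls, K_full: float, K_partial: float, omega: float = 1.0
    ) -> "BindingParameters":
        """The default parameterization: both edge classes share one constant."""
        return cls(K_full, K_partial, K_partial, omega)

    def site_constant(self, site: SiteClass) -> float:
        if site is SiteClass.FULL:
            return self.K_full
        if site is SiteClass.PARTIAL_A:
            return self.K_partial_a
        return self.K_partial_b

    def site_constants(self, lattice: SiteLattice) -> np.ndarray:
        return np.array([self.site_constant(s) for s in lattice.sites], dtype=float)


@dataclass
class OccupancyDistribution:
    """P(k ligands bound) at one free-ligand concentration."""

    free_ligand: float
    probs: np.ndarray
    partition_value: float

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)


def build_topology(
    oligomer_order: int, mode: str, n_override: int | None = None
) -> SiteLattice:
    """Construct the site lattice of a j-mer.

    Modes
    -----
    ``open_chain``
        j + 1 sites: PARTIAL_A, FULL x (j - 1), PARTIAL_B.  This is the open
        washer: j - 1 complete inter-subunit sites flanked by the two exposed
        edge sites (a monomer has two partial sites and no complete one).
    ``uniform_linear``
        n identical FULL sites on a line (n = ``n_override`` or j); the
        six-site model used for hexamer fitting is ``uniform_linear`` with
        n = 6.
    ``closed_ring``
        j FULL sites with cyclic adjacency.
    """
    if oligomer_order < 1:
        raise TopologyError(f"oligomer_order must be >= 1, got {oligomer_order}")
    if mode == "open_chain":
        sites = (
            (SiteClass.PARTIAL_A,)
            + (SiteClass.FULL,) * (oligomer_order - 1)
            + (SiteClass.PARTIAL_B,)
        )
        return SiteLattice(oligomer_order, sites, Adjacency.LINEAR)
    if mode == "uniform_linear":
        n = n_override if n_override is not None else oligomer_order
        if n < 1:
            raise TopologyError("uniform_linear needs at least one site")
        return SiteLattice(oligomer_order, (SiteClass.FULL,) * n, Adjacency.LINEAR)
    if mode == "closed_ring":
        if oligomer_order < 3:
            raise TopologyError("closed_ring needs oligomer_order >= 3")
        return SiteLattice(
            oligomer_order, (SiteClass.FULL,) * oligomer_order, Adjacency.CYCLIC
        )
    raise TopologyError(f"unknown topology mode {mode!r}")


def default_topologies(max_order: int = 6, mode: str = "open_chain") -> dict[int, SiteLattice]:
    """Per-oligomer lattices for monomer..max_order, default the open-chain family."""
    return {j: build_topology(j, mode) for j in range(1, max_order + 1)}


def configuration_weight(
    lattice: SiteLattice,
    params: BindingParameters,
    occupancy,
    free_ligand: float,
) -> float:
    """Boltzmann weight of one occupancy configuration (all-empty = 1)."""
    occ = np.asarray(occupancy, dtype=int)
    if occ.shape != (lattice.n_sites,):
        raise ConfigurationError(
            f"occupancy length {occ.size} != site count {lattice.n_sites}"
        )
    if not np.isin(occ, (0, 1)).all():
        raise ConfigurationError("occupancy must be binary")
    w = 1.0
    for i, s in enumerate(occ):
        if s:
            w *= params.site_constant(lattice.sites[i]) * free_ligand
    for i, jdx in lattice.edges:
        if occ[i] and occ[jdx]:
            w *= params.omega
    return w


@lru_cache(maxsize=64)
def _config_tables(lattice: SiteLattice):
    """All 2^n occupancy configurations with their bound counts and adjacent pairs."""
    n = lattice.n_sites
    if n > ENUMERATION_GUARD:
        raise LatticeSizeError(
            f"{n} sites exceeds the enumeration guard ({ENUMERATION_GUARD}); "
            "use the transfer matrix (partition_function_tm)"
        )
    occ = np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.int8)
    k = occ.sum(axis=1)
    edges = lattice.edges
    if edges:
        e = np.array(edges)
        n_adj = (occ[:, e[:, 0]] & occ[:, e[:, 1]]).sum(axis=1)
    else:
        n_adj = np.zeros(len(occ), dtype=np.int64)
    return occ, k.astype(np.int64), n_adj.astype(np.int64)


def partition_coefficients(lattice: SiteLattice, params: BindingParameters) -> np.ndarray:
    """Ligand-independent coefficients a_k with Z(L) = sum_k a_k L^k.

    a_k collects the site constants and coupling factors of every
    configuration with exactly k occupied sites, so the k-bound concentration
    term of a species is proportional to a_k L^k.
    """
    occ, k, n_adj = _config_tables(lattice)
    site_K = params.site_constants(lattice)
    w = np.where(occ.astype(bool), site_K[None, :], 1.0).prod(axis=1)
    w = w * params.omega ** n_adj
    return np.bincount(k, weights=w, minlength=lattice.n_sites + 1)


def partition_function_enum(
    lattice: SiteLattice, params: BindingParameters, free_ligand: float
) -> tuple[float, np.ndarray]:
    """Exact configuration sum; returns (Z, c_k) with Z = sum_k c_k."""
    a = partition_coefficients(lattice, params)
    c = a * np.power(float(free_ligand), np.arange(a.size))
    return float(c.sum()), c


def partition_function_tm(
    lattice: SiteLattice, params: BindingParameters, free_ligand: float
) -> float:
    """Transfer-matrix evaluation of the same partition function.

    Independent of the enumeration path: the lattice is swept site by site
    with 2x2 transfer matrices; cyclic adjacency uses the trace form.
    """
    x = params.site_constants(lattice) * free_ligand
    om = params.omega
    n = lattice.n_sites
    if lattice.adjacency is Adjacency.LINEAR:
        v0, v1 = 1.0, x[0]
        for i in range(1, n):
            v0, v1 = v0 + v1, x[i] * (v0 + om * v1)
        return v0 + v1
    if n < 3:
        raise TopologyError("cyclic adjacency needs at least 3 sites")
    # M_i[s_prev, s_i] = x_i^{s_i} * omega^{s_prev * s_i}
    M = np.eye(2)
    for i in range(n):
        M = M @ np.array([[1.0, x[i]], [1.0, x[i] * om]])
    return float(np.trace(M))


def occupancy_distribution(
    lattice: SiteLattice, params: BindingParameters, free_ligand: float
) -> OccupancyDistribution:
    """Probability of k = 0..n bound ligands at a free-ligand concentration."""
    if free_ligand < 0:
        raise ValueError(f"free_ligand must be >= 0, got {free_ligand}")
    Z, c = partition_function_enum(lattice, params, free_ligand)
    return OccupancyDistribution(free_ligand=free_ligand, probs=c / Z, partition_value=Z)


def mean_occupancy(
    lattice: SiteLattice, params: BindingParameters, free_ligand: float
) -> float:
    """Expected bound-ligand count, sum_k k P(k) = d ln Z / d ln L."""
    return occupancy_distribution(lattice, params, free_ligand).mean
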