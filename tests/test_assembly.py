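"""Coupled assembly/binding speciation: mass balance, linkage, apparent Kd."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hexalig.assembly import (
    AssemblyParameters,
    SolutionConditions,
    apparent_kd,
    oligomer_particle_fractions,
    speciate,
)
from hexalig.lattice import BindingParameters, default_topologies


def test_no_assembly_no_ligand_gives_apo_monomer(topologies, binding):
    params = AssemblyParameters({j: 0.0 for j in range(2, 7)})
    table = speciate(params, binding, topologies, SolutionConditions(1e-5, 0.0))
    assert table.concentrations[1][0] == pytest.approx(1e-5, rel=1e-12)
    for j in range(2, 7):
        assert table.concentrations[j].sum() == 0.0
    assert table.free_ligand == 0.0


def test_apo_distribution_matches_closed_form(topologies, binding, assembly):
    # at L_tot = 0 the linkage vanishes: independent oracle solves
    # sum_j j beta_j m^j = P_tot directly
    p_tot = 3e-7
    table = speciate(assembly, binding, topologies, SolutionConditions(p_tot, 0.0))
    betas = assembly.betas
    m_oracle = brentq(
        lambda m: sum(j * betas[j] * m**j for j in range(1, 7)) - p_tot,
        0.0,
        p_tot,
        xtol=1e-30,
        rtol=1e-15,
    )
    assert table.free_monomer == pytest.approx(m_oracle, rel=1e-10)
    for j in range(1, 7):
        assert table.concentrations[j].sum() == pytest.approx(
            betas[j] * m_oracle**j, rel=1e-9
        )


def test_mass_balance_residuals_random_sweep(topologies, rng):
    # substituting the returned (m, l) must reproduce both totals
    for _ in range(25):
        binding = BindingParameters.with_shared_partial(
            10 ** rng.uniform(3, 7), 10 ** rng.uniform(2, 6), 10 ** rng.uniform(-1.5, 1.5)
        )
        assembly = AssemblyParameters.nucleated(
            10 ** rng.uniform(5, 9), 10 ** rng.uniform(-2, 1)
        )
        cond = SolutionConditions(
            10 ** rng.uniform(-8, -4), 10 ** rng.uniform(-7, -3)
        )
        table = speciate(assembly, binding, topologies, cond)
        rp, rl = table.residuals()
        assert abs(rp) <= 1e-9
        assert abs(rl) <= 1e-9
        for c in table.concentrations.values():
            assert (c >= 0).all()


def test_particle_fractions_normalization_and_limits(topologies, binding):
    monomer_only = AssemblyParameters({j: 0.0 for j in range(2, 7)})
    t1 = speciate(monomer_only, binding, topologies, SolutionConditions(1e-6, 0.0))
    f1 = oligomer_particle_fractions(t1)
    assert f1[0] == pytest.approx(1.0)

    strong_hex = AssemblyParameters({6: 1e60})
    t6 = speciate(strong_hex, binding, topologies, SolutionConditions(1e-5, 0.0))
    f6 = oligomer_particle_fractions(t6)
    assert f6.sum() == pytest.approx(1.0, abs=1e-12)
    assert f6[5] > 0.999

    empty = speciate(monomer_only, binding, topologies, SolutionConditions(0.0, 0.0))
    with pytest.raises(ValueError, match="undefined|zero"):
        oligomer_particle_fractions(empty)


def test_apparent_kd_matches_analytic_crossover(topologies, apo_binding):
    # nucleated ladder: crossover where f6 = f1 has the closed form
    # m* = (sigma K^5)^(-1/5), P* = sum_j j beta_j m*^j
    K, sig = 2e8, 0.1
    assembly = AssemblyParameters.nucleated(K, sig)
    m_star = (sig * K**5) ** (-1 / 5)
    p_star = m_star + sum(j * sig * K ** (j - 1) * m_star**j for j in range(2, 7))
    kd = apparent_kd(assembly, apo_binding, topologies)
    assert kd == pytest.approx(p_star, rel=1e-6)


def test_apparent_kd_monotone_in_assembly_strength(topologies, apo_binding):
    kd_weak = apparent_kd(AssemblyParameters.nucleated(1e8, 0.1), apo_binding, topologies)
    kd_strong = apparent_kd(AssemblyParameters.nucleated(4e8, 0.1), apo_binding, topologies)
    assert kd_strong < kd_weak


def test_saturating_ligand_lowers_apparent_kd(topologies, assembly):
    # hexamer holds the most intact sites, so linkage to a full-site-selective
    # ligand pulls the crossover to lower protomer concentrations
    binding = BindingParameters.with_shared_partial(1e6, 1e2, 1.0)
    kd_apo = apparent_kd(assembly, binding, topologies, l_total=0.0)
    kd_atp = apparent_kd(assembly, binding, topologies, l_total=1e-4)
    assert kd_atp < kd_apo


def test_apparent_kd_range_error(topologies, apo_binding):
    no_hex = AssemblyParameters({6: 0.0})
    with pytest.raises(ValueError, match="hexamer"):
        apparent_kd(no_hex, apo_binding, topologies)
    weak = AssemblyParameters.nucleated(1e4, 1.0)
    with pytest.raises(ValueError, match="crossover"):
        apparent_kd(weak, apo_binding, topologies, p_range=(1e-12, 1e-10))


def test_ligand_linkage_never_lowers_hexamer_fraction(topologies, assembly):
    # raising total ATP at fixed protomer can only stabilize species with
    # more intact sites when K_full > K_partial
    binding = BindingParameters.with_shared_partial(1e5, 1e3, 1.0)
    for p_tot in (5e-8, 1e-7, 1e-6):
        fracs = []
        for l_tot in (0.0, 1e-6, 1e-5, 1e-4):
            t = speciate(assembly, binding, topologies, SolutionConditions(p_tot, l_tot))
            fracs.append(oligomer_particle_fractions(t)[5])
        assert np.all(np.diff(fracs) >= -1e-12)


def test_speciation_continuity_under_perturbation(topologies, binding, assembly):
    cond = SolutionConditions(1e-6, 5e-6)
    base = speciate(assembly, binding, topologies, cond)
    bumped = AssemblyParameters({j: assembly.betas[j] * 1.0001 for j in range(2, 7)})
    pert = speciate(bumped, binding, topologies, cond)
    for j in range(1, 7):
        num = np.abs(pert.concentrations[j] - base.concentrations[j]).max()
        scale = base.concentrations[j].max() or 1.0
        assert num / scale < 0.01
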