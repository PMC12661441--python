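"""Likelihood machinery: consistency, recovery, bootstrap, identifiability."""

import warnings

import numpy as np
import pytest

from hexalig.fitting import (
    IdentifiabilityError,
    TitrationPoint,
    bootstrap_ci,
    fit_assembly,
    fit_binding,
    negative_log_likelihood,
    simulate_multinomial_rows,
)
from hexalig.lattice import BindingParameters, build_topology


@pytest.fixture(scope="module")
def six_site():
    return {6: build_topology(6, "uniform_linear")}


@pytest.fixture(scope="module")
def truth():
    return BindingParameters.with_shared_partial(1e5, 0.0, 0.5)


@pytest.fixture(scope="module")
def synthetic_data(six_site, truth):
    rng = np.random.default_rng(404)
    grid = [(l * 1e-6, 10e-6) for l in np.linspace(0, 100, 11)]
    return simulate_multinomial_rows(truth, six_site, grid, 5000, rng, ligand_mode="hexamer")


def test_nll_order_invariance(six_site, truth, synthetic_data):
    nll = negative_log_likelihood(truth, synthetic_data, six_site)
    nll_perm = negative_log_likelihood(truth, synthetic_data[::-1], six_site)
    assert nll_perm == pytest.approx(nll, rel=1e-12)


def test_nll_prefers_truth_over_perturbation(six_site, truth, synthetic_data):
    worse = BindingParameters.with_shared_partial(1e6, 0.0, 0.5)
    assert negative_log_likelihood(truth, synthetic_data, six_site) < (
        negative_log_likelihood(worse, synthetic_data, six_site)
    )


def test_nll_floors_zero_probability_with_warning(six_site, truth):
    # an observed k = 6 count is impossible at L = 0 -> floored, warned, finite
    rows = {6: np.array([0.9, 0, 0, 0, 0, 0, 0.1])}
    data = [TitrationPoint(0.0, 10e-6, rows)]
    with pytest.warns(UserWarning, match="floored"):
        nll = negative_log_likelihood(truth, data, six_site)
    assert np.isfinite(nll)


def test_fit_requires_three_points(six_site, synthetic_data):
    with pytest.raises(IdentifiabilityError):
        fit_binding(synthetic_data[:2], six_site)
    empty = [TitrationPoint(p.l_tot, p.p_tot, {}) for p in synthetic_data]
    with pytest.raises(IdentifiabilityError):
        fit_binding(empty, six_site)


def test_single_replicate_recovery(six_site, synthetic_data):
    fit = fit_binding(synthetic_data, six_site, seed=1, check_identifiability=False)
    assert abs(fit.params["log10_K_full"] - 5.0) < 0.1
    assert 10 ** fit.params["log10_omega"] < 1.0


def test_fit_deterministic_given_seed(six_site, synthetic_data):
    a = fit_binding(synthetic_data, six_site, seed=5, check_identifiability=False)
    b = fit_binding(synthetic_data, six_site, seed=5, check_identifiability=False)
    assert a.params == b.params


def test_nested_model_consistency(six_site):
    # data generated at omega = 1: freeing omega should barely improve the fit
    gen = BindingParameters.with_shared_partial(1e5, 0.0, 1.0)
    rng = np.random.default_rng(77)
    grid = [(l * 1e-6, 10e-6) for l in np.linspace(0, 100, 11)]
    data = simulate_multinomial_rows(gen, six_site, grid, 5000, rng, ligand_mode="hexamer")
    free = fit_binding(data, six_site, seed=2, check_identifiability=False)
    fixed = fit_binding(
        data, six_site, seed=2, fixed={"log10_omega": 0.0}, check_identifiability=False
    )
    lr = 2 * (fixed.nll - free.nll)
    assert 0 <= lr < 6.0  # ~chi2_1 scale, no significant improvement


def test_omega_unidentified_at_low_occupancy(six_site, truth):
    # L_tot << Kd: never more than ~1 ligand bound, coupling invisible
    rng = np.random.default_rng(55)
    grid = [(l, 10e-6) for l in (0.0, 2e-8, 5e-8, 1e-7)]
    data = simulate_multinomial_rows(truth, six_site, grid, 5000, rng, ligand_mode="hexamer")
    fit = fit_binding(data, six_site, seed=3)
    assert fit.extra["omega_identified"] is False


def test_omega_identified_at_informative_occupancy(six_site, synthetic_data):
    fit = fit_binding(synthetic_data, six_site, seed=3)
    assert fit.extra["omega_identified"] is True


def test_bootstrap_contracts(six_site, synthetic_data):
    fit = fit_binding(synthetic_data, six_site, seed=4, check_identifiability=False)
    assert bootstrap_ci(synthetic_data, six_site, fit, n_boot=0) == {}
    ci_a = bootstrap_ci(synthetic_data, six_site, fit, n_boot=10, seed=11)
    ci_b = bootstrap_ci(synthetic_data, six_site, fit, n_boot=10, seed=11)
    assert ci_a == ci_b
    lo, hi = ci_a["log10_K_full"]
    assert lo <= fit.params["log10_K_full"] + 0.05 and hi >= fit.params["log10_K_full"] - 0.05


def test_bootstrap_coverage(six_site, truth):
    # reduced-n coverage experiment: nominal 95% intervals cover truth >= 80%
    grid = [(l * 1e-6, 10e-6) for l in np.linspace(0, 100, 11)]
    covered = 0
    n_rep = 10
    for rep in range(n_rep):
        rng = np.random.default_rng(900 + rep)
        data = simulate_multinomial_rows(truth, six_site, grid, 5000, rng, ligand_mode="hexamer")
        fit = fit_binding(data, six_site, seed=rep, n_starts=4, check_identifiability=False)
        ci = bootstrap_ci(data, six_site, fit, n_boot=30, seed=rep)
        lo, hi = ci["log10_K_full"]
        covered += lo <= 5.0 <= hi
    assert covered >= 0.8 * n_rep


def test_fit_assembly_recovers_apparent_kd(topologies, apo_binding, assembly, rng):
    from hexalig.assembly import SolutionConditions, apparent_kd, oligomer_particle_fractions, speciate

    kd_true = apparent_kd(assembly, apo_binding, topologies)
    counts = {}
    for p_tot in (0.05e-6, 0.1e-6, 0.2e-6):
        table = speciate(assembly, apo_binding, topologies, SolutionConditions(p_tot, 0.0))
        f = oligomer_particle_fractions(table)
        counts[p_tot] = rng.multinomial(5000, f)
    fit = fit_assembly(counts, seed=0)
    assert kd_true / 2 < fit.extra["apparent_kd"] < kd_true * 2


def test_fit_assembly_edge_cases():
    mono = np.array([5000, 0, 0, 0, 0, 0])
    with pytest.raises(IdentifiabilityError):
        fit_assembly({1e-7: mono})
    with pytest.warns(UserWarning, match="flat"):
        fit = fit_assembly({1e-7: mono, 2e-7: mono}, seed=1, n_starts=2)
    # monomer-everywhere data drive the stepwise constant to its lower bound
    assert fit.params["log10_K_step"] == pytest.approx(4.0, abs=0.3)
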