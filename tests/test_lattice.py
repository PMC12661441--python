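"""Lattice partition functions: exact limits, dual-route consistency, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexalig.lattice import (
    Adjacency,
    BindingParameters,
    ConfigurationError,
    LatticeSizeError,
    SiteClass,
    SiteLattice,
    TopologyError,
    build_topology,
    configuration_weight,
    mean_occupancy,
    occupancy_distribution,
    partition_function_enum,
    partition_function_tm,
)


@pytest.mark.parametrize(
    "order,mode,n_sites,n_full,adjacency",
    [
        (2, "open_chain", 3, 1, Adjacency.LINEAR),  # dimer: one enclosed site, two edges
        (6, "open_chain", 7, 5, Adjacency.LINEAR),  # hexamer washer: up to 7 ATP
        (1, "open_chain", 2, 0, Adjacency.LINEAR),  # monomer: no complete interface
        (6, "closed_ring", 6, 6, Adjacency.CYCLIC),
        (6, "uniform_linear", 6, 6, Adjacency.LINEAR),
    ],
)
def test_topology_modes(order, mode, n_sites, n_full, adjacency):
    lat = build_topology(order, mode)
    assert lat.n_sites == n_sites
    assert sum(s is SiteClass.FULL for s in lat.sites) == n_full
    assert lat.adjacency is adjacency
    if mode == "open_chain":
        assert lat.sites[0] is SiteClass.PARTIAL_A
        assert lat.sites[-1] is SiteClass.PARTIAL_B


def test_topology_rejects_bad_requests():
    with pytest.raises(TopologyError):
        build_topology(0, "open_chain")
    with pytest.raises(TopologyError):
        build_topology(2, "closed_ring")
    with pytest.raises(TopologyError):
        build_topology(3, "mystery_mode")


def test_configuration_weights_hand_expansion():
    lat = build_topology(3, "uniform_linear")
    p = BindingParameters.with_shared_partial(2e4, 0.0, 0.25)
    L = 1e-4
    assert configuration_weight(lat, p, [0, 0, 0], L) == 1.0
    assert configuration_weight(lat, p, [0, 1, 0], L) == pytest.approx(2e4 * L)
    assert configuration_weight(lat, p, [1, 1, 0], L) == pytest.approx((2e4 * L) ** 2 * 0.25)
    assert configuration_weight(lat, p, [1, 0, 1], L) == pytest.approx((2e4 * L) ** 2)
    with pytest.raises(ConfigurationError):
        configuration_weight(lat, p, [1, 0], L)


def test_two_site_partition_hand_enumeration():
    lat = SiteLattice(2, (SiteClass.FULL, SiteClass.PARTIAL_A))
    K1, K2, om, L = 3e4, 7e3, 0.4, 2e-5
    p = BindingParameters(K_full=K1, K_partial_a=K2, K_partial_b=0.0, omega=om)
    Z, c = partition_function_enum(lat, p, L)
    assert Z == pytest.approx(1 + (K1 + K2) * L + K1 * K2 * om * L**2, rel=1e-14)
    assert c[1] == pytest.approx((K1 + K2) * L, rel=1e-14)


def test_independent_sites_closed_form():
    # omega = 1 factorizes into the per-site product
    lat = build_topology(6, "open_chain")
    p = BindingParameters.with_shared_partial(1e5, 1e4, 1.0)
    L = 3e-5
    Ks = p.site_constants(lat)
    expected = np.prod(1 + Ks * L)
    Z, _ = partition_function_enum(lat, p, L)
    assert Z == pytest.approx(expected, rel=1e-12)
    assert partition_function_tm(lat, p, L) == pytest.approx(expected, rel=1e-12)


def test_zero_partial_collapses_to_uniform_chain():
    # K_partial = 0 reduces the open-chain j-mer to the (j-1)-site uniform model
    p_open = BindingParameters.with_shared_partial(1e5, 0.0, 0.5)
    L = 5e-5
    for j in (2, 4, 6):
        Z_open, _ = partition_function_enum(build_topology(j, "open_chain"), p_open, L)
        Z_uni, _ = partition_function_enum(
            build_topology(j - 1, "uniform_linear"), p_open, L
        )
        assert Z_open == pytest.approx(Z_uni, rel=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    j=st.integers(1, 6),
    mode=st.sampled_from(["open_chain", "uniform_linear", "closed_ring"]),
    logK=st.floats(2, 8),
    logKp=st.floats(1, 7),
    log_om=st.floats(-2, 2),
    logL=st.floats(-8, -3),
)
def test_enumeration_matches_transfer_matrix(j, mode, logK, logKp, log_om, logL):
    if mode == "closed_ring" and j < 3:
        j = 3
    lat = build_topology(j, mode)
    p = BindingParameters.with_shared_partial(10**logK, 10**logKp, 10**log_om)
    Z_enum, _ = partition_function_enum(lat, p, 10**logL)
    Z_tm = partition_function_tm(lat, p, 10**logL)
    assert Z_tm == pytest.approx(Z_enum, rel=1e-10)


def test_cyclic_differs_from_linear_by_wraparound():
    p = BindingParameters.with_shared_partial(1e5, 0.0, 0.3)
    L = 1e-4
    ring = build_topology(6, "closed_ring")
    chain = build_topology(6, "uniform_linear")
    Z_ring = partition_function_tm(ring, p, L)
    Z_chain = partition_function_tm(chain, p, L)
    assert Z_ring != pytest.approx(Z_chain, rel=1e-6)
    # with omega = 1 the wrap-around coupling carries no weight
    p1 = BindingParameters.with_shared_partial(1e5, 0.0, 1.0)
    assert partition_function_tm(ring, p1, L) == pytest.approx(
        partition_function_tm(chain, p1, L), rel=1e-12
    )


def test_occupancy_distribution_properties(binding):
    lat = build_topology(6, "open_chain")
    d0 = occupancy_distribution(lat, binding, 0.0)
    assert d0.probs[0] == 1.0
    for L in (1e-6, 1e-5, 1e-4):
        d = occupancy_distribution(lat, binding, L)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (d.probs >= 0).all()
    with pytest.raises(ValueError):
        occupancy_distribution(lat, binding, -1e-6)


def test_binomial_limit_independent_intact_sites():
    # omega = 1, dead edges: j-1 independent FULL sites -> binomial occupancy
    from scipy.stats import binom

    j, K, L = 5, 2e5, 1.3e-5
    lat = build_topology(j, "open_chain")
    p = BindingParameters.with_shared_partial(K, 0.0, 1.0)
    d = occupancy_distribution(lat, p, L)
    q = K * L / (1 + K * L)
    expected = binom.pmf(np.arange(j), j - 1, q)
    np.testing.assert_allclose(d.probs[:j], expected, rtol=1e-10)
    assert d.probs[j:] == pytest.approx(0.0, abs=1e-15)


def test_mean_occupancy_is_log_derivative(binding):
    # thermodynamic linkage: <k> = d ln Z / d ln L
    lat = build_topology(6, "open_chain")
    for L in (1e-6, 1e-5, 5e-5):
        h = 1e-6
        lnZ = lambda x: np.log(partition_function_enum(lat, binding, x)[0])
        deriv = (lnZ(L * (1 + h)) - lnZ(L * (1 - h))) / (2 * h)
        assert mean_occupancy(lat, binding, L) == pytest.approx(deriv, rel=1e-6)


def test_mean_occupancy_limits_and_monotonicity(binding):
    lat = build_topology(6, "open_chain")
    assert mean_occupancy(lat, binding, 0.0) == 0.0
    assert mean_occupancy(lat, binding, 1e3) == pytest.approx(lat.n_sites, rel=1e-4)
    grid = np.logspace(-8, -2, 25)
    means = [mean_occupancy(lat, binding, L) for L in grid]
    assert np.all(np.diff(means) > 0)


def test_linear_lattice_reversal_symmetry(binding):
    lat = build_topology(6, "open_chain")
    L = 2.7e-5
    Z_fwd, _ = partition_function_enum(lat, binding, L)
    Z_rev, _ = partition_function_enum(lat.reversed(), binding, L)
    assert Z_rev == pytest.approx(Z_fwd, rel=1e-14)


def test_enumeration_size_guard():
    lat = SiteLattice(25, (SiteClass.FULL,) * 25)
    p = BindingParameters.with_shared_partial(1e5, 0.0, 1.0)
    with pytest.raises(LatticeSizeError, match="transfer"):
        partition_function_enum(lat, p, 1e-5)
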