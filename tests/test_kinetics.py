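import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatterkin.kinetics import (
    DT_RATES,
    InstrumentResponse,
    RateSet,
    ReactionNetwork,
    Species,
    asymptotic_fractions,
    default_delay_grid,
    default_dt_network,
    equilibrium_ratio,
    solve_populations,
)

rates_strategy = st.builds(
    RateSet,
    **{sym: st.floats(min_value=1e8, max_value=5e13) for sym in
       ("k1", "k2", "km2", "k3", "k4", "k5", "k6", "k7")},
)


def test_default_network_topology():
    net = default_dt_network()
    assert len(net.species) == 6
    assert len(net.edges) == 8
    out_deg = {}
    for src, _, _ in net.edges:
        out_deg[src] = out_deg.get(src, 0) + 1
    assert out_deg["DT*"] == 3
    assert "FA-2" not in out_deg and "FB" not in out_deg


def test_edge_assignment_must_be_bijective():
    with pytest.raises(ValueError):
        default_dt_network({"FA-1->FA-2": "k5", "DT_hot->FB": "k5",
                            "biradical->FA-2": "k7"})


def test_network_invariants_enforced():
    with pytest.raises(ValueError, match="unique"):
        ReactionNetwork((Species("A", "excited"), Species("A")), (), initial="A")
    with pytest.raises(ValueError, match="unreachable"):
        ReactionNetwork((Species("A", "excited"), Species("B", "product")), (),
                        initial="A")
    with pytest.raises(ValueError, match="product"):
        ReactionNetwork(
            (Species("A", "excited"), Species("B", "product")),
            (("A", "B", "k1"), ("B", "A", "k2")), initial="A")


def test_single_exponential_decay():
    net = default_dt_network()
    k1 = 4.23e12
    tau_fs = 1.0 / (k1 * 1e-15)
    pops = solve_populations(net, RateSet(k1=k1), irf=None,
                             tgrid=np.array([0.0, tau_fs]))
    assert pops["DT*"][1] == pytest.approx(math.exp(-1.0), rel=1e-9)


def test_total_excited_state_decay_constant():
    """k1 + k3 + k4 from the reference rates gives 1/k ~ 100.6 fs."""
    net = default_dt_network()
    ktot = (DT_RATES.k1 + DT_RATES.k3 + DT_RATES.k4) * 1e-15  # per fs
    tau = 1.0 / ktot
    assert tau == pytest.approx(100.6, abs=0.05)
    pops = solve_populations(net, DT_RATES, None, np.array([tau]))
    assert pops["DT*"][0] == pytest.approx(math.exp(-1.0), rel=1e-9)


def test_fast_branching_fraction_into_biradical():
    net = default_dt_network()
    rates = RateSet(k1=4.23e12, k3=2.86e12, k4=2.85e12)
    pops = solve_populations(net, rates, None, np.array([5000.0]))
    expected = 4.23 / (4.23 + 2.86 + 2.85)
    assert pops["biradical"][0] == pytest.approx(expected, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rates=rates_strategy)
def test_population_conservation_and_nonnegativity(rates):
    net = default_dt_network()
    t = default_delay_grid(n_linear=15, n_log=15)
    pops = solve_populations(net, rates, InstrumentResponse(238.0, 0.0), t)
    total = pops.populations.sum(axis=1)
    late = t > 3 * 238.0
    assert np.all(np.abs(total[late] - 1.0) < 1e-6)
    assert np.all(pops.populations >= 0.0)


def test_irf_convolution_reduces_to_delta_response():
    net = default_dt_network()
    t = np.array([500.0, 2000.0, 50000.0])
    delta = solve_populations(net, DT_RATES, None, t).populations
    narrow = solve_populations(net, DT_RATES, InstrumentResponse(1e-3, 0.0), t).populations
    np.testing.assert_allclose(narrow, delta, atol=1e-9)


def test_analytic_solver_agrees_with_stiff_integrator():
    from scipy.integrate import solve_ivp

    net = default_dt_network()
    a = net.rate_matrix(DT_RATES)  # per fs
    p0 = np.zeros(6)
    p0[0] = 1.0
    t = np.geomspace(10.0, 3.0e6, 25)
    num = solve_ivp(lambda _, y: a @ y, (0.0, t[-1]), p0, t_eval=t,
                    method="LSODA", rtol=1e-10, atol=1e-14)
    ana = solve_populations(net, DT_RATES, None, t).populations
    np.testing.assert_allclose(ana, num.y.T, rtol=1e-6, atol=1e-9)


def test_equilibrium_ratio():
    assert equilibrium_ratio(RateSet(k2=1e12, km2=1e12)) == pytest.approx(1.0)
    assert equilibrium_ratio(DT_RATES) == pytest.approx(0.95 / 0.31, rel=1e-12)
    with pytest.raises(ValueError):
        equilibrium_ratio(RateSet(k2=1e12, km2=0.0))


def test_equilibrium_reached_by_dynamics():
    """With the slow drains off, the DT_hot/biradical ratio relaxes to k2/km2."""
    net = default_dt_network()
    rates = RateSet(k1=4.23e12, k2=0.95e12, km2=0.31e12, k3=2.86e12, k4=2.85e12)
    pops = solve_populations(net, rates, None, np.array([2.0e5]))
    ratio = pops["DT_hot"][0] / pops["biradical"][0]
    assert ratio == pytest.approx(0.95 / 0.31, abs=1e-4)


def test_asymptotic_fractions_single_path():
    net = ReactionNetwork(
        (Species("DT*", "excited"), Species("FB", "product")),
        (("DT*", "FB", "k4"),),
    )
    assert asymptotic_fractions(net, RateSet(k4=1e12)) == {"FB": pytest.approx(1.0)}


def test_asymptotic_fractions_reference_rates():
    net = default_dt_network()
    fr = asymptotic_fractions(net, DT_RATES)
    assert 0.60 <= fr["FB"] <= 0.66
    assert fr["FA-2"] == pytest.approx(1.0 - fr["FB"], abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(rates=rates_strategy)
def test_asymptotic_fractions_conserve_probability(rates):
    net = default_dt_network()
    fr = asymptotic_fractions(net, rates)
    assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in fr.values())


def test_trapped_species_is_reported():
    net = default_dt_network()
    # k5 = 0 leaves FA-1 with no path to any product
    rates = DT_RATES.replace(k5=0.0)
    with pytest.raises(ValueError, match="FA-1"):
        asymptotic_fractions(net, rates)


def test_negative_rates_rejected():
    with pytest.raises(ValueError):
        RateSet(k1=-1.0)
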