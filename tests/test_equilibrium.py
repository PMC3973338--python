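import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimex import (
    BathModel,
    EnergyModel,
    binding_activities,
    correlation_g,
    dimer_occupancy_infinite,
    dimer_occupancy_tm,
    enumerate_dimer_lattice,
    monomer_coverage,
)
from dimex.params import ParameterError

weights = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestBindingActivities:
    @pytest.mark.parametrize("de, cc, zs, zd", [
        (0.0, 1.0, 1.0, 1.0),                       # all Boltzmann factors unity
        (5.0, 0.01, 0.01 * math.e**5, 0.01 * math.e**10),
    ])
    def test_statistical_weights(self, de, cc, zs, zd):
        bath = BathModel.from_coefficient(concentration=cc, capture_coefficient=1.0)
        e = EnergyModel(barrier_unbind=de)
        got = binding_activities(e, bath)
        assert got[0] == pytest.approx(zs, rel=1e-12)
        assert got[1] == pytest.approx(zd, rel=1e-12)

    def test_empty_bath_zero_weights(self):
        e = EnergyModel(barrier_unbind=5.0)
        assert binding_activities(e, BathModel(concentration=0.0)) == (0.0, 0.0)


class TestMonomerCoverage:
    def test_limits_and_symmetric_point(self):
        e = EnergyModel(barrier_unbind=5.0)
        assert monomer_coverage(e, BathModel(concentration=0.0)) == 0.0
        # z_s = 1 is the half-coverage point of the isotherm
        bath = BathModel.from_coefficient(math.exp(-5.0), 1.0)
        assert monomer_coverage(e, bath) == pytest.approx(0.5)

    def test_closed_form_value(self):
        e = EnergyModel(barrier_unbind=5.0)
        bath = BathModel.from_coefficient(0.01, 1.0)
        zs = 0.01 * math.e**5
        assert monomer_coverage(e, bath) == pytest.approx(zs / (1 + zs))


class TestEnumeration:
    def test_single_site_partition(self):
        zs = 0.7
        s = enumerate_dimer_lattice(1, zs, 5.0)
        assert s.mean_bound_proteins == pytest.approx(zs / (1 + zs))
        assert s.singly_fraction == 1.0

    def test_two_site_partition_by_hand(self):
        # configurations: empty; single@1; single@2; two singles; one double
        zs, zd = 0.7, 5.0
        z = 1 + 2 * zs + zs**2 + zd
        s = enumerate_dimer_lattice(2, zs, zd)
        assert s.mean_bound_proteins == pytest.approx((2 * zs + 2 * zs**2 + zd) / z)
        assert s.mean_bound_monomers == pytest.approx((2 * zs + 2 * zs**2 + 2 * zd) / z)

    def test_full_tiling_limit(self):
        # z_s = 0 and huge z_d: even chain tiles completely with doubles
        s = enumerate_dimer_lattice(8, 0.0, 1e12, j_max=5)
        assert s.mean_bound_proteins == pytest.approx(4.0, abs=1e-6)
        assert s.mean_bound_monomers == pytest.approx(8.0, abs=1e-6)
        assert np.allclose(s.g, 1.0, atol=1e-6)

    def test_refuses_combinatorial_blowup(self):
        with pytest.raises(ParameterError):
            enumerate_dimer_lattice(17, 1.0, 1.0)


class TestTransferMatrix:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=10), zs=weights, zd=weights)
    def test_matches_enumeration_oracle(self, n, zs, zd):
        jm = n - 1 - n // 4 if n >= 2 else None
        a = enumerate_dimer_lattice(n, zs, zd, j_max=jm)
        b = dimer_occupancy_tm(n, zs, zd, j_max=jm)
        assert b.mean_bound_monomers == pytest.approx(a.mean_bound_monomers, abs=1e-10)
        assert b.mean_bound_proteins == pytest.approx(a.mean_bound_proteins, abs=1e-10)
        assert b.singly_fraction == pytest.approx(a.singly_fraction, abs=1e-10)
        if jm is not None:
            np.testing.assert_allclose(b.g, a.g, atol=1e-10)

    def test_single_site_langmuir_reduction(self):
        s = dimer_occupancy_tm(1, 0.3, 99.0)
        assert s.mean_bound_monomers == pytest.approx(0.3 / 1.3)

    def test_empty_weights_empty_chain(self):
        assert dimer_occupancy_tm(50, 0.0, 0.0).mean_bound_monomers == 0.0

    def test_thermodynamic_limit_insensitivity(self):
        # per-site occupancy changes < 1% between N = 50 and N = 200
        for zs, zd in [(0.5, 3.0), (0.05, 10.0), (2.0, 0.5)]:
            a = dimer_occupancy_tm(50, zs, zd).mean_bound_monomers / 50
            b = dimer_occupancy_tm(200, zs, zd).mean_bound_monomers / 200
            assert abs(a - b) / b < 0.01

    def test_infinite_chain_closed_form(self):
        nb, npp, phis = dimer_occupancy_infinite(0.5, 3.0)
        s = dimer_occupancy_tm(400, 0.5, 3.0)
        assert nb == pytest.approx(s.mean_bound_monomers / 400, rel=2e-3)
        assert npp == pytest.approx(s.mean_bound_proteins / 400, rel=2e-3)
        # Langmuir reduction when doubles are forbidden
        nb2, _, _ = dimer_occupancy_infinite(1.0, 0.0)
        assert nb2 == pytest.approx(0.5)


class TestCorrelationFunction:
    def test_g0_is_one_everywhere(self):
        for zs, zd in [(0.1, 1.0), (3.0, 40.0)]:
            g = correlation_g(60, zs, zd, 10)
            assert g[0] == 1.0

    def test_decorrelation_to_unconditional_occupancy(self):
        from dimex.equilibrium import _interior_refs, _site_state_probs

        n, zs, zd, jm = 300, 0.5, 2.0, 25
        g = correlation_g(n, zs, zd, jm)
        p = _site_state_probs(n, zs, zd)
        occ = p[:, 1:].sum(axis=1)
        refs = _interior_refs(n, jm)
        theta = (occ[refs] * occ[refs + jm]).sum() / occ[refs].sum()
        assert abs(g[jm] - theta) < 1e-8

    def test_neighbour_excess_and_correlation_hole_at_low_activity(self):
        e = EnergyModel(barrier_unbind=8.0)
        zs, zd = binding_activities(e, BathModel(concentration=1e-8))
        g = correlation_g(100, zs, zd, 20)
        assert g[1] > g[20]   # dimer footprint: neighbour abundance
        assert g[2] < g[20]   # correlation hole two sites away

    def test_oscillation_shrinks_with_concentration(self):
        e = EnergyModel(barrier_unbind=8.0)
        excess = []
        for c in (1e-8, 1e-7, 1e-6, 1e-5):
            zs, zd = binding_activities(e, BathModel(concentration=c))
            g = correlation_g(100, zs, zd, 20)
            excess.append(g[1] - g[20])
        assert all(a > b for a, b in zip(excess, excess[1:]))

    def test_rejects_bad_lag(self):
        with pytest.raises(IndexError):
            correlation_g(10, 1.0, 1.0, 10)


def test_equilibrium_sampler_matches_enumeration_frequencies():
    # forward-filter/backward-sample draws reproduce exact configuration
    # probabilities on a 3-site chain
    from collections import Counter

    from dimex.equilibrium import _enumerate_tilings, sample_equilibrium_configuration

    zs, zd = 0.7, 2.0
    rng = np.random.default_rng(0)
    n_draws = 20_000
    counts = Counter(
        tuple(sample_equilibrium_configuration(3, zs, zd, rng)) for _ in range(n_draws)
    )
    weights = {t[0]: zs ** t[1] * zd ** t[2] for t in _enumerate_tilings(3)}
    z_part = sum(weights.values())
    for config, w in weights.items():
        assert abs(counts.get(config, 0) / n_draws - w / z_part) < 0.011  # ~3 SE


def test_singly_fraction_monotone_in_concentration():
    # stabilized singly bound states fill in as c grows
    e = EnergyModel(barrier_unbind=8.0)
    phis = []
    for c in np.geomspace(1e-8, 1e-3, 8):
        zs, zd = binding_activities(e, BathModel(concentration=c))
        phis.append(dimer_occupancy_tm(100, zs, zd).singly_fraction)
    assert all(a < b for a, b in zip(phis, phis[1:]))
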