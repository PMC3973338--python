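import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimex import (
    BathModel,
    EnergyModel,
    KineticParams,
    bound_monomer_curve,
    build_rate_matrix,
    dominant_rate,
    gillespie_five_state,
    koff_analytic,
    propagate,
)
from dimex.master_equation import FiveStateSystem
from dimex.params import ParameterError

P0_BOUND = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


def make_params(barrier_unbind=8.0, barrier_bind=0.0, c=2e-4, n_sites=100, seed=0):
    return KineticParams(
        n_sites=n_sites,
        energy=EnergyModel(barrier_unbind=barrier_unbind, barrier_bind=barrier_bind),
        bath=BathModel(concentration=c),
        seed=seed,
    )


class TestBuildRateMatrix:
    def test_pathway_structure(self):
        p = make_params()
        k = build_rate_matrix(p).K
        p_ub, p_b = p.p_unbind, p.p_bind
        cap = p.capture_probability
        assert k[1, 0] == k[2, 0] == pytest.approx(p_ub)
        assert k[0, 1] == k[0, 2] == pytest.approx(p_b)
        assert k[3, 1] == k[3, 2] == pytest.approx(cap)
        assert k[4, 1] == k[4, 2] == k[4, 3] == pytest.approx(p_ub)
        # no other off-diagonal channels (state 4 competitor permanent,
        # state 5 absorbing)
        mask = np.zeros((5, 5), dtype=bool)
        mask[[1, 2], 0] = mask[0, [1, 2]] = mask[3, [1, 2]] = mask[4, [1, 2, 3]] = True
        np.fill_diagonal(mask, True)
        assert np.all(k[~mask] == 0.0)

    def test_zero_concentration_disables_capture(self):
        k = build_rate_matrix(make_params(c=0.0)).K
        assert k[3, 1] == 0.0 and k[3, 2] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        de_ub=st.floats(min_value=0.5, max_value=12.0),
        de_b=st.floats(min_value=0.0, max_value=3.0),
        c=st.floats(min_value=0.0, max_value=5e-4),
    )
    def test_columns_sum_to_zero_for_any_parameters(self, de_ub, de_b, c):
        k = build_rate_matrix(make_params(de_ub, de_b, c)).K
        assert np.max(np.abs(k.sum(axis=0))) < 1e-14
        off = k - np.diag(np.diag(k))
        assert off.min() >= 0.0


class TestPropagate:
    def test_initial_state_preserved_at_t0(self):
        sol = propagate(build_rate_matrix(make_params()), P0_BOUND, 0.0)
        np.testing.assert_array_equal(sol.P_traj[0], P0_BOUND)

    def test_frozen_when_unbinding_impossible(self):
        p = make_params(barrier_unbind=200.0)  # p_UB ~ 0
        sol = propagate(build_rate_matrix(p), P0_BOUND, 500.0, record_every=100)
        np.testing.assert_allclose(sol.P_traj[-1], P0_BOUND, atol=1e-12)

    def test_left_right_symmetry_of_singly_bound_states(self):
        sol = propagate(build_rate_matrix(make_params()), P0_BOUND, 5000.0, record_every=100)
        np.testing.assert_allclose(sol.P_traj[:, 1], sol.P_traj[:, 2], atol=1e-12)

    def test_modes_agree_at_small_timestep(self):
        s = build_rate_matrix(make_params())
        small = FiveStateSystem(s.K, timestep=0.05)
        a = propagate(small, P0_BOUND, 2000.0, mode="discrete_iteration", record_every=400)
        b = propagate(small, P0_BOUND, 2000.0, mode="matrix_exponential", record_every=400)
        assert np.abs(a.P_traj - b.P_traj).max() < 1e-6

    def test_probability_conserved(self):
        s = build_rate_matrix(make_params())
        sol = propagate(s, P0_BOUND, 20000.0, record_every=100)
        assert np.abs(sol.P_traj.sum(axis=1) - 1.0).max() < 1e-12
        assert sol.P_traj.min() >= -1e-12

    def test_rejects_off_simplex_start(self):
        with pytest.raises(ValueError):
            propagate(build_rate_matrix(make_params()), np.array([0.5, 0, 0, 0, 0]), 10.0)

    def test_unstable_discrete_timestep_refused(self):
        s = build_rate_matrix(make_params())  # p_B = 1 -> |K_22| slightly > 1
        with pytest.raises(ParameterError):
            propagate(s, P0_BOUND, 10.0, mode="discrete_iteration")

    def test_finite_box_schedule_accelerates_with_released_dimers(self):
        p = make_params(c=1e-4)
        s = build_rate_matrix(p)
        n0_per_vol = 50 / p.box_volume

        def schedule(t, prob):
            return 1e-4 + prob[4] * n0_per_vol

        small = FiveStateSystem(s.K, timestep=0.5)
        fixed = propagate(small, P0_BOUND, 30000.0, mode="discrete_iteration", record_every=600)
        fed = propagate(small, P0_BOUND, 30000.0, c_schedule=schedule, params=p, record_every=600)
        # released dimers raise c, so the scheduled run decays at least as fast
        assert fed.nB_curve[-1] <= fixed.nB_curve[-1] + 1e-12


class TestBoundMonomerCurve:
    def test_endpoints(self):
        sol = propagate(build_rate_matrix(make_params()), P0_BOUND, 0.0)
        assert bound_monomer_curve(sol, 100)[0] == pytest.approx(100.0)
        sol.P_traj = np.array([[0.0, 0, 0, 0, 1.0]])
        assert bound_monomer_curve(sol, 100)[0] == 0.0

    def test_half_weight_of_singly_bound_states(self):
        sol = propagate(build_rate_matrix(make_params()), P0_BOUND, 0.0)
        sol.P_traj = np.array([[0.0, 0.5, 0.5, 0.0, 0.0]])
        assert bound_monomer_curve(sol, 100)[0] == pytest.approx(50.0)


class TestDominantRate:
    def test_zero_without_unbinding(self):
        assert dominant_rate(build_rate_matrix(make_params(barrier_unbind=200.0))) == 0.0

    def test_monotone_in_concentration(self):
        rates = [
            dominant_rate(build_rate_matrix(make_params(c=c)))
            for c in np.linspace(0.0, 5e-4, 8)
        ]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_zero_concentration_limit_matches_bare_rate(self):
        for de in (6.0, 8.0):
            p = make_params(barrier_unbind=de, c=0.0)
            k_me = dominant_rate(build_rate_matrix(p))
            k0 = koff_analytic(p, 0.0).k0
            assert k_me == pytest.approx(k0, rel=0.10)

    def test_requires_absorbing_state(self):
        k = build_rate_matrix(make_params()).K.copy()
        k[0, 4] = 1e-3
        k[4, 4] -= 1e-3
        with pytest.raises(ParameterError):
            dominant_rate(FiveStateSystem(K=k))


class TestGillespieOracle:
    def test_matches_propagated_distribution_within_3se(self):
        p = make_params(c=2e-4)
        s = build_rate_matrix(p)
        t_grid = np.linspace(0.0, 20000.0, 11)
        emp = gillespie_five_state(s, P0_BOUND, t_grid, 2000, np.random.default_rng(3))
        ref = propagate(s, P0_BOUND, 20000.0, record_every=2000).P_traj
        se = np.sqrt(np.clip(ref * (1 - ref), 1e-12, None) / 2000)
        assert np.all(np.abs(emp - ref) <= 3.0 * se + 1e-9)
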