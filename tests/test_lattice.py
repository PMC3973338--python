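import numpy as np
import pytest

from dimex import (
    BathModel,
    EnergyModel,
    KineticParams,
    binding_activities,
    dimer_occupancy_tm,
    equilibrate_saturation,
    gillespie_step,
    make_saturated_state,
    mc_sweep,
    monomer_coverage,
    run_exchange,
    run_titration,
)
from dimex.lattice import AbsorbingConfigurationError
from dimex.params import ParameterError


def make_params(barrier_unbind=6.0, c=2e-4, n_sites=20, seed=0, **kw):
    return KineticParams(
        n_sites=n_sites,
        energy=kw.pop("energy", EnergyModel(barrier_unbind=barrier_unbind)),
        bath=BathModel(concentration=c, capture_radius=kw.pop("capture_radius", 4.0)),
        seed=seed,
        **kw,
    )


class TestSaturatedState:
    def test_even_chain_full_tiling(self):
        st = make_saturated_state(make_params(n_sites=10))
        assert st.n_bound_monomers == 10
        assert st.n_bound_tagged_monomers == 10
        assert len(st.dimer_registry) == 5
        assert all(d["bound_halves"] == 2 for d in st.dimer_registry.values())
        st.audit()

    def test_odd_chain_leaves_last_site_empty(self):
        st = make_saturated_state(make_params(n_sites=11))
        assert st.n_bound_monomers == 10
        assert st.kind[10] == 0

    def test_rejects_single_site(self):
        with pytest.raises(ParameterError):
            make_saturated_state(make_params(n_sites=1))


class TestMcSweep:
    def test_frozen_without_events(self):
        p = make_params(barrier_unbind=500.0, c=0.0)
        st = make_saturated_state(p)
        before = st.kind.copy()
        rng = np.random.default_rng(0)
        for _ in range(50):
            mc_sweep(st, p, rng)
        np.testing.assert_array_equal(st.kind, before)

    def test_bookkeeping_consistent_after_many_sweeps(self):
        p = make_params(barrier_unbind=3.0, c=3e-4, n_sites=30)
        st = make_saturated_state(p)
        rng = np.random.default_rng(1)
        for _ in range(20):
            for _ in range(25):
                mc_sweep(st, p, rng)
            st.audit()

    def test_single_site_monomer_stationary_occupancy(self):
        # N = 1 admits only empty<->singly transitions: Langmuir by detailed balance
        p = make_params(barrier_unbind=3.0, c=2e-4, n_sites=1, seed=5)
        from dimex.lattice import _empty_state, _run_sweeps

        st = _empty_state(1)
        records, _ = _run_sweeps(st, p, 200_000, 10, seed=17)
        occ = records[:, 1].mean()
        theta = monomer_coverage(p.energy, p.bath)
        se = records[:, 1].std() / np.sqrt(len(records) / 30)  # crude autocorr allowance
        assert abs(occ - theta) < 3 * max(se, 5e-3)

    def test_adjacent_singly_bound_dimers_stay_stabilized(self):
        # two singly bound dimers on adjacent sites cannot rebind into each
        # other's occupied sites: with unbinding disabled they persist forever
        p = make_params(barrier_unbind=500.0, c=0.0, n_sites=2)
        from dimex.lattice import _empty_state

        st = _empty_state(2)
        st.kind[:] = 1
        st.tag[:] = 1
        st.dimer_id[:] = [0, 1]
        st.next_id = 2
        rng = np.random.default_rng(0)
        for _ in range(100):
            mc_sweep(st, p, rng)
        assert list(st.kind) == [1, 1]
        assert list(st.dimer_id) == [0, 1]


class TestEquilibrateSaturation:
    def test_strong_binding_high_activity_saturates(self):
        sat_bath = BathModel(concentration=3e-3)
        p = make_params(barrier_unbind=10.0, c=1e-4, n_sites=40)
        st = equilibrate_saturation(p, duration=4000.0, saturation_bath=sat_bath)
        assert st.n_bound_monomers >= 0.95 * 40
        assert st.time == 0.0

    def test_zero_concentration_stays_empty(self):
        p = make_params(barrier_unbind=6.0, c=0.0, n_sites=10)
        st = equilibrate_saturation(p, duration=100.0)
        assert st.n_bound_monomers == 0

    def test_all_bound_dimers_tagged(self):
        p = make_params(barrier_unbind=8.0, c=1e-3, n_sites=30)
        st = equilibrate_saturation(p, duration=2000.0)
        bound = st.kind > 0
        assert np.all(st.tag[bound] == 1)
        assert np.all(st.tag[~bound] == 0)


class TestRunExchange:
    def test_trace_invariants(self):
        p = make_params(barrier_unbind=4.0, c=3e-4, n_sites=20, seed=3)
        traces = run_exchange(p, t_max=2000, n_replicates=3, record_every=10)
        assert len(traces) == 3
        for tr in traces:
            assert np.all(tr.n_B <= tr.n_B_total)
            assert np.all(tr.n_B_total <= 20)
            # tagged dimers never reappear once departed (absorbing bath)
            assert np.all(np.diff(tr.n_tagged_dimers) <= 0)
            assert np.all(tr.n_B <= 2 * tr.n_tagged_dimers)

    def test_replicates_are_independent_but_reproducible(self):
        p = make_params(barrier_unbind=4.0, c=3e-4, seed=9)
        a = run_exchange(p, t_max=500, n_replicates=2, record_every=5)
        b = run_exchange(p, t_max=500, n_replicates=2, record_every=5)
        assert np.array_equal(a[0].n_B, b[0].n_B)
        assert not np.array_equal(a[0].n_B, a[1].n_B)

    def test_no_competitors_without_bath(self):
        # c = 0: decay only through spontaneous unbinding, independent of C
        p1 = make_params(barrier_unbind=5.0, c=0.0, capture_radius=2.0, seed=4)
        p2 = make_params(barrier_unbind=5.0, c=0.0, capture_radius=6.0, seed=4)
        a = run_exchange(p1, t_max=3000, n_replicates=4, record_every=50)
        b = run_exchange(p2, t_max=3000, n_replicates=4, record_every=50)
        np.testing.assert_array_equal(
            np.mean([t.n_B for t in a], axis=0), np.mean([t.n_B for t in b], axis=0)
        )

    def test_half_life_ordering_with_concentration(self):
        halves = []
        for c in (4e-5, 2e-4, 6e-4):
            p = make_params(barrier_unbind=7.0, c=c, n_sites=40, seed=11)
            traces = run_exchange(p, t_max=40000, n_replicates=12, record_every=100)
            m = np.mean([t.n_B for t in traces], axis=0)
            t_half = traces[0].times[np.argmax(m <= 0.5 * m[0])]
            halves.append(t_half)
        assert halves[0] > halves[1] > halves[2]


class TestTitration:
    def test_monomer_mode_matches_langmuir(self):
        p = make_params(barrier_unbind=4.0, c=1e-4, n_sites=100, seed=21)
        stats = run_titration(p, c_grid=[1e-4], t_equil=2000, t_sample=30000,
                              record_every=20, mode="monomer")[0]
        theta = monomer_coverage(p.energy, p.bath) * 100
        assert abs(stats.mean_bound_monomers - theta) < 3 * stats.se_bound_monomers + 0.5

    def test_dimer_mode_matches_transfer_matrix(self):
        p = make_params(barrier_unbind=4.0, c=1e-4, n_sites=100, seed=22)
        stats = run_titration(p, c_grid=[1e-4], t_equil=5000, t_sample=50000,
                              record_every=25)[0]
        zs, zd = binding_activities(p.energy, p.bath)
        ref = dimer_occupancy_tm(100, zs, zd)
        assert abs(stats.mean_bound_monomers - ref.mean_bound_monomers) < max(
            3 * stats.se_bound_monomers, 0.8
        )

    def test_dimer_transition_before_monomer_transition(self):
        # at equal c the dimer's apparent binding transition sits at lower ΔẼ
        p = make_params(c=2e-4, n_sites=100, seed=23)
        grid = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        dim = run_titration(p, energy_grid=grid, t_equil=2000, t_sample=20000)
        mon = run_titration(p, energy_grid=grid, t_equil=2000, t_sample=20000,
                            mode="monomer")
        half = 50.0
        de_dim = next(de for de, s in zip(grid, dim) if s.mean_bound_monomers > half)
        de_mon = next(de for de, s in zip(grid, mon) if s.mean_bound_monomers > half)
        assert de_dim < de_mon

    def test_requires_exactly_one_grid(self):
        p = make_params()
        with pytest.raises(ParameterError):
            run_titration(p, c_grid=[1e-4], energy_grid=[4.0])


class TestGillespie:
    def test_mean_waiting_time_single_exit_channel(self):
        # one singly bound half with no free neighbour and no bath: the only
        # channel is departure, so the waiting time is exponential with mean
        # 1/(nu_MC * p_UB)
        p = make_params(barrier_unbind=4.0, c=0.0, n_sites=1)
        from dimex.lattice import _empty_state

        rng = np.random.default_rng(12)
        waits = []
        for _ in range(3000):
            st = _empty_state(1)
            st.kind[0] = 1
            st.dimer_id[0] = 0
            st.next_id = 1
            t0 = st.time
            gillespie_step(st, p, rng)
            waits.append(st.time - t0)
        expected = 1.0 / (p.mc_frequency * p.p_unbind)
        assert np.mean(waits) == pytest.approx(expected, rel=0.06)

    def test_absorbing_configuration_raises(self):
        p = make_params(barrier_unbind=6.0, c=0.0, n_sites=4)
        from dimex.lattice import _empty_state

        st = _empty_state(4)
        with pytest.raises(AbsorbingConfigurationError):
            gillespie_step(st, p, np.random.default_rng(0))

    def test_stationary_occupancy_matches_sweep_dynamics(self):
        # long Gillespie run and sweep dynamics sample the same equilibrium
        p = make_params(barrier_unbind=3.0, c=3e-4, n_sites=8, seed=31)
        from dimex.lattice import _empty_state, _run_sweeps

        rng = np.random.default_rng(31)
        st = _empty_state(8)
        occ_time = 0.0
        tot_time = 0.0
        # warm up
        for _ in range(2000):
            gillespie_step(st, p, rng)
        for _ in range(30000):
            t0 = st.time
            nb = st.n_bound_monomers
            gillespie_step(st, p, rng)
            occ_time += nb * (st.time - t0)
            tot_time += st.time - t0
        g_occ = occ_time / tot_time
        zs, zd = binding_activities(p.energy, p.bath)
        ref = dimer_occupancy_tm(8, zs, zd).mean_bound_monomers
        assert g_occ == pytest.approx(ref, rel=0.05)


def test_total_occupancy_relaxes_faster_at_higher_concentration():
    # the saturated start relaxes towards an equilibrium below full tiling;
    # the time to cover half the gap shrinks with concentration
    times = []
    for c in (4e-5, 3e-4):
        p = make_params(barrier_unbind=3.0, c=c, n_sites=60, seed=41)
        traces = run_exchange(p, t_max=3000, n_replicates=16, record_every=2)
        m = np.mean([t.n_B_total for t in traces], axis=0)
        eq = m[-len(m) // 5 :].mean()
        assert eq < 0.95 * m[0]  # a visible relaxation gap exists
        target = m[0] + 0.5 * (eq - m[0])
        times.append(traces[0].times[np.argmax(m <= target)])
    assert times[1] < times[0]
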