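"""Kinetic Monte Carlo of dimeric binders on a 1D lattice.

Implements the Bell-model attempt probabilities (``p_UB = exp(-ΔẼ_UB)``,
``p_B = exp(-ΔẼ_b)``, capture ``C·c·p_B``; one attempt per elementary
kernel per sweep at frequency ``ν_MC``) and the tagged-exchange protocol:
saturate the chain, tag every bound dimer at ``t = 0``, switch the bath to
untagged competitors at concentration ``c`` and record the tagged
bound-monomer count ``n_B(t)``.

See :mod:`dimex._kernels` for the sweep algorithm; its random-order
composition of reversible elementary kernels makes the stationary state of
this simulator exactly the transfer-matrix Gibbs measure of
:mod:`dimex.equilibrium`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dimex import _kernels
from dimex.equilibrium import (
    LatticeEnsembleStats,
    _interior_refs,
    binding_activities,
    sample_equilibrium_configuration,
)
from dimex.params import BathModel, EnergyModel, KineticParams, ParameterError

__all__ = [
    "LatticeState",
    "ExchangeTrace",
    "make_saturated_state",
    "equilibrate_saturation",
    "mc_sweep",
    "gillespie_step",
    "run_exchange",
    "run_titration",
    "AbsorbingConfigurationError",
]


class AbsorbingConfigurationError(RuntimeError):
    """No kinetic event is possible from this configuration."""


@dataclass
class LatticeState:
    """Mutable occupancy state of the lattice plus the free pools.

    ``kind[i]`` is 0 (empty), 1 (singly bound half, partner dangling) or
    2 (doubly bound half); ``partner[i]`` holds the adjacent site of the
    other half for doubly bound dimers.  ``free_tagged`` / ``free_untagged``
    count fully unbound dimers in the finite-box pool (in absorbing mode
    the untagged bath is an infinite reservoir and tagged leavers vanish).
    """

    kind: np.ndarray
    partner: np.ndarray
    tag: np.ndarray
    dimer_id: np.ndarray
    free_tagged: float = 0.0
    free_untagged: float = 0.0
    time: float = 0.0
    next_id: int = 0

    @property
    def n_sites(self) -> int:
        return self.kind.size

    @property
    def n_bound_monomers(self) -> int:
        return int((self.kind > 0).sum())

    @property
    def n_bound_tagged_monomers(self) -> int:
        return int(((self.kind > 0) & (self.tag == 1)).sum())

    @property
    def n_singly(self) -> int:
        return int((self.kind == 1).sum())

    @property
    def dimer_registry(self) -> dict:
        """Map dimer_id -> {tagged, bound_halves, sites} for bound dimers."""
        reg: dict = {}
        for i in range(self.n_sites):
            if self.kind[i] == 0:
                continue
            did = int(self.dimer_id[i])
            entry = reg.setdefault(
                did, {"tagged": bool(self.tag[i]), "bound_halves": 0, "sites": []}
            )
            entry["bound_halves"] += 1
            entry["sites"].append(i)
        return reg

    def audit(self) -> None:
        """Exhaustive consistency check of occupancy bookkeeping."""
        n = self.n_sites
        for i in range(n):
            k = self.kind[i]
            if k == 0:
                assert self.partner[i] == -1 and self.dimer_id[i] == -1, i
            elif k == 1:
                assert self.partner[i] == -1, i
                assert self.dimer_id[i] >= 0, i
            elif k == 2:
                j = self.partner[i]
                assert 0 <= j < n and abs(j - i) == 1, (i, j)
                assert self.kind[j] == 2 and self.partner[j] == i, (i, j)
                assert self.dimer_id[j] == self.dimer_id[i], (i, j)
                assert self.tag[j] == self.tag[i], (i, j)
            else:  # pragma: no cover
                raise AssertionError(f"invalid kind {k} at {i}")
        for did, entry in self.dimer_registry.items():
            assert entry["bound_halves"] in (1, 2), did
            if entry["bound_halves"] == 2:
                a, b = sorted(entry["sites"])
                assert b - a == 1, did
        assert self.free_tagged >= 0 and self.free_untagged >= 0

    def copy(self) -> "LatticeState":
        return LatticeState(
            kind=self.kind.copy(),
            partner=self.partner.copy(),
            tag=self.tag.copy(),
            dimer_id=self.dimer_id.copy(),
            free_tagged=self.free_tagged,
            free_untagged=self.free_untagged,
            time=self.time,
            next_id=self.next_id,
        )


@dataclass
class ExchangeTrace:
    """Time series of one exchange replicate.

    ``n_B`` counts tagged bound monomers, ``n_B_total`` all bound monomers,
    ``n_singly`` all singly bound dimers and ``n_singly_tagged`` /
    ``n_tagged_dimers`` the tagged subsets (used to measure the singly
    bound fractions behind the analytic rate law).
    """

    times: np.ndarray
    n_B: np.ndarray
    n_B_total: np.ndarray
    n_singly: np.ndarray
    n_singly_tagged: np.ndarray
    n_tagged_dimers: np.ndarray
    replicate_id: int
    params_digest: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "replicate": self.replicate_id,
                "n_B": self.n_B,
                "n_B_total": self.n_B_total,
                "n_singly": self.n_singly,
            }
        )


def _empty_state(n_sites: int) -> LatticeState:
    return LatticeState(
        kind=np.zeros(n_sites, dtype=np.int8),
        partner=np.full(n_sites, -1, dtype=np.int32),
        tag=np.zeros(n_sites, dtype=np.uint8),
        dimer_id=np.full(n_sites, -1, dtype=np.int64),
    )


def make_saturated_state(params: KineticParams) -> LatticeState:
    """Chain tiled with doubly bound tagged dimers at ``t = 0``.

    Pairs occupy sites (0,1), (2,3), ...; an odd final site stays empty.
    """
    n = params.n_sites
    if n < 2:
        raise ParameterError("saturated initialisation requires n_sites >= 2")
    st = _empty_state(n)
    did = 0
    for a in range(0, n - 1, 2):
        b = a + 1
        st.kind[a] = st.kind[b] = 2
        st.partner[a], st.partner[b] = b, a
        st.tag[a] = st.tag[b] = 1
        st.dimer_id[a] = st.dimer_id[b] = did
        did += 1
    st.next_id = did
    if params.bath_mode == "finite_box":
        st.free_untagged = params.bath.concentration * params.box_volume
    return st


def _finite_box_capture_bound(params: KineticParams, state: LatticeState) -> None:
    # Worst case: every bound dimer joins the pool; the capture probability
    # must remain a valid probability throughout the run.
    max_pool = state.free_tagged + state.free_untagged + state.n_bound_monomers
    worst = params.bath.capture_coefficient * params.p_bind * max_pool / params.box_volume
    if worst > 1.0:
        raise ParameterError(
            f"finite-box capture probability can reach {worst:.3g} > 1; "
            "enlarge box_volume or reduce capture_radius"
        )


def _kernel_args(state: LatticeState, params: KineticParams):
    absorbing = params.bath_mode == "absorbing"
    offsets = params.energy.site_offsets(params.n_sites)
    off_factor = np.exp(-offsets)
    cap_const = params.capture_probability
    cap_per_dimer = params.bath.capture_coefficient * params.p_bind / params.box_volume
    pool = np.array([state.free_tagged, state.free_untagged, float(state.next_id)])
    if not absorbing:
        _finite_box_capture_bound(params, state)
    return absorbing, off_factor, cap_const, cap_per_dimer, pool


def _run_sweeps(
    state: LatticeState,
    params: KineticParams,
    n_sweeps: int,
    record_every: int,
    seed: int,
    j_max: int = -1,
) -> tuple[np.ndarray, Optional[tuple[np.ndarray, int]]]:
    """Advance ``state`` in place; return records (and g accumulators)."""
    absorbing, off_factor, cap_const, cap_per_dimer, pool = _kernel_args(state, params)
    n_rec = n_sweeps // record_every if record_every > 0 else 0
    records = np.zeros((n_rec, 5), dtype=np.int64)
    if j_max >= 0:
        refs = _interior_refs(params.n_sites, j_max)
        ref_lo, ref_hi = int(refs[0]), int(refs[-1])
    else:
        ref_lo, ref_hi = 0, -1
    g_ref = np.zeros(1, dtype=np.int64)
    g_pair = np.zeros(max(j_max, 0) + 1, dtype=np.int64)
    _kernels.run_lattice(
        state.kind, state.partner, state.tag, state.dimer_id,
        off_factor, params.p_unbind, params.p_bind,
        cap_const, cap_per_dimer, absorbing, pool,
        n_sweeps, record_every, records, seed,
        j_max, ref_lo, ref_hi, g_ref, g_pair,
    )
    state.free_tagged, state.free_untagged = pool[0], pool[1]
    state.next_id = int(pool[2])
    state.time += n_sweeps * params.timestep
    g_out = (g_pair, int(g_ref[0])) if j_max >= 0 else None
    return records, g_out


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def mc_sweep(
    state: LatticeState, params: KineticParams, rng: np.random.Generator
) -> LatticeState:
    """Advance the state by one sweep (time ``Δt``), in place."""
    _run_sweeps(state, params, 1, 0, _spawn_seed(rng))
    return state


def equilibrate_saturation(
    params: KineticParams,
    duration: float,
    saturation_bath: Optional[BathModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> LatticeState:
    """Saturate by running the kinetics at high bath activity, then tag.

    Starts from an empty chain, evolves for ``duration`` under
    ``saturation_bath`` (default: the run bath), tags every currently
    bound dimer, resets ``t = 0`` and returns the state.  Unlike
    :func:`make_saturated_state` this retains the natural minority of
    singly bound dimers present at saturation.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    sat_params = params if saturation_bath is None else params.with_bath(saturation_bath)
    # saturation happens against an open (absorbing-mode) reservoir
    if sat_params.bath_mode != "absorbing":
        sat_params = KineticParams(
            n_sites=sat_params.n_sites, energy=sat_params.energy, bath=sat_params.bath,
            mc_frequency=sat_params.mc_frequency, bath_mode="absorbing",
            box_volume=sat_params.box_volume, seed=sat_params.seed,
        )
    state = _empty_state(params.n_sites)
    n_sweeps = int(round(duration * params.mc_frequency))
    _run_sweeps(state, sat_params, n_sweeps, 0, _spawn_seed(rng))
    bound = state.kind > 0
    state.tag[bound] = 1
    state.tag[~bound] = 0
    state.time = 0.0
    if params.bath_mode == "finite_box":
        state.free_untagged = params.bath.concentration * params.box_volume
        state.free_tagged = 0.0
    return state


def run_exchange(
    params: KineticParams,
    t_max: float,
    n_replicates: int,
    record_every: int = 1,
    init: str = "tiled",
    equilibration: float = 0.0,
    saturation_bath: Optional[BathModel] = None,
) -> list[ExchangeTrace]:
    """Tagged-exchange protocol over independent replicates.

    Each replicate starts saturated and fully tagged, then evolves to
    ``t_max`` against the untagged bath at the parameters' concentration,
    recording ``(t, n_B, n_B_total, n_singly, ...)`` every
    ``record_every`` sweeps.  Replicates use independent seeded RNG
    streams spawned from ``params.seed``.
    """
    if t_max <= 0 or n_replicates < 1:
        raise ParameterError("t_max must be > 0 and n_replicates >= 1")
    if init not in ("tiled", "equilibrated"):
        raise ParameterError("init must be 'tiled' or 'equilibrated'")
    n_sweeps = int(round(t_max * params.mc_frequency))
    digest = params.digest()
    root = np.random.SeedSequence(params.seed)
    traces = []
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        if init == "tiled":
            state = make_saturated_state(params)
        else:
            state = equilibrate_saturation(
                params, equilibration, saturation_bath=saturation_bath, rng=rng
            )
        t0_row = (
            state.n_bound_tagged_monomers,
            state.n_bound_monomers,
            state.n_singly,
            int(((state.kind == 1) & (state.tag == 1)).sum()),
            len([1 for d in state.dimer_registry.values() if d["tagged"]]),
        )
        seed = _spawn_seed(rng)
        records, _ = _run_sweeps(state, params, n_sweeps, record_every, seed)
        n_rec = records.shape[0]
        times = np.concatenate(
            [[0.0], (np.arange(1, n_rec + 1) * record_every) * params.timestep]
        )
        full = np.vstack([np.array(t0_row, dtype=np.int64), records])
        traces.append(
            ExchangeTrace(
                times=times,
                n_B=full[:, 0],
                n_B_total=full[:, 1],
                n_singly=full[:, 2],
                n_singly_tagged=full[:, 3],
                n_tagged_dimers=full[:, 4],
                replicate_id=rep,
                params_digest=digest,
                seed=seed,
            )
        )
    return traces


def state_from_equilibrium_draw(
    params: KineticParams, rng: np.random.Generator
) -> LatticeState:
    """Lattice state initialised from an exact Gibbs draw (untagged)."""
    zs, zd = binding_activities(params.energy, params.bath)
    codes = sample_equilibrium_configuration(params.n_sites, zs, zd, rng)
    st = _empty_state(params.n_sites)
    did = 0
    for i, code in enumerate(codes):
        if code == 1:  # singly bound
            st.kind[i] = 1
            st.dimer_id[i] = did
            did += 1
        elif code == 2:  # left half of a doubly bound dimer
            st.kind[i] = st.kind[i + 1] = 2
            st.partner[i], st.partner[i + 1] = i + 1, i
            st.dimer_id[i] = st.dimer_id[i + 1] = did
            did += 1
    st.next_id = did
    if params.bath_mode == "finite_box":
        st.free_untagged = params.bath.concentration * params.box_volume
    return st


def _block_stats(samples: np.ndarray, n_blocks: int) -> tuple[float, float]:
    samples = np.asarray(samples, dtype=float)
    usable = (samples.size // n_blocks) * n_blocks
    if usable == 0:
        return float(samples.mean()), float("nan")
    blocks = samples[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def run_titration(
    params: KineticParams,
    c_grid: Optional[Sequence[float]] = None,
    energy_grid: Optional[Sequence[float]] = None,
    t_equil: float = 10_000.0,
    t_sample: float = 100_000.0,
    record_every: int = 50,
    mode: str = "dimer",
    j_max: Optional[int] = None,
    n_blocks: int = 20,
    n_replicates: int = 1,
    init: str = "tiled",
) -> list[LatticeEnsembleStats]:
    """Long-run equilibrium averages over a concentration or energy grid.

    ``energy_grid`` values replace the unbinding barrier ``ΔẼ_UB`` (the
    binding barrier is kept); exactly one grid must be given.  In
    ``mode='monomer'`` the binders are independent single-site monomers
    and the observables reduce to the Langmuir isotherm.

    With ``n_replicates == 1`` standard errors come from block averaging
    of the single time series; with more replicates each runs an
    independent stream and the SE is taken across replicate means, which
    also captures modes slower than the sampling window.
    ``init='equilibrium'`` starts each dimer-mode run from an exact
    transfer-matrix Gibbs draw instead of the saturated tiling — essential
    at strong binding and low activity, where the defect density relaxes
    on ``~1/(2 p_UB C c)`` sweeps, far beyond feasible windows.
    """
    if (c_grid is None) == (energy_grid is None):
        raise ParameterError("provide exactly one of c_grid or energy_grid")
    if t_equil <= 0 or t_sample <= 0:
        raise ParameterError("equilibration and sampling windows must be positive")
    if mode not in ("dimer", "monomer"):
        raise ParameterError("mode must be 'dimer' or 'monomer'")
    if init not in ("tiled", "equilibrium"):
        raise ParameterError("init must be 'tiled' or 'equilibrium'")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")

    grid: list[KineticParams] = []
    if c_grid is not None:
        grid = [params.with_concentration(float(c)) for c in c_grid]
    else:
        for de_ub in energy_grid:  # type: ignore[union-attr]
            energy = EnergyModel(
                barrier_unbind=float(de_ub),
                barrier_bind=params.energy.barrier_bind,
                disorder_sigma=params.energy.disorder_sigma,
                disorder_seed=params.energy.disorder_seed,
            )
            grid.append(
                KineticParams(
                    n_sites=params.n_sites, energy=energy, bath=params.bath,
                    mc_frequency=params.mc_frequency, bath_mode=params.bath_mode,
                    box_volume=params.box_volume, seed=params.seed,
                )
            )

    root = np.random.SeedSequence(params.seed)
    out = []
    for p, child in zip(grid, root.spawn(len(grid))):
        n_equil = int(round(t_equil * p.mc_frequency))
        n_sample = int(round(t_sample * p.mc_frequency))
        jm = j_max if j_max is not None else -1
        rep_nb, rep_np, rep_phi = [], [], []
        g_pair_total = np.zeros(max(jm, 0) + 1, dtype=np.int64)
        g_ref_total = 0
        for rep_child in child.spawn(n_replicates):
            rng = np.random.default_rng(rep_child)
            if mode == "monomer":
                occ = np.zeros(p.n_sites, dtype=np.int8)
                if init == "equilibrium":
                    zs, _ = binding_activities(p.energy, p.bath)
                    occ[:] = rng.random(p.n_sites) < zs / (1.0 + zs)
                n_rec = n_sample // record_every
                records = np.zeros(n_rec, dtype=np.int64)
                _kernels.run_monomer(
                    occ, p.p_unbind, p.capture_probability,
                    n_equil, 0, np.zeros(0, dtype=np.int64), _spawn_seed(rng),
                )
                _kernels.run_monomer(
                    occ, p.p_unbind, p.capture_probability,
                    n_sample, record_every, records, _spawn_seed(rng),
                )
                rep_nb.append(records.astype(float))
                continue

            if init == "equilibrium":
                state = state_from_equilibrium_draw(p, rng)
            elif p.n_sites >= 2:
                state = make_saturated_state(p)
            else:
                state = _empty_state(p.n_sites)
            state.tag[:] = 0  # titration tracks occupancy, not tags
            _run_sweeps(state, p, n_equil, 0, _spawn_seed(rng))
            records, g_acc = _run_sweeps(
                state, p, n_sample, record_every, _spawn_seed(rng), j_max=jm
            )
            nb_samples = records[:, 1].astype(float)
            ns_samples = records[:, 2].astype(float)
            np_samples = ns_samples + (nb_samples - ns_samples) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                phi_samples = np.where(
                    np_samples > 0, ns_samples / np.maximum(np_samples, 1e-300), 0.0
                )
            rep_nb.append(nb_samples)
            rep_np.append(np_samples)
            rep_phi.append(phi_samples)
            if g_acc is not None:
                g_pair, g_refcount = g_acc
                g_pair_total += g_pair
                g_ref_total += g_refcount

        def _aggregate(series_list):
            if n_replicates == 1:
                return _block_stats(series_list[0], n_blocks)
            means = np.array([s.mean() for s in series_list])
            return float(means.mean()), float(
                means.std(ddof=1) / np.sqrt(n_replicates)
            )

        nb, nb_se = _aggregate(rep_nb)
        if mode == "monomer":
            out.append(
                LatticeEnsembleStats(
                    n_sites=p.n_sites,
                    mean_bound_monomers=nb,
                    mean_bound_proteins=nb,
                    singly_fraction=1.0,
                    se_bound_monomers=nb_se,
                    se_bound_proteins=nb_se,
                )
            )
            continue
        npr, np_se = _aggregate(rep_np)
        phi, phi_se = _aggregate(rep_phi)
        g = None
        if jm >= 0:
            g = np.ones(jm + 1)
            if g_ref_total > 0:
                g[1:] = g_pair_total[1:] / g_ref_total
        zs, zd = binding_activities(p.energy, p.bath)
        out.append(
            LatticeEnsembleStats(
                n_sites=p.n_sites,
                mean_bound_monomers=nb,
                mean_bound_proteins=npr,
                singly_fraction=phi,
                g=g,
                z_s=zs,
                z_d=zd,
                se_bound_monomers=nb_se,
                se_bound_proteins=np_se,
                se_singly_fraction=phi_se,
            )
        )
    return out


# ---------------------------------------------------------------------------
# continuous-time oracle
# ---------------------------------------------------------------------------

def _lattice_channels(state: LatticeState, params: KineticParams) -> list[tuple[float, tuple]]:
    """Enumerate (rate, event) pairs for the current configuration."""
    nu = params.mc_frequency
    p_ub, p_b = params.p_unbind, params.p_bind
    offsets = params.energy.site_offsets(params.n_sites)
    off_factor = np.exp(-offsets)
    absorbing = params.bath_mode == "absorbing"
    if absorbing:
        cap = params.capture_probability
    else:
        cap = (
            params.bath.capture_coefficient * params.p_bind
            * (state.free_tagged + state.free_untagged) / params.box_volume
        )
    channels: list[tuple[float, tuple]] = []
    n = state.n_sites
    for i in range(n):
        k = state.kind[i]
        if k == 0:
            if cap > 0:
                channels.append((nu * cap, ("capture", i)))
        elif k == 1:
            channels.append((nu * p_ub * off_factor[i], ("depart", i)))
            for j in (i - 1, i + 1):
                if 0 <= j < n and state.kind[j] == 0:
                    channels.append((nu * p_b, ("rebind", i, j)))
        elif k == 2:
            j = int(state.partner[i])
            # unbind the half at i, anchored at j (each half listed once)
            channels.append((nu * p_ub * off_factor[i], ("halve", j, i)))
    return channels


def gillespie_step(
    state: LatticeState, params: KineticParams, rng: np.random.Generator
) -> LatticeState:
    """One exact continuous-time event (oracle for :func:`mc_sweep`).

    Draws an exponential waiting time at the total current event rate,
    picks a channel categorically and applies it.  Statistically
    equivalent to the fixed-timestep sweeps in the small-probability
    limit.  Raises :class:`AbsorbingConfigurationError` when no event is
    possible.
    """
    channels = _lattice_channels(state, params)
    rates = np.array([r for r, _ in channels])
    total = rates.sum()
    if total <= 0:
        raise AbsorbingConfigurationError("no possible event and zero capture rate")
    state.time += rng.exponential(1.0 / total)
    event = channels[rng.choice(len(channels), p=rates / total)][1]
    absorbing = params.bath_mode == "absorbing"
    if event[0] == "capture":
        i = event[1]
        is_tagged = 0
        if not absorbing:
            total_pool = state.free_tagged + state.free_untagged
            if total_pool <= 0:
                return state
            if rng.random() < state.free_tagged / total_pool:
                is_tagged, state.free_tagged = 1, state.free_tagged - 1
            else:
                state.free_untagged -= 1
        state.kind[i], state.partner[i] = 1, -1
        state.tag[i], state.dimer_id[i] = is_tagged, state.next_id
        state.next_id += 1
    elif event[0] == "depart":
        i = event[1]
        if not absorbing:
            if state.tag[i]:
                state.free_tagged += 1
            else:
                state.free_untagged += 1
        state.kind[i], state.partner[i] = 0, -1
        state.tag[i], state.dimer_id[i] = 0, -1
    elif event[0] == "rebind":
        i, j = event[1], event[2]
        state.kind[i] = state.kind[j] = 2
        state.partner[i], state.partner[j] = j, i
        state.tag[j], state.dimer_id[j] = state.tag[i], state.dimer_id[i]
    elif event[0] == "halve":
        anchor, gone = event[1], event[2]
        state.kind[gone], state.partner[gone] = 0, -1
        state.tag[gone], state.dimer_id[gone] = 0, -1
        state.kind[anchor], state.partner[anchor] = 1, -1
    return state
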