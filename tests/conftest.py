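"""Shared fixtures.

The expensive exchange simulations used by several acceptance checks are
session-scoped so the concentration-grid runs are executed once and
shared between the off-rate-law and regime-discrimination tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dimex import (
    BathModel,
    EnergyModel,
    KineticParams,
    build_rate_matrix,
    dominant_rate,
    fit_exponential,
    run_exchange,
)

BOX_VOLUME = 125_000.0  # (50 a)^3 simulation box
DIMER_COUNTS = (4, 12, 24, 36, 48)  # free dimers in the box -> c grid
C_GRID = tuple(n / BOX_VOLUME for n in DIMER_COUNTS)
N_SITES = 100
N_REPLICATES = 32


def lattice_params(barrier_unbind: float, c: float, seed: int, **kw) -> KineticParams:
    return KineticParams(
        n_sites=kw.pop("n_sites", N_SITES),
        energy=EnergyModel(barrier_unbind=barrier_unbind, **kw.pop("energy_kw", {})),
        bath=BathModel(concentration=c, capture_radius=kw.pop("capture_radius", 4.0)),
        seed=seed,
        **kw,
    )


def run_cgrid_exchange(barrier_unbind: float, t_cap: float, seed: int):
    """Exchange runs + exponential fits over the concentration grid."""
    out = []
    for i, c in enumerate(C_GRID):
        params = lattice_params(barrier_unbind, c, seed + i)
        k_me = dominant_rate(build_rate_matrix(params))
        t_max = min(2.0 / k_me, t_cap)
        record_every = max(1, int(t_max // 400))
        traces = run_exchange(
            params, t_max=t_max, n_replicates=N_REPLICATES, record_every=record_every
        )
        fit = fit_exponential(traces, rng=np.random.default_rng(seed + i))
        out.append({"c": c, "params": params, "k_me": k_me, "traces": traces, "fit": fit})
    return out


@pytest.fixture(scope="session")
def exchange_grid_strong():
    """Concentration-grid exchange at a strong unbinding barrier (8 k_BT)."""
    return run_cgrid_exchange(8.0, t_cap=120_000.0, seed=101)


@pytest.fixture(scope="session")
def exchange_grid_weak():
    """Concentration-grid exchange at a weak unbinding barrier (2 k_BT)."""
    return run_cgrid_exchange(2.0, t_cap=600.0, seed=201)
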