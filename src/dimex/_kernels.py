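"""Numba kernels for the lattice kinetic Monte Carlo.

One sweep visits, in a fresh random permutation, all ``3N`` elementary
kernels of the chain:

* site kernel ``i``: empty site captures a bath dimer with probability
  ``C*c_eff*p_B`` / a singly bound dimer departs with ``p_UB*exp(-δ_i)``;
* bond kernel ``(i, i±1)``: a singly bound dimer at ``i`` rebinds its
  dangling half onto a free neighbour with ``p_B`` / a doubly bound dimer
  anchored at ``i`` loses its half at the neighbour with ``p_UB*exp(-δ_j)``.

Each elementary kernel is a reversible two-configuration move satisfying
detailed balance with the weights ``z_s = C*c*e^{ΔẼ}`` and
``z_d = C*c*e^{2ΔẼ}``, so their random-order composition leaves the exact
transfer-matrix Gibbs measure stationary for *any* attempt probabilities,
not only in the small-probability limit.  Inapplicable kernels are no-ops,
which is what makes the permutation configuration-independent.

Site state codes: 0 empty, 1 singly bound half (partner dangling),
2 doubly bound half.  ``pool`` carries mutable scalars:
``[n_free_tagged, n_free_untagged, next_dimer_id]`` (finite-box mode) —
in absorbing mode the untagged bath is an infinite reservoir at fixed
``c`` and tagged leavers are deleted.
"""

import numpy as np
from numba import njit

__all__ = ["run_lattice", "run_monomer"]


@njit(cache=True)
def _capture_prob(absorbing, cap_const, cap_per_dimer, pool):
    if absorbing:
        return cap_const
    return cap_per_dimer * (pool[0] + pool[1])


@njit(cache=True)
def run_lattice(
    kind,            # int8[N]
    partner,         # int32[N]
    tag,             # uint8[N]
    dimid,           # int64[N]
    off_factor,      # float64[N], exp(-site offset) multiplying p_UB
    p_ub,
    p_b,
    cap_const,       # C*c*p_B (absorbing mode)
    cap_per_dimer,   # C*p_B/V (finite-box mode)
    absorbing,       # bool
    pool,            # float64[3]
    n_sweeps,
    record_every,
    records,         # int64[n_records, 5]
    seed,
    j_max,           # -1 disables correlation accumulation
    ref_lo,
    ref_hi,          # inclusive
    g_ref,           # int64[1]: occupied-reference counter
    g_pair,          # int64[j_max+1]
):
    np.random.seed(seed)
    n = kind.size
    slots = np.arange(3 * n)
    rec = 0
    for sweep in range(n_sweeps):
        np.random.shuffle(slots)
        for q in slots:
            i = q % n
            typ = q // n
            if typ == 0:
                if kind[i] == 0:
                    cap = _capture_prob(absorbing, cap_const, cap_per_dimer, pool)
                    if cap > 0.0 and np.random.random() < cap:
                        is_tagged = 0
                        if not absorbing:
                            total = pool[0] + pool[1]
                            if total <= 0.0:
                                continue
                            if np.random.random() < pool[0] / total:
                                is_tagged = 1
                                pool[0] -= 1.0
                            else:
                                pool[1] -= 1.0
                        kind[i] = 1
                        partner[i] = -1
                        tag[i] = is_tagged
                        dimid[i] = np.int64(pool[2])
                        pool[2] += 1.0
                elif kind[i] == 1:
                    if np.random.random() < p_ub * off_factor[i]:
                        if not absorbing:
                            if tag[i] == 1:
                                pool[0] += 1.0
                            else:
                                pool[1] += 1.0
                        kind[i] = 0
                        partner[i] = -1
                        tag[i] = 0
                        dimid[i] = -1
            else:
                j = i + 1 if typ == 1 else i - 1
                if j < 0 or j >= n:
                    continue
                if kind[i] == 1 and kind[j] == 0:
                    if np.random.random() < p_b:
                        kind[i] = 2
                        kind[j] = 2
                        partner[i] = j
                        partner[j] = i
                        tag[j] = tag[i]
                        dimid[j] = dimid[i]
                elif kind[i] == 2 and partner[i] == j:
                    if np.random.random() < p_ub * off_factor[j]:
                        kind[j] = 0
                        partner[j] = -1
                        tag[j] = 0
                        dimid[j] = -1
                        kind[i] = 1
                        partner[i] = -1
        if record_every > 0 and (sweep + 1) % record_every == 0:
            nb_tag = 0
            nb_tot = 0
            n_singly = 0
            n_singly_tag = 0
            n_dimers_tag = 0
            for i in range(n):
                if kind[i] > 0:
                    nb_tot += 1
                    if tag[i] == 1:
                        nb_tag += 1
                    if kind[i] == 1:
                        n_singly += 1
                        if tag[i] == 1:
                            n_singly_tag += 1
                            n_dimers_tag += 1
                    elif tag[i] == 1 and partner[i] > i:
                        n_dimers_tag += 1
            records[rec, 0] = nb_tag
            records[rec, 1] = nb_tot
            records[rec, 2] = n_singly
            records[rec, 3] = n_singly_tag
            records[rec, 4] = n_dimers_tag
            rec += 1
            if j_max >= 0:
                for i in range(ref_lo, ref_hi + 1):
                    if kind[i] > 0:
                        g_ref[0] += 1
                        for jj in range(1, j_max + 1):
                            if kind[i + jj] > 0:
                                g_pair[jj] += 1


@njit(cache=True)
def run_monomer(occ, p_ub, cap, n_sweeps, record_every, records, seed):
    """Independent-site monomer lattice: capture ``C*c*p_B``, unbind ``p_UB``."""
    np.random.seed(seed)
    n = occ.size
    rec = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            if occ[i] == 0:
                if np.random.random() < cap:
                    occ[i] = 1
            else:
                if np.random.random() < p_ub:
                    occ[i] = 0
        if record_every > 0 and (sweep + 1) % record_every == 0:
            records[rec] = occ.sum()
            rec += 1
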