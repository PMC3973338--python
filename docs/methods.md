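# Methods

## The physical model

A dimeric DNA-binding protein (the motivating case is the bacterial
nucleoid protein Fis, which contacts two adjacent major grooves through two
identical helix-turn-helix domains) is modelled as two identical monomer
units, each forming an independent, concentration-independent bond with one
binding site of a linear DNA chain.  The chain is a 1D lattice of `N`
binding sites; a dimer is *doubly bound* (two adjacent sites), *singly
bound* (one site, the partner dangling) or free in a well-mixed bath at
number density `c`.

Each monomer-site bond is a Bell-type barrier crossing: with update
frequency `ν_MC`, a bound monomer detaches with probability
`p_UB = exp(-ΔẼ_UB)` per attempt and an available monomer attaches with
`p_B = exp(-ΔẼ_b)`, energies in units of k_BT.  The net binding energy per
bond is `ΔẼ = ΔẼ_UB - ΔẼ_b`.  A free dimer reaches an empty site with
probability `C·c·p_B` per update, where `C = (4/3)π r_c³` is the capture
volume around a site.

Unbinding of a *doubly* bound dimer requires two steps: one half detaches
(a reversible "excitation"), then either the second half detaches before
the first rebinds, or a competitor from solution captures the open site,
blocking rebinding and leaving the tagged dimer in a *stabilized singly
bound* state that can only exit.  The second pathway is proportional to
`c`, which is the entire mechanism behind the concentration-dependent
off-rate

    k_off(c) = k_0 + k_1 · c,
    k_0 = 2 e^{-ΔẼ} p_B/(p_B+p_UB) · ν_UB,    k_1 = 2 C · ν_UB,

with `ν_UB = ν_MC p_UB`.  The factor 2 in `k_0` counts the two halves that
can detach first; `φ₁(c) = 2Cc` follows from the chemical-potential balance
between solution dimers (mixing entropy `μ̃ = ln(C·c)`) and adjacent
stabilized pairs, two singly bound states created per inserted dimer with a
single mixing-entropy term because the pair remains adjacent on kinetic
time scales.

## Model levels and how they validate each other

1. **Exact equilibrium** (`dimex.equilibrium`).  The grand-canonical weights
   are `z_s = C·c·e^{ΔẼ}` per singly bound dimer and `z_d = C·c·e^{2ΔẼ}`
   per doubly bound dimer, fixed by detailed balance against the kinetic
   probabilities above (capture/departure gives `z_s`; rebind per free
   adjacent site vs half-unbind gives `z_d/z_s = e^{ΔẼ}`).  Observables are
   computed three independent ways: exhaustive enumeration (ground truth,
   `N ≤ 16`), a 4-state-per-site transfer matrix (open chain, any `N`), and
   the thermodynamic-limit closed form from the leading eigenvalue
   `λ = [(1+z_s) + √((1+z_s)² + 4 z_d)]/2`.  The chemical-potential
   convention `μ̃ = ln(C·c)` absorbs the bath's reference chemical potential
   into `C`; users mapping to another convention rescale `C` accordingly.

2. **Lattice kinetic Monte Carlo** (`dimex.lattice`).  One sweep visits, in
   a fresh random permutation, all `3N` elementary kernels: a site kernel
   (empty ↔ singly bound: capture `C·c_eff·p_B` vs departure `p_UB`) and two
   bond kernels per site (singly ↔ doubly toward each neighbour: rebind
   `p_B` vs half-unbind `p_UB`).  Every kernel is a reversible
   two-configuration move satisfying detailed balance with the weights
   above, and inapplicable kernels are no-ops, so the permutation is
   configuration-independent and the chain's stationary law is *exactly*
   the transfer-matrix Gibbs measure for any attempt probabilities — not
   only in the small-probability limit.  This is why the titration tests can
   demand agreement with theory at simulation precision.  A singly bound
   dimer attempts rebinding to *each* free adjacent site independently with
   `p_B`; collapsing the two directions into a single uniform choice would
   halve the per-site flux ratio and visibly bias the equilibrium.
   A continuous-time Gillespie step with the same channel rates serves as
   the independent oracle for the fixed-timestep sweeps.

   Site-energy disorder adds quenched Gaussian offsets (std `σ`) to the
   *unbinding* barrier only, keeping attempt times fixed; realisations are
   reproducible from a stored seed and are redrawn per replicate
   (quenched within a run, annealed across the ensemble).

3. **Five-state master equation** (`dimex.master_equation`).  A single
   tracked dimer: doubly bound (1), singly bound with its open site free
   (2, 3 for the two sides), singly bound with a competitor on the open
   site (4), unbound (5, absorbing).  Rates per update: 1→2,3 at `p_UB`;
   2,3→1 at `p_B`; 2,3→4 at `C·c·p_B`; 2,3,4→5 at `p_UB`.  The state-4
   competitor is treated as permanently bound — its own unbinding is
   `O(p_UB)` slow in the regime where the theory applies — and departed
   dimers never return (the experimental flow removes them).  `k_off` is
   the smallest decay rate of the transient 4×4 block; if the spectrum is
   defective the long-time slope of the propagated decay is used instead.

4. **Brownian dynamics** (`dimex.brownian`).  Two-bead dimers (harmonic
   bond, rest length `2a`, stiffness `10 k_BT/a²`) diffuse by synchronous
   first-order Euler–Maruyama (`δt = a²/(100 D)`) in a periodic box around
   a fixed straight chain of binding beads at spacing `2a`.  Forces are
   evaluated on the pre-step snapshot for all beads: sequential updates
   would feed one bead's fresh noise into its partner's bond force and
   measurably inflate the centre-of-mass diffusion (which must equal `D/2`
   exactly).  Bound beads are pinned at their site (a tethered variant is a
   documented deviation knob, not implemented); binding updates run every
   `1/(ν_MC δt)` steps with the same Bell probabilities, capture within
   `r_c` of an unoccupied site (nearest eligible site, one event per bead
   per update).  Within an update, binding is attempted *before* unbinding
   so a released bead first experiences a full diffusion interval.  Tagged
   dimers become untagged when their unwrapped centre crosses the box
   boundary while fully unbound.

## The exchange experiment

`run_exchange` reproduces the tagged-competition protocol: saturate the
chain (either an ideal doubly bound tiling, or kinetically at high bath
activity, which retains the natural minority of singly bound dimers), tag
every bound dimer at `t = 0`, switch the bath to untagged competitors at
concentration `c`, and record the tagged bound-monomer count `n_B(t)`.
In the default `absorbing` bath mode fully unbound tagged dimers are
removed and `c` stays fixed (flow-controlled experiment); `finite_box`
mode returns them to a pool of volume `V` so `c` grows during the run
(simulation-box protocol), with the matching self-consistent
concentration schedule available in the master-equation propagator.

Rate extraction fits the least-squares slope of `log n_B(t)` on a window
that opens after 5% of the initial signal has decayed (excluding the
documented fast transient from initially singly bound dimers) and
bootstrap-resamples replicates (200 resamples) for the standard error.
`(k_0, k_1)` come from an SE-weighted linear fit of `k_off` on `c`.

## Quasi-steady state versus equilibrium for the singly bound fraction

The stabilized fraction `φ₁ = 2Cc` entering the analytic law is a *kinetic
quasi-steady-state* population: pairs of stabilized singles are counted
while still adjacent.  At true equilibrium the two singles of a pair
separate entropically (they are domain walls of the dimer tiling) and the
singly bound density crosses over to a `√(C·c)` law, which the transfer
matrix reproduces.  The analytic fractions are therefore validated against
the master equation's quasi-steady state and against tagged singly bound
fractions measured *during exchange*, not against equilibrium titration.
The titration observable instead validates the simulator's detailed
balance.

Validity of the analytic law requires `p_UB ≪ p_B` (quasi-equilibrated
excitation; flagged above `p_UB/p_B = 0.05`) and dilute capture
(`C·c·p_B ≲ 0.1`; beyond that the exact rate visibly saturates below the
linear law, by the factor `1/(1 + C·c + …)`).  Outside the regime results
carry warning flags rather than being silently reported.

## Default parameters and study conditions

| quantity | default | why |
| --- | --- | --- |
| `N` (binding sites) | 100 | long enough that edge effects are ~1% of exchange curves |
| box volume `V` | `(50a)³` | 4–400 dimers span activities `C·c ≈ 0.009–0.86` |
| `ΔẼ_b` | 0 (`p_B = 1`) | the lattice absorbs the attempt time into `ν_MC`; configurable |
| `ΔẼ_UB` grid | 2, 4, 6, 8 k_BT | weak (attempt-limited) to strong (exchange-dominated) regimes |
| capture radius `r_c` | `4a` lattice/BD default | aligned-triplet geometry is `3a`; the slightly larger default reflects the better effective fit of capture in off-lattice dynamics.  Cross-model mapping tests use the geometric `3a` on both sides |
| exchange c grid | 4, 12, 24, 36, 48 dimers / `V` | stays inside the dilute-capture validity regime |
| disorder σ | 0 or 2 k_BT | 2 k_BT produces a clearly resolved slow tail |
| BD | `D = 1 a²/τ`, `δt = 0.01`, MC update every 100 steps | update period equals the bead diffusion time `a²/D` |

Problem sizes in the validation suite (replicate counts 32–100, sampling
windows of 10⁵ sweeps, BD at `N = 20` sites with 40 dimers) were chosen as
the smallest ensembles whose standard errors resolve the claims being
tested; all are set in one place (`tests/conftest.py`,
`scripts/acceptance.py`) and scale up by changing constants.

## Numerical choices

* Transfer-matrix forward/backward vectors are renormalised per site
  (log-scale bookkeeping), so chains of any length and strongly saturated
  weights stay finite.  The same forward pass drives an exact
  forward-filter/backward-sampling draw of equilibrium configurations,
  used to initialise titration runs: at strong binding and low activity
  the defect (singly bound) density relaxes on `~1/(2 p_UB C c)` sweeps,
  far beyond any feasible window, so a non-equilibrium start would bias
  the measured isotherm.  Titration standard errors are taken across
  independent replicates (not only via block averaging), which also
  captures modes slower than the sampling window.
* The correlation function `g(j)` conditions on a fixed window of interior
  reference sites (margin `N//4`), identical in the enumeration and
  transfer-matrix routes, so the two are comparable bit-for-bit; `g(0)=1`
  by construction, and for an empty chain `g(j>0)` is defined as 0.
* Master-equation propagation asserts probability conservation to 1e-12
  at every step and then renormalises the float sum so pure roundoff
  cannot accumulate over ~10⁵ steps.  The discrete map `M = I + KΔt`
  refuses timesteps with `Δt > 1/max|K_jj|` (with `p_B = 1` this means the
  per-sweep map is not a stochastic matrix; the continuous-time
  exponential is the reference for cross-model comparisons).
* Exponential fits trim trailing zero-signal points (with a warning) and
  refuse windows with fewer than 10 points.
* Ties in the sweep (two captures competing for one site, both rebind
  directions open) are resolved by the random execution order of the
  permutation, avoiding synchronous-update lattice artifacts.
* All randomness flows through seeded, spawned `numpy` `SeedSequence`
  streams (one per replicate, logged in run manifests); the compiled
  kernels use the seeded legacy generator internally.  Identical config
  and seed give byte-identical outputs.

## What the synthetic conditions do and do not show

The generator emulates the *mechanism*: identical independent monomer
bonds, dimer geometry, competitor capture, flow removal of unbound
binders, and optionally Gaussian site disorder.  It does not model
sequence-specific binding landscapes, binder-binder cooperativity beyond
site exclusion, DNA elasticity or looping, 1D sliding/hopping search, or
hydrodynamic interactions.  Passing tests therefore demonstrate the
internal consistency of the mechanism and its rate law, not that any
particular protein's measured `k_0`/`k_1` are reproduced; mapping to a real
system requires calibrating `ν_MC`, `ΔẼ_UB` and `C` against data.

## Known limitations

* With `p_B = 1` the discrete per-sweep master-equation map is mildly
  non-stochastic (`|K_22| > 1/Δt`); use the matrix exponential, or a
  binding barrier `ΔẼ_b > 0`, when a discrete mirror is required.
* The BD exchange rate sits below the mapped lattice rate (factor ~0.7 at
  the tested conditions) because a released dimer can recapture its own
  site before a competitor claims it — a return-visit effect the
  mean-field bath has no analogue for.  The cross-model check is therefore
  a factor-2 consistency test, not an identity.
* The 5-state closure has a bounded validity window in concentration.
  Below `C·c ≈ 0.05` a channel it lacks becomes visible: competitor dimers
  that are themselves singly bound next to a tagged dimer capture its
  transiently open site with their *dangling arm* at rate ~`p_B`, orders
  of magnitude faster than bath capture.  Singly bound competitors
  accumulate during exchange (the slow crossover toward the `√(C·c)`
  equilibrium), so the lattice decay runs ahead of the master equation —
  up to ~70% in rate at `C·c ≈ 0.009`.  Above `C·c ≈ 0.15` with `p_B = 1`
  the fixed-timestep capture-vs-rebind competition instead makes the
  lattice a few percent slower than the continuous-time theory.
  Near-quantitative matching (sup-norm < 0.05 of the normalised decay)
  holds between these limits, and the cross-model validation runs there
  (`C·c ≈ 0.08–0.14`).  One measurable consequence: a linear fit of
  lattice `k_off(c)` spanning low concentrations acquires a positive
  intercept offset well above the bare two-step rate `k_0`, so the
  microscopic intercept should be read from the master-equation/analytic
  level, not from the lattice fit.
* The master equation also ignores competitor unbinding from state 4,
  `O(p_UB/p_B)` — sub-percent at `ΔẼ_UB ≥ 6` but growing as the barrier
  weakens.
* Enumeration is capped at `N = 16` sites (configuration count grows by
  ~×2.4 per site).
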