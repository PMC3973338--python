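"""Closed-form off-rate law from the two-pathway quasi-equilibrium argument.

A doubly bound dimer unbinds through two channels (the two-pathway map):

* the *excited* pathway: one half detaches spontaneously, leaving a singly
  bound dimer whose open site is still free; a fraction

      φ₀ = 2 · exp(-ΔẼ) · p_B / (p_B + p_UB)

  of bound dimers occupy this state (quasi-equilibrium of the singly bound
  "excited" state against the bath of doubly bound dimers; the factor of
  two counts the two halves that can detach first), independent of
  concentration;

* the *stabilized* pathway: a competitor from solution captures the open
  site, so the dangling half can no longer rebind.  The chemical-potential
  balance between solution dimers (mixing entropy μ̃ = ln(C·c)) and
  adjacent stabilized pairs — two singly bound states created per inserted
  dimer, one mixing-entropy term because the pair stays adjacent on
  kinetic time scales — gives the linear-in-c fraction

      φ₁(c) = 2 · C · c.

Each singly bound dimer leaves at ν_UB = ν_MC·p_UB, so

    k_off(c) = (φ₀ + φ₁(c)) · ν_UB = k_0 + k_1·c,
    k_0 = 2·exp(-ΔẼ)·p_B/(p_B+p_UB)·ν_UB,   k_1 = 2·C·ν_UB.

φ₁ is a kinetic quasi-steady-state population (the stabilized pair is
counted while still adjacent), *not* the full-equilibrium singly bound
fraction: at equilibrium the two singles of a pair separate entropically
and the singly bound density crosses over to a sqrt(C·c) domain-wall law,
visible in the transfer-matrix isotherm.  Validation therefore runs
against exchange kinetics (master-equation quasi-steady state and tagged
singly bound fractions during lattice exchange), where the linear law is
the controlling population.

Validity requires the quasi-equilibrium regime ``p_UB << p_B`` and dilute
capture ``C·c·p_B << 1``; outside it the result carries warning flags
rather than being silently reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dimex.params import KineticParams

__all__ = ["RateLaw", "phi_fractions", "koff_analytic", "koff_from_experiment_shape"]

# Regime thresholds for the quasi-equilibrium closure.
_MAX_PUB_OVER_PB = 0.05
_MAX_CAPTURE_PROB = 0.1


def _validity_flags(params: KineticParams, c: float) -> list[str]:
    flags = []
    if params.p_unbind / params.p_bind > _MAX_PUB_OVER_PB:
        flags.append(
            f"p_UB/p_B = {params.p_unbind / params.p_bind:.3g} > {_MAX_PUB_OVER_PB}: "
            "excited-state quasi-equilibrium unreliable (attempt-limited regime)"
        )
    cap = params.bath.capture_coefficient * c * params.p_bind
    if cap > _MAX_CAPTURE_PROB:
        flags.append(
            f"C*c*p_B = {cap:.3g} > {_MAX_CAPTURE_PROB}: capture not dilute, "
            "linear-in-c law saturates"
        )
    return flags


@dataclass
class RateLaw:
    """Evaluated off-rate law ``k_off(c) = k0 + k1*c`` at one concentration."""

    k0: float
    k1: float
    c: float
    phi_excited: float
    phi_stabilized: float
    nu_unbind: float
    validity_flags: list[str] = field(default_factory=list)

    @property
    def k_off(self) -> float:
        return self.k0 + self.k1 * self.c

    @property
    def valid(self) -> bool:
        return not self.validity_flags

    def to_record(self) -> dict:
        return {
            "k0": self.k0,
            "k1": self.k1,
            "c": self.c,
            "k_off": self.k_off,
            "phi0": self.phi_excited,
            "phi1": self.phi_stabilized,
            "validity_flags": list(self.validity_flags),
        }


def phi_fractions(params: KineticParams, c: float) -> tuple[float, float, list[str]]:
    """Singly bound population fractions ``(φ₀, φ₁(c))`` plus validity flags.

    ``φ₀`` is the concentration-independent excited fraction,
    ``φ₁ = 2·C·c`` the stabilized fraction.  In the master equation's
    quasi-steady state these are the populations ``(P₂+P₃)/P₁`` and
    ``P₄/P₁`` of a tracked dimer, which is what lattice exchange runs
    measure on their tagged population.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    p_b, p_ub = params.p_bind, params.p_unbind
    phi0 = 2.0 * math.exp(-params.energy.net_energy) * p_b / (p_b + p_ub)
    phi1 = 2.0 * params.bath.capture_coefficient * c
    return phi0, phi1, _validity_flags(params, c)


def koff_analytic(params: KineticParams, c: float) -> RateLaw:
    """Evaluate ``k_off = (φ₀ + φ₁(c))·ν_UB ≡ k0 + k1·c`` at ``c``."""
    phi0, phi1, flags = phi_fractions(params, c)
    nu_ub = params.mc_frequency * params.p_unbind
    return RateLaw(
        k0=phi0 * nu_ub,
        k1=2.0 * params.bath.capture_coefficient * nu_ub,
        c=c,
        phi_excited=phi0,
        phi_stabilized=phi1,
        nu_unbind=nu_ub,
        validity_flags=flags,
    )


def koff_from_experiment_shape(k0: float, k1: float, c_grid) -> np.ndarray:
    """Evaluate the linear law ``k_off = k0 + k1*c`` on a concentration grid."""
    if k0 < 0 or k1 < 0:
        raise ValueError("k0 and k1 must be >= 0")
    return k0 + k1 * np.asarray(c_grid, dtype=float)
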