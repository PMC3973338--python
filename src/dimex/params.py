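"""Parameter containers shared by every model level.

Units
-----
Energies are in units of k_BT (written with a tilde in the docs, e.g.
``ΔẼ_UB``).  Lengths are in units of the bead radius ``a``; volumes in
``a**3``.  Time is measured in Monte-Carlo update periods ``1/ν_MC``
unless a physical ``mc_frequency`` is supplied, in which case rates are
reported in ``ν_MC`` per unit time.

Concentration ``c`` is a number density (free dimers per ``a**3``).  The
capture coefficient ``C = (4/3)·π·r_c**3`` is the effective volume within
which a free dimer can reach an empty site during one update, so the
dimensionless activity is ``z = C·c``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["EnergyModel", "BathModel", "KineticParams"]


class ParameterError(ValueError):
    """Raised for physically inadmissible parameter combinations."""


@dataclass(frozen=True)
class EnergyModel:
    """Bell-model binding landscape of a single monomer-site bond.

    Parameters
    ----------
    barrier_unbind :
        Unbinding barrier ``ΔẼ_UB >= 0`` (k_BT).  The per-attempt unbinding
        probability is ``exp(-ΔẼ_UB)``.
    barrier_bind :
        Binding barrier ``ΔẼ_b >= 0`` (k_BT); per-attempt binding
        probability ``exp(-ΔẼ_b)``.  Default 0: the lattice abstraction
        absorbs the attempt time into the update frequency.
    disorder_sigma :
        Standard deviation (k_BT) of quenched Gaussian offsets added to the
        unbinding barrier per site.  0 means a homogeneous landscape.
    disorder_seed :
        Seed from which per-site offsets are (re)drawn, so a disorder
        realisation is reproducible.
    """

    barrier_unbind: float
    barrier_bind: float = 0.0
    disorder_sigma: float = 0.0
    disorder_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.barrier_unbind < 0 or self.barrier_bind < 0:
            raise ParameterError("energy barriers must be >= 0 k_BT")
        if self.disorder_sigma < 0:
            raise ParameterError("disorder_sigma must be >= 0")
        if self.disorder_sigma > 0 and self.disorder_seed is None:
            raise ParameterError(
                "disorder_sigma > 0 requires disorder_seed for reproducibility"
            )

    @property
    def net_energy(self) -> float:
        """Net binding energy ``ΔẼ = ΔẼ_UB - ΔẼ_b`` per bond (k_BT).

        Always recomputed from the two barriers, never stored separately.
        """
        return self.barrier_unbind - self.barrier_bind

    @property
    def p_unbind(self) -> float:
        """Per-attempt unbinding probability ``exp(-ΔẼ_UB)``."""
        return math.exp(-self.barrier_unbind)

    @property
    def p_bind(self) -> float:
        """Per-attempt binding probability ``exp(-ΔẼ_b)``."""
        return math.exp(-self.barrier_bind)

    def site_offsets(self, n_sites: int) -> np.ndarray:
        """Quenched Gaussian barrier offsets for ``n_sites`` sites.

        Returns zeros when ``disorder_sigma == 0``.  Offsets are added to
        the *unbinding* barrier only, so a positive offset slows unbinding
        at that site while the attempt frequency stays fixed.
        """
        if self.disorder_sigma == 0.0:
            return np.zeros(n_sites)
        rng = np.random.default_rng(self.disorder_seed)
        return rng.normal(0.0, self.disorder_sigma, size=n_sites)


@dataclass(frozen=True)
class BathModel:
    """Well-mixed bath of free dimers.

    Parameters
    ----------
    concentration :
        Number density ``c >= 0`` of free dimers (per ``a**3``).
    capture_radius :
        Radius ``r_c > 0`` (units of ``a``) of the sphere within which a
        free dimer can bind a site in one update.  The capture coefficient
        is ``C = (4/3)·π·r_c**3``; the two are kept mutually consistent.
    """

    concentration: float
    capture_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")
        if self.capture_radius <= 0:
            raise ParameterError("capture_radius must be > 0")

    @classmethod
    def from_coefficient(cls, concentration: float, capture_coefficient: float) -> "BathModel":
        """Construct from the capture volume ``C`` instead of ``r_c``."""
        if capture_coefficient <= 0:
            raise ParameterError("capture_coefficient must be > 0")
        r_c = (3.0 * capture_coefficient / (4.0 * math.pi)) ** (1.0 / 3.0)
        return cls(concentration=concentration, capture_radius=r_c)

    @property
    def capture_coefficient(self) -> float:
        """Capture volume ``C = (4/3)·π·r_c**3`` (units ``a**3``)."""
        return (4.0 / 3.0) * math.pi * self.capture_radius**3

    @property
    def activity(self) -> float:
        """Dimensionless bath activity ``z = C·c >= 0``."""
        return self.capture_coefficient * self.concentration

    def with_concentration(self, c: float) -> "BathModel":
        return BathModel(concentration=c, capture_radius=self.capture_radius)


@dataclass(frozen=True)
class KineticParams:
    """Full parameter set of the lattice kinetic Monte Carlo.

    ``bath_mode='absorbing'`` removes fully unbound tagged dimers (the
    experimental flow carries them away; the untagged bath concentration is
    held fixed).  ``bath_mode='finite_box'`` returns every fully unbound
    dimer to a well-mixed pool of volume ``box_volume`` so the free
    concentration evolves during an exchange run.
    """

    n_sites: int
    energy: EnergyModel
    bath: BathModel
    mc_frequency: float = 1.0
    bath_mode: str = "absorbing"
    box_volume: float = 125_000.0  # (50 a)^3 default simulation box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if self.mc_frequency <= 0:
            raise ParameterError("mc_frequency must be > 0")
        if self.bath_mode not in ("absorbing", "finite_box"):
            raise ParameterError("bath_mode must be 'absorbing' or 'finite_box'")
        if self.box_volume <= 0:
            raise ParameterError("box_volume must be > 0")
        if self.capture_probability > 1.0:
            raise ParameterError(
                f"capture probability C*c*p_B = {self.capture_probability:.3g} > 1; "
                "reduce concentration, capture radius or rescale the timestep"
            )

    @property
    def timestep(self) -> float:
        """Sweep duration ``Δt = 1/ν_MC``."""
        return 1.0 / self.mc_frequency

    @property
    def p_unbind(self) -> float:
        return self.energy.p_unbind

    @property
    def p_bind(self) -> float:
        return self.energy.p_bind

    @property
    def capture_probability(self) -> float:
        """Per-site capture probability ``C·c·p_B`` per sweep."""
        return self.bath.activity * self.energy.p_bind

    def with_bath(self, bath: BathModel) -> "KineticParams":
        return KineticParams(
            n_sites=self.n_sites,
            energy=self.energy,
            bath=bath,
            mc_frequency=self.mc_frequency,
            bath_mode=self.bath_mode,
            box_volume=self.box_volume,
            seed=self.seed,
        )

    def with_concentration(self, c: float) -> "KineticParams":
        return self.with_bath(self.bath.with_concentration(c))

    def digest(self) -> str:
        """Stable short hash of the full parameter set, for trace metadata."""
        payload = {
            "n_sites": self.n_sites,
            "barrier_unbind": self.energy.barrier_unbind,
            "barrier_bind": self.energy.barrier_bind,
            "disorder_sigma": self.energy.disorder_sigma,
            "disorder_seed": self.energy.disorder_seed,
            "concentration": self.bath.concentration,
            "capture_radius": self.bath.capture_radius,
            "mc_frequency": self.mc_frequency,
            "bath_mode": self.bath_mode,
            "box_volume": self.box_volume,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
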