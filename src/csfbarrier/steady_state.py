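"""The connected steady-state model of blood-CSF protein exchange.

Blood-derived proteins enter the cerebrospinal fluid by barrier-restricted
diffusion while CSF bulk flow carries them away; every point along the
neuraxis is a steady state between the two.  Writing the barrier-restricted
exchange coefficient as ``aleph = D * B`` (free diffusion coefficient D
attenuated by a dimensionless barrier factor 0 < B < 1), the CSF/serum
concentration quotient as a function of CSF flow time t is the saturation
law

    Q(t) = 1 - exp(-aleph * k * t / L),        F(t) = exp(-aleph * k * t / L)

where k (unit 1/m) is a proportionality constant, L the barrier thickness,
and F the molecular flux relative to its initial (back-diffusion-free)
value.  Two operating modes are supported and kept explicit: ``fitted``
(aleph dimensionless, k/L = 1, t in arbitrary flow-time units — the
convention used when fitting the empirical quotient curves) and
``physical`` (SI-consistent units).

Because aleph = D * B and the Stokes-Einstein relation ties D to the
hydrodynamic radius R_H, ratios of fitted exchange coefficients decompose
into an R_H ratio and a barrier-factor ratio,

    aleph_ref / aleph_x = (R_H(x) / R_H(ref)) * (B_ref / B_x),

which is the basis for inferring in-vivo hydrodynamic radii and barrier
specificity from quotient data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Optional

import numpy as np

__all__ = [
    "BOLTZMANN",
    "SteadyStateParams",
    "MoleculeSpec",
    "StokesEinsteinContext",
    "planar_flux",
    "steady_state_q",
    "steady_state_flux",
    "cascade_q",
    "stokes_einstein_d",
    "barrier_quotient",
    "infer_rh",
    "flow_time_for_q",
    "load_default_molecules",
]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class SteadyStateParams:
    """Parameters of the saturation law Q(t) = 1 - exp(-aleph*k*t/L).

    In ``fitted`` mode aleph is dimensionless and k, L default to 1; in
    ``physical`` mode aleph is in cm^2/s, k in 1/cm, L in cm, t in s.
    The exponent rate ``aleph*k*t/L`` is dimensionless in both.
    """

    aleph: float
    t: float
    k: float = 1.0
    l: float = 1.0
    mode: Literal["fitted", "physical"] = "fitted"

    def __post_init__(self) -> None:
        if self.aleph < 0:
            raise ValueError("aleph must be >= 0")
        if self.k <= 0 or self.l <= 0:
            raise ValueError("k and L must be > 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def rate(self) -> float:
        """Dimensionless exponent aleph * k * t / L."""
        return self.aleph * self.k * self.t / self.l


@dataclass(frozen=True)
class MoleculeSpec:
    """A protein's size and transport characteristics.

    r_h: hydrodynamic radius in nm.  d: free diffusion coefficient in
    cm^2/s (optional).  b: barrier factor, 0 < b < 1 (optional).
    aleph_fitted: dimensionless exchange coefficient from fitting the
    saturation curve to the empirical quotient relations (optional).
    When both d and b are given, the physical exchange coefficient is
    their product.
    """

    name: str
    r_h: float
    d: Optional[float] = None
    b: Optional[float] = None
    aleph_fitted: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r_h <= 0:
            raise ValueError("r_h must be > 0")
        if self.b is not None and not (0 < self.b < 1):
            raise ValueError("barrier factor b must satisfy 0 < b < 1")
        if self.d is not None and self.d <= 0:
            raise ValueError("d must be > 0")

    @property
    def aleph_physical(self) -> Optional[float]:
        """aleph = D * B (cm^2/s) when both factors are known."""
        if self.d is None or self.b is None:
            return None
        return self.d * self.b


@dataclass(frozen=True)
class StokesEinsteinContext:
    """Temperature/viscosity context for the Stokes-Einstein relation.

    Defaults: body temperature 310.15 K and water viscosity at 37 C,
    6.9e-4 Pa*s.  Only ratios of diffusion coefficients are anchored in
    the quotient data; absolute values are convenience output.
    """

    temperature: float = 310.15  # K
    viscosity: float = 6.9e-4  # Pa*s
    boltzmann: float = BOLTZMANN

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be > 0")


def planar_flux(d: float, c1: float, c2: float, l: float) -> float:
    """Steady-state diffusive flux between parallel planes: D*(c1-c2)/L."""
    if l <= 0:
        raise ValueError("l must be > 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    return d * (c1 - c2) / l


def steady_state_q(p: SteadyStateParams) -> float:
    """CSF/serum quotient Q(t) = 1 - exp(-aleph*k*t/L); in [0, 1)."""
    return -math.expm1(-p.rate)


def steady_state_flux(p: SteadyStateParams) -> float:
    """Relative molecular flux F(t) = exp(-aleph*k*t/L) = 1 - Q(t)."""
    return math.exp(-p.rate)


def cascade_q(
    aleph: float,
    v: float,
    c_blood: float = 1.0,
    n_segments: int = 1,
    l: float = 1.0,
) -> np.ndarray:
    """Quotients along the discrete cascade of consecutive steady states.

    The most upstream CSF segment receives the full influx
    ``aleph/L * c_blood``; bulk flow at velocity v dilutes it to
    ``C(E1) = aleph * c_blood / (L*v)``.  Each downstream segment sees the
    influx reduced by the concentration already accumulated:

        C(E_{i+1}) = C(E_i) + (aleph/L) * (c_blood - C(E_i)) / v

    Returns the per-segment quotients Q_i = C(E_i)/c_blood.  With the
    per-segment increment read as ``aleph*k*dt/L`` this is the
    forward-Euler discretization of dQ/dtau = (aleph*k/L)*(1-Q) and
    converges to the closed-form saturation law as segments are refined.
    """
    if v <= 0:
        raise ValueError("bulk flow velocity v must be > 0")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if l <= 0:
        raise ValueError("l must be > 0")
    if c_blood <= 0:
        raise ValueError("c_blood must be > 0")
    # quotients are invariant to c_blood; it only scales the concentrations
    delta = aleph / (l * v)
    q = np.empty(n_segments)
    current = 0.0
    for i in range(n_segments):
        current = current + delta * (1.0 - current)
        q[i] = current
    return q


def stokes_einstein_d(r_h: float, ctx: StokesEinsteinContext = StokesEinsteinContext()) -> float:
    """Free diffusion coefficient D = k_B*T / (6*pi*eta*R_H), in cm^2/s.

    ``r_h`` is in nm.  Strictly decreasing in R_H; the product D*R_H is
    constant across molecules at fixed temperature and viscosity.
    """
    if r_h <= 0:
        raise ValueError("r_h must be > 0")
    d_m2 = ctx.boltzmann * ctx.temperature / (6 * math.pi * ctx.viscosity * r_h * 1e-9)
    return d_m2 * 1e4  # m^2/s -> cm^2/s


def barrier_quotient(aleph_ratio: float, rh_ratio: float) -> float:
    """Barrier-factor quotient B_ref/B_x from exchange and radius ratios.

    From aleph_ref/aleph_x = (R_H(x)/R_H(ref)) * (B_ref/B_x):
    ``aleph_ratio`` is aleph_ref/aleph_x, ``rh_ratio`` is R_H(x)/R_H(ref).
    A value of 1 means the barrier does not discriminate between the two
    molecules beyond their size-driven diffusion difference.
    """
    if aleph_ratio <= 0 or rh_ratio <= 0:
        raise ValueError("ratios must be > 0")
    return aleph_ratio / rh_ratio


def infer_rh(
    aleph_ratio: float,
    reference: MoleculeSpec,
    assume_equal_b: bool = True,
    barrier_ratio: Optional[float] = None,
) -> float:
    """In-vivo hydrodynamic radius from an exchange-coefficient ratio.

    ``aleph_ratio`` is aleph_ref/aleph_x.  Under equal barrier factors,
    R_H(x) = R_H(ref) * aleph_ratio.  Otherwise the barrier-factor
    quotient B_ref/B_x must be supplied and is divided out.
    """
    if aleph_ratio <= 0:
        raise ValueError("aleph_ratio must be > 0")
    if assume_equal_b:
        return reference.r_h * aleph_ratio
    if barrier_ratio is None:
        raise ValueError("barrier_ratio required when assume_equal_b is False")
    if barrier_ratio <= 0:
        raise ValueError("barrier_ratio must be > 0")
    return reference.r_h * aleph_ratio / barrier_ratio


def flow_time_for_q(q: float, aleph: float, k_over_l: float = 1.0) -> float:
    """CSF flow time reaching quotient q: t = -ln(1-q) / (aleph*k/L).

    Inverse of the saturation law.  In the small-Q regime t is nearly
    proportional to Q, so a doubling of flow time doubles the quotient.
    """
    if not (0 <= q < 1):
        raise ValueError("q must be in [0, 1); the quotient saturates at 1")
    if aleph <= 0 or k_over_l <= 0:
        raise ValueError("aleph and k/L must be > 0")
    return -math.log1p(-q) / (aleph * k_over_l)


def load_default_molecules() -> dict[str, MoleculeSpec]:
    """Packaged reference molecules (albumin, IgG, IgA monomer, IgM)."""
    with resources.files("csfbarrier.data").joinpath("molecules.json").open() as fh:
        raw = json.load(fh)
    return {
        name: MoleculeSpec(name=name, r_h=m["r_h"], aleph_fitted=m.get("aleph_fitted"))
        for name, m in raw["molecules"].items()
    }
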