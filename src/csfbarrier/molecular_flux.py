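"""The erfc-based "molecular flux" description, kept for comparison.

An earlier description of blood-to-CSF protein transfer models CSF as a
semi-infinite medium fed by diffusion from the blood boundary.  With the
concentration held constant at the boundary the textbook solution is
``Q = erfc(z)`` with ``z = x / (2*sqrt(D*t))``; the variant actually used
historically is the half-erfc form ``Q = 0.5*erfc(z)``, whose boundary
concentration is pinned at half the blood value for all t > 0.  That
boundary condition means CSF could never equilibrate with blood and
violates Fick's first law at the boundary, which is why this package uses
the connected steady-state model for all inference and exposes the erfc
forms only through this comparison namespace.

The half-erfc model's practical signature is an extreme sensitivity of Q
to CSF flow time: since z ~ 1/sqrt(t) at fixed position and D, the
flow-time multiplier between two quotients is (z_from/z_to)^2, so a mere
doubling of flow time drives a tenfold quotient increase in the normal
range (e.g. Q_Alb 0.002 -> 0.02), where the saturation model predicts the
physiologically plausible doubling.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "mf_q_constant_boundary",
    "mf_q_reiber",
    "mf_inverse",
    "mf_flow_time_factor",
]


def _check_nonneg(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0 (CSF side of the boundary, x > 0)")
    return z


def mf_q_constant_boundary(z):
    """Q = erfc(z), the solution with concentration held at c0 at x = 0."""
    zz = _check_nonneg(z)
    out = special.erfc(zz)
    return float(out) if out.ndim == 0 else out


def mf_q_reiber(z):
    """Q = 0.5*erfc(z): the half-erfc variant.

    Its boundary value Q(0) = 0.5 for all t > 0 is the pathology that
    disqualifies it as a model of blood-CSF exchange.
    """
    zz = _check_nonneg(z)
    out = 0.5 * special.erfc(zz)
    return float(out) if out.ndim == 0 else out


def mf_inverse(q):
    """Argument z with 0.5*erfc(z) = q, for q in (0, 0.5]."""
    qq = np.asarray(q, dtype=float)
    if np.any((qq <= 0) | (qq > 0.5)):
        raise ValueError("q must be in (0, 0.5] for the half-erfc model")
    out = special.erfcinv(2.0 * qq)
    return float(out) if out.ndim == 0 else out


def mf_flow_time_factor(q_from: float, q_to: float) -> float:
    """Flow-time multiplier taking Q from q_from to q_to under half-erfc.

    At fixed position and diffusion coefficient z ~ 1/sqrt(t), so
    t_to/t_from = (z_from/z_to)^2.
    """
    z_from = mf_inverse(q_from)
    z_to = mf_inverse(q_to)
    if z_to == 0:
        raise ValueError("q_to = 0.5 corresponds to infinite flow time factor")
    return (z_from / z_to) ** 2
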