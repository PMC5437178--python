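"""Fitting exchange-coefficient ratios to the empirical quotient curves.

The empirical relation between an immunoglobulin quotient and the albumin
quotient is the mean hyperbolic curve of the reference population.  Under
the connected steady-state model both quotients follow the saturation law
with the same composite rate k/L but molecule-specific exchange
coefficients, so with anchors aleph_Alb = 2 and k/L = 1 (arbitrary, since
only the ratio is identified) the theoretical curve

    Q_IgX(t) = 1 - exp(-aleph_Alb * (k/L) * t * r),   r = aleph_IgX/aleph_Alb

is fitted to the empirical Q_IgX(Q_Alb(t)) by least squares on the
quotient scale over a flow-time grid mapping Q_Alb onto the calibrated
window.  The fitted ratio converts directly into the quotient
aleph_Alb/aleph_IgX used in the hydrodynamic-radius and barrier-factor
algebra.

The analogous fit for the rival half-erfc model scales the erfc argument
by sqrt(D_Alb/D_IgX): for each grid Q_Alb the argument z is obtained by
inverting Q_Alb = 0.5*erfc(z), the empirical Q_IgX is inverted the same
way, and the argument-scaling factor is fitted by least squares in
argument space, where the model is exactly linear (z_x = sqrt(s) * z_alb).
Argument-space residuals weight the whole window evenly; residuals on the
quotient scale are dominated by the far upper end of the window and pull
the fitted ratio far from what the curves show over the physiological
range.  The squared scaling factor is the diffusion-coefficient ratio
s = D_Alb/D_IgX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .molecular_flux import mf_inverse, mf_q_reiber
from .reibergram import HyperbolicParams, ReibergramFamily, hyperbolic_q

__all__ = ["FitConfig", "FitResult", "ssm_target_curve", "fit_aleph_ratio", "fit_mf_d_ratio"]


@dataclass(frozen=True)
class FitConfig:
    """Anchors, evaluation window and grid for the ratio fits.

    aleph_ref and k_over_l are arbitrary anchors (only ratios are
    identified); the default window is the calibrated Q_Alb range of the
    quotient diagrams.  The grid is log-spaced in flow time.
    """

    aleph_ref: float = 2.0
    k_over_l: float = 1.0
    q_alb_window: tuple[float, float] = (2e-3, 0.15)
    n_grid: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.q_alb_window
        if not (0 < lo < hi < 1):
            raise ValueError(f"q_alb_window must lie within (0, 1), got {self.q_alb_window}")
        if self.n_grid < 10:
            raise ValueError("n_grid must be >= 10")
        if self.aleph_ref <= 0 or self.k_over_l <= 0:
            raise ValueError("anchors must be > 0")

    def t_grid(self) -> np.ndarray:
        """Log-spaced flow-time grid whose Q_Alb images span the window."""
        rate = self.aleph_ref * self.k_over_l
        lo, hi = self.q_alb_window
        t_lo = -np.log1p(-lo) / rate
        t_hi = -np.log1p(-hi) / rate
        return np.geomspace(t_lo, t_hi, self.n_grid)


@dataclass(frozen=True)
class FitResult:
    """Fitted ratio with residual diagnostics.

    ratio: aleph_x/aleph_ref for the steady-state fit, D_ref/D_x for the
    erfc fit.  quotient: the reference-over-x form (1/ratio for the
    steady-state fit, ratio itself for the erfc fit).
    """

    analyte: str
    model: str
    ratio: float
    quotient: float
    aleph_x: Optional[float]
    residual_rms: float
    window_used: tuple[float, float]
    diagnostics: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("fitted ratio must be > 0")

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "model": self.model,
            "ratio": self.ratio,
            "quotient": self.quotient,
            "aleph_x": self.aleph_x,
            "residual_rms": self.residual_rms,
            "window_used": list(self.window_used),
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


class FitConvergenceError(RuntimeError):
    """Raised when the least-squares fit does not converge."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


def ssm_target_curve(
    family_mean: HyperbolicParams, cfg: FitConfig, t: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (Q_Alb(t), Q_IgX(Q_Alb(t))) pairs on the flow-time grid."""
    if t is None:
        t = cfg.t_grid()
    q_alb = -np.expm1(-cfg.aleph_ref * cfg.k_over_l * np.asarray(t))
    lo, hi = cfg.q_alb_window
    if q_alb.size == 0 or q_alb.min() > hi or q_alb.max() < lo:
        raise ValueError("flow-time grid does not map into the Q_Alb window")
    return q_alb, hyperbolic_q(q_alb, family_mean)


def _run_scalar_ls(residual_fn, x0: float, label: str) -> tuple[float, np.ndarray]:
    sol = optimize.least_squares(
        residual_fn, x0=[x0], bounds=([1e-9], [np.inf]), xtol=1e-14, ftol=1e-14
    )
    if not sol.success:
        raise FitConvergenceError(f"{label}: {sol.message}", residuals=sol.fun)
    return float(sol.x[0]), sol.fun


def fit_aleph_ratio(family: ReibergramFamily, cfg: FitConfig = FitConfig()) -> FitResult:
    """Least-squares fit of r = aleph_IgX/aleph_Alb to the mean curve.

    Returns the fitted r, the derived aleph_IgX = r*aleph_ref and the
    quotient aleph_ref/aleph_IgX.  Diagnostics carry the Q_Alb grid and
    per-point residuals; the ratio is invariant to joint rescaling of the
    anchors.
    """
    t = cfg.t_grid()
    q_alb, q_emp = ssm_target_curve(family.mean, cfg, t)

    def residual(x):
        r = x[0]
        return -np.expm1(-cfg.aleph_ref * cfg.k_over_l * t * r) - q_emp

    r, res = _run_scalar_ls(residual, 0.5, f"steady-state fit {family.analyte}")
    rms = float(np.sqrt(np.mean(res**2)))
    return FitResult(
        analyte=family.analyte,
        model="steady_state",
        ratio=r,
        quotient=1.0 / r,
        aleph_x=r * cfg.aleph_ref,
        residual_rms=rms,
        window_used=cfg.q_alb_window,
        diagnostics={"q_alb": q_alb, "residuals": res, "q_empirical": q_emp},
    )


def fit_mf_d_ratio(family: ReibergramFamily, cfg: FitConfig = FitConfig()) -> FitResult:
    """Least-squares fit of s = D_Alb/D_IgX under the half-erfc model.

    Both the reference and the empirical immunoglobulin quotients are
    inverted through the half-erfc, and the argument-scaling factor a
    with z_x = a * z_alb is the exact linear least-squares solution; the
    reported ratio is s = a**2.  The window must keep Q_Alb below 0.5
    (the half-erfc model cannot represent larger quotients at all).
    """
    if cfg.q_alb_window[1] >= 0.5:
        raise ValueError("half-erfc model requires Q_Alb window below 0.5")
    t = cfg.t_grid()
    q_alb, q_emp = ssm_target_curve(family.mean, cfg, t)
    z = mf_inverse(q_alb)
    z_emp = mf_inverse(q_emp)
    a = float(np.dot(z_emp, z) / np.dot(z, z))
    s = a * a
    res = z_emp - a * z
    rms = float(np.sqrt(np.mean(res**2)))
    q_res = mf_q_reiber(z * a) - q_emp
    return FitResult(
        analyte=family.analyte,
        model="molecular_flux",
        ratio=s,
        quotient=s,
        aleph_x=None,
        residual_rms=rms,
        window_used=cfg.q_alb_window,
        diagnostics={
            "q_alb": q_alb,
            "residuals": res,
            "q_residuals": q_res,
            "q_empirical": q_emp,
        },
    )
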