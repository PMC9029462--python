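"""Flow-curve characterisation of film-forming polymer stock solutions.

The stock solutions were profiled by rotational rheometry over 30 shear
rates ascending logarithmically from 0.01 to 100 1/s. The CMC solutions
shear-thin across the whole range; the PVA solutions shear-thin mildly and
plateau. Two constitutive models cover both behaviours:

* power law: eta = K * gamma_dot**(n - 1), fitted as a straight line in
  log-log space (slope n - 1, intercept log K);
* Cross: eta = eta_inf + (eta0 - eta_inf) / (1 + (lambda * gamma_dot)**m),
  fitted by nonlinear least squares with data-driven initialisation.

A solution is classified shear-thinning when n < 1 - tol (power law) or
when the fitted Cross plateaus separate by more than the same tolerance.
``viscosity_at`` interpolates a measured curve at a physiological shear
rate (e.g. 50 1/s, the pharyngeal swallowing regime) in log-log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FlowCurve",
    "RheoFit",
    "RheoFitError",
    "SHEAR_THINNING_TOL",
    "fit_power_law",
    "fit_cross",
    "viscosity_at",
]

#: Tolerance on the flow index n used to call a fluid shear-thinning.
SHEAR_THINNING_TOL = 0.02


class RheoFitError(RuntimeError):
    """Raised when a nonlinear flow-curve fit fails to converge."""


@dataclass
class FlowCurve:
    """Shear-rate / viscosity pairs, shear rates strictly ascending."""

    shear_rate_1_per_s: np.ndarray
    viscosity_Pa_s: np.ndarray

    def __post_init__(self) -> None:
        self.shear_rate_1_per_s = np.asarray(self.shear_rate_1_per_s, dtype=float)
        self.viscosity_Pa_s = np.asarray(self.viscosity_Pa_s, dtype=float)
        if self.shear_rate_1_per_s.shape != self.viscosity_Pa_s.shape:
            raise ValueError("shear rate and viscosity must have equal length")
        if np.any(self.shear_rate_1_per_s <= 0) or np.any(self.viscosity_Pa_s <= 0):
            raise ValueError("shear rates and viscosities must be positive")
        if self.shear_rate_1_per_s.size >= 2 and not np.all(
            np.diff(self.shear_rate_1_per_s) > 0
        ):
            raise ValueError("shear rates must be strictly ascending")

    def __len__(self) -> int:
        return self.shear_rate_1_per_s.size


@dataclass(frozen=True)
class RheoFit:
    """Fitted constitutive model for one flow curve."""

    model: str  # "power_law" | "cross"
    params: dict
    r2_loglog: float
    shear_thinning: bool
    degenerate: bool = False
    residual_ss: float = 0.0
    message: str = ""
    predicted: Optional[np.ndarray] = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "r2_loglog": self.r2_loglog,
            "shear_thinning": self.shear_thinning,
            "degenerate": self.degenerate,
            "residual_ss": self.residual_ss,
        }


def _r2_loglog(eta: np.ndarray, eta_hat: np.ndarray) -> float:
    y, yh = np.log(eta), np.log(np.clip(eta_hat, 1e-300, None))
    ss_res = float(np.sum((y - yh) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_power_law(curve: FlowCurve) -> RheoFit:
    """Ordinary least squares in log-log space: slope n - 1, intercept log K."""
    if len(curve) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    x = np.log(curve.shear_rate_1_per_s)
    y = np.log(curve.viscosity_Pa_s)
    slope, intercept = np.polyfit(x, y, 1)
    n_idx = float(slope + 1.0)
    K = float(np.exp(intercept))
    eta_hat = K * curve.shear_rate_1_per_s ** (n_idx - 1.0)
    return RheoFit(
        model="power_law",
        params={"K": K, "n": n_idx},
        r2_loglog=_r2_loglog(curve.viscosity_Pa_s, eta_hat),
        shear_thinning=n_idx < 1.0 - SHEAR_THINNING_TOL,
        residual_ss=float(np.sum((curve.viscosity_Pa_s - eta_hat) ** 2)),
        predicted=eta_hat,
    )


def _cross(gd, eta0, eta_inf, lam, m):
    return eta_inf + (eta0 - eta_inf) / (1.0 + (lam * gd) ** m)


def fit_cross(curve: FlowCurve, init: Optional[dict] = None) -> RheoFit:
    """Nonlinear least-squares Cross-model fit.

    Initialised from the data extremes: eta0 from the lowest-shear point,
    eta_inf from the highest-shear point, lambda from the reciprocal shear
    rate at mid-decay, m = 1. Near-Newtonian data (plateaus within the
    shear-thinning tolerance) are flagged degenerate rather than fitted;
    genuine non-convergence raises :class:`RheoFitError` with the residual.
    """
    if len(curve) < 5:
        raise ValueError("Cross fit needs at least 5 points")
    gd, eta = curve.shear_rate_1_per_s, curve.viscosity_Pa_s
    eta0_0 = float(eta[0])
    etai_0 = float(eta[-1])
    if init:
        eta0_0 = float(init.get("eta0", eta0_0))
        etai_0 = float(init.get("eta_inf", etai_0))

    span = eta0_0 - etai_0
    if span <= SHEAR_THINNING_TOL * eta0_0:
        mean_eta = float(np.mean(eta))
        eta_hat = np.full_like(eta, mean_eta)
        return RheoFit(
            model="cross",
            params={"eta0": mean_eta, "eta_inf": mean_eta, "lam": np.nan, "m": np.nan},
            r2_loglog=_r2_loglog(eta, eta_hat),
            shear_thinning=False,
            degenerate=True,
            residual_ss=float(np.sum((eta - eta_hat) ** 2)),
            message="near-Newtonian data: eta0 ~ eta_inf, lambda/m unidentifiable",
            predicted=eta_hat,
        )

    mid = etai_0 + 0.5 * span
    lam0 = 1.0 / float(gd[np.argmin(np.abs(eta - mid))])
    p0 = [eta0_0, max(etai_0, 1e-9), max(lam0, 1e-6), 1.0]
    if init:
        p0[2] = float(init.get("lam", p0[2]))
        p0[3] = float(init.get("m", p0[3]))
    def _log_cross(gd_, eta0_, eta_inf_, lam_, m_):
        # residuals in log space: measurement noise is multiplicative
        return np.log(np.clip(_cross(gd_, eta0_, eta_inf_, lam_, m_), 1e-300, None))

    try:
        popt, _ = curve_fit(
            _log_cross,
            gd,
            np.log(eta),
            p0=p0,
            bounds=([1e-12, 1e-12, 1e-9, 0.05], [np.inf] * 4),
            maxfev=20000,
        )
    except RuntimeError as exc:
        eta_hat = _cross(gd, *p0)
        raise RheoFitError(
            f"Cross fit did not converge: {exc}; "
            f"initial residual SS = {float(np.sum((eta - eta_hat) ** 2)):.4g}"
        ) from exc
    eta0, eta_inf, lam, m = (float(v) for v in popt)
    eta_hat = _cross(gd, eta0, eta_inf, lam, m)
    degenerate = (eta0 - eta_inf) <= SHEAR_THINNING_TOL * eta0
    return RheoFit(
        model="cross",
        params={"eta0": eta0, "eta_inf": eta_inf, "lam": lam, "m": m},
        r2_loglog=_r2_loglog(eta, eta_hat),
        shear_thinning=(not degenerate) and eta0 > eta_inf,
        degenerate=degenerate,
        residual_ss=float(np.sum((eta - eta_hat) ** 2)),
        message="converged",
        predicted=eta_hat,
    )


def viscosity_at(curve: FlowCurve, gamma_dot: float) -> float:
    """Viscosity at ``gamma_dot`` by log-log interpolation (no extrapolation)."""
    gd = curve.shear_rate_1_per_s
    if not gd[0] <= gamma_dot <= gd[-1]:
        raise ValueError(
            f"shear rate {gamma_dot} outside measured range [{gd[0]}, {gd[-1]}]"
        )
    return float(
        np.exp(np.interp(np.log(gamma_dot), np.log(gd), np.log(curve.viscosity_Pa_s)))
    )
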