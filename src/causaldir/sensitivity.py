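"""Measurement-error sensitivity analysis for causal-direction inference.

Non-differential measurement error attenuates the correlation between an
instrument and a trait: if x_o is the observed value of a true trait x,
then rho_g,xo = rho_g,x * rho_x,xo.  Differential error between the two
traits can therefore flip which observed correlation is larger and lead
the Steiger comparison astray.  This module provides the analytic results
quantifying that fallibility:

* the attenuation factor D and the residual instrument-outcome covariance
  that survives adjusting for a mismeasured exposure (the failure mode of
  mediation-based tests);
* the d statistic d = rho_x,xo - rho_xy * rho_y,yo whose sign delimits
  where the direction call is reliable;
* a reliability ratio R obtained by integrating the direction the test
  *would* take over every admissible measurement-error value, treating all
  admissible values as equally likely.

Admissible region: attenuation cannot push a corrected correlation above 1,
so rho_x,xo ranges from the observed instrument correlation rho_g,xo up to
1 (and likewise for y).  Over an inclusive uniform grid on that rectangle
the predicted difference in variance explained,
z = (rho_g,yo / rho_y,yo)^2 - (rho_g,xo / rho_x,xo)^2, is accumulated
separately where its sign supports and where it opposes the empirically
inferred direction; R is the ratio of the two volumes.  R = 1 means the
call is maximally sensitive to measurement error; large R means most
admissible measurement-error values leave the call unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "MeasurementErrorPoint",
    "SensitivityResult",
    "attenuation_D",
    "residual_cov_bias",
    "d_statistic",
    "predicted_surface",
    "reliability_R",
]


@dataclass(frozen=True)
class MeasurementErrorPoint:
    """A hypothesised pair of true-vs-observed trait correlations."""

    rho_xxo: float
    rho_yyo: float

    def __post_init__(self) -> None:
        for name in ("rho_xxo", "rho_yyo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SensitivityResult:
    """Reliability ratio and the two integrated volumes behind it."""

    R: float
    vol_support: float
    vol_oppose: float
    grid_resolution: int
    direction: str
    infinite: bool = False


def attenuation_D(beta_mx: float, var_x: float, var_eps_mx: float) -> float:
    """Fraction of observed-exposure variance carried by the scaled true value.

    D = beta_mx^2 var(x) / (beta_mx^2 var(x) + var(eps_mx)); D = 1 iff the
    measurement is noise-free (scale changes alone do not attenuate).
    """
    if var_x <= 0:
        raise DomainError(f"var_x must be > 0, got {var_x!r}")
    if var_eps_mx < 0:
        raise DomainError(f"var_eps_mx must be >= 0, got {var_eps_mx!r}")
    if beta_mx == 0:
        raise DomainError("beta_mx must be non-zero")
    signal = beta_mx * beta_mx * var_x
    return signal / (signal + var_eps_mx)


def residual_cov_bias(
    beta_g: float, beta_x: float, beta_my: float, var_g: float, D: float
) -> float:
    """Residual cov(g, y_o - y_hat_o) left after adjusting for a noisy exposure.

    Equals beta_my * beta_g * beta_x * var(g) * (1 - D): zero only when the
    exposure is measured without imprecision (D = 1) or some link in the
    chain is absent.  This is the quantity whose non-zero value violates
    the mediation condition of the CIT.
    """
    if var_g <= 0:
        raise DomainError(f"var_g must be > 0, got {var_g!r}")
    return beta_my * beta_g * beta_x * var_g * (1.0 - D)


def d_statistic(rho_xxo: float, rho_xy: float, rho_yyo: float) -> float:
    """d = rho_x,xo - rho_xy * rho_y,yo.

    d > 0 marks the region of measurement-error values where the Steiger
    comparison of observed correlations recovers the true direction; with a
    perfectly measured exposure (rho_xxo = 1) d is never negative.
    """
    for name, v in (("rho_xxo", rho_xxo), ("rho_yyo", rho_yyo)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {v!r}")
    if not -1.0 <= rho_xy <= 1.0:
        raise DomainError(f"rho_xy must lie in [-1, 1], got {rho_xy!r}")
    return rho_xxo - rho_xy * rho_yyo


def predicted_surface(
    r_gx_obs: float, r_gy_obs: float, point: MeasurementErrorPoint
) -> float:
    """Predicted rho_gy - rho_gx after undoing a hypothesised measurement error.

    Each observed instrument correlation is divided by its hypothesised
    true-vs-observed correlation.  A positive value means that this much
    measurement error would make the instrument *more* correlated with y
    than with x, i.e. would favour the y -> x direction.
    """
    _check_observed(r_gx_obs, r_gy_obs)
    if point.rho_xxo < r_gx_obs or point.rho_yyo < r_gy_obs:
        raise DomainError(
            "hypothesised measurement error exceeds the admissible bound: "
            "a corrected correlation would be larger than 1"
        )
    if point.rho_xxo == 0 or point.rho_yyo == 0:
        raise DomainError("rho_xxo and rho_yyo must be positive")
    return r_gy_obs / point.rho_yyo - r_gx_obs / point.rho_xxo


def _check_observed(r_gx_obs: float, r_gy_obs: float) -> None:
    for name, v in (("r_gx_obs", r_gx_obs), ("r_gy_obs", r_gy_obs)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must lie in (0, 1), got {v!r}")


def reliability_R(
    r_gx_obs: float,
    r_gy_obs: float,
    grid_resolution: int = 500,
    prior: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> SensitivityResult:
    """Reliability ratio of the inferred direction under measurement error.

    The admissible rectangle [r_gx_obs, 1] x [r_gy_obs, 1] of true-vs-
    observed correlations is covered by an inclusive uniform grid with
    ``grid_resolution`` points per axis.  At each point the difference in
    corrected variance explained,

        z = (r_gy_obs / rho_yyo)^2 - (r_gx_obs / rho_xxo)^2,

    is evaluated; |z| is accumulated into the volume favouring x -> y
    (z < 0) and the volume favouring y -> x (z > 0).

    R is reported in the fixed x -> y orientation,
    R = vol(favour x->y) / vol(favour y->x), so that swapping the two
    observed correlations yields the reciprocal ratio.  Callers normally
    pass the Steiger-inferred exposure as x, in which case R equals
    vol_support / vol_oppose (those two fields are always relative to the
    empirically inferred direction).

    ``prior`` optionally weights grid points (called with the rho_xxo and
    rho_yyo meshes); the default is the uniform weighting, i.e. every
    admissible measurement-error value equally likely.  A zero opposing
    volume is reported as R = +inf with ``infinite=True`` rather than an
    error.
    """
    _check_observed(r_gx_obs, r_gy_obs)
    if grid_resolution < 2:
        raise DomainError("grid_resolution must be >= 2")
    u = np.linspace(r_gx_obs, 1.0, grid_resolution)
    v = np.linspace(r_gy_obs, 1.0, grid_resolution)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    z = (r_gy_obs / vv) ** 2 - (r_gx_obs / uu) ** 2
    w = np.ones_like(z) if prior is None else np.asarray(prior(uu, vv), dtype=float)
    if w.shape != z.shape or np.any(w < 0):
        raise ValidationError("prior must return non-negative weights on the grid")
    vol_pos = float(np.sum(w * np.where(z > 0, z, 0.0)))  # favours y -> x
    vol_neg = float(np.sum(w * np.where(z < 0, -z, 0.0)))  # favours x -> y
    cell = ((1.0 - r_gx_obs) / (grid_resolution - 1)) * (
        (1.0 - r_gy_obs) / (grid_resolution - 1)
    )
    vol_pos *= cell
    vol_neg *= cell
    if r_gx_obs >= r_gy_obs:
        direction, vol_support, vol_oppose = "x_causes_y", vol_neg, vol_pos
    else:
        direction, vol_support, vol_oppose = "y_causes_x", vol_pos, vol_neg
    if vol_pos == 0.0 or vol_oppose == 0.0:
        return SensitivityResult(
            R=math.inf if vol_pos == 0.0 else 0.0,
            vol_support=vol_support,
            vol_oppose=vol_oppose,
            grid_resolution=grid_resolution,
            direction=direction,
            infinite=True,
        )
    return SensitivityResult(
        R=vol_neg / vol_pos,
        vol_support=vol_support,
        vol_oppose=vol_oppose,
        grid_resolution=grid_resolution,
        direction=direction,
    )
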