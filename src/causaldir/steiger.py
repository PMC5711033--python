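"""Steiger tests for comparing instrument-trait correlations.

A SNP that is a valid instrument for an exposure ``x`` which causes an
outcome ``y`` must, under the causal chain g -> x -> y, be more strongly
correlated with x than with y (|rho_gx| > |rho_gy| since
rho_gy = rho_gx * rho_xy).  Testing which of the two correlations is larger
therefore orients the causal direction.  Two variants are provided:

* one-sample: both traits and the SNP measured in the same individuals;
  Steiger's (1980) Z-test for correlated correlations sharing one variable.
* two-sample: the two instrument-trait correlations estimated in
  independent cohorts (the usual GWAS summary-data setting); the classic
  Fisher-z test of two independent correlations, which tolerates unequal
  sample sizes.

Correlations enter the comparison as absolute values; the sign of the
resulting Z carries the direction (Z > 0 favours x -> y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, DomainError, ValidationError
from .summary_io import ObservedCorrelations

__all__ = [
    "SteigerResult",
    "DirectionCall",
    "fisher_z",
    "steiger_one_sample",
    "steiger_two_sample",
    "aggregate_instruments",
    "infer_direction",
]

Direction = Literal["x_causes_y", "y_causes_x", "undetermined"]


@dataclass(frozen=True)
class SteigerResult:
    """Outcome of a correlation-difference test.

    ``direction`` is ``x_causes_y`` iff ``z_stat > 0``, ``y_causes_x`` iff
    ``z_stat < 0`` and ``undetermined`` iff ``z_stat == 0`` (no tie-break).
    """

    z_stat: float
    p_steiger: float
    direction: Direction
    r_gx: float
    r_gy: float
    mode: Literal["one_sample", "two_sample"]


@dataclass(frozen=True)
class DirectionCall:
    """Combined MR + Steiger decision at significance level ``alpha``."""

    outcome: Literal["x_causes_y", "y_causes_x", "no_call"]
    p_mr: float
    steiger: SteigerResult
    alpha: float


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    if not -1.0 < r < 1.0:
        raise DomainError(f"fisher_z requires |r| < 1, got {r!r}")
    return float(np.arctanh(r))


def _direction_from_z(z: float) -> Direction:
    if z > 0:
        return "x_causes_y"
    if z < 0:
        return "y_causes_x"
    return "undetermined"


def steiger_one_sample(obs: ObservedCorrelations) -> SteigerResult:
    """Steiger's Z-test for two correlations sharing the instrument g.

    Implements the correlated-correlations statistic

        Z = (z_gx - z_gy) * sqrt((N - 3) / (2 (1 - rho_xy) h))

    with r_m^2 = (rho_gx^2 + rho_gy^2)/2,
    f = (1 - rho_xy) / (2 (1 - r_m^2)) and h = (1 - f r_m^2) / (1 - r_m^2),
    the formulation used by the classic ``r.test`` routine.  The two
    instrument-trait correlations are compared in absolute value; rho_xy
    keeps its sign.
    """
    if obs.mode != "one_sample":
        raise ValidationError("steiger_one_sample requires one-sample correlations")
    if obs.r_xy is None:
        raise ValidationError("one-sample Steiger test requires r_xy")
    if abs(obs.r_xy) >= 1.0:
        raise DegenerateInputError("|r_xy| = 1 leaves the h term undefined")
    n = obs.n
    assert n is not None
    r_gx = abs(obs.r_gx)
    r_gy = abs(obs.r_gy)
    r_xy = obs.r_xy
    z_gx = fisher_z(r_gx)
    z_gy = fisher_z(r_gy)
    rm2 = (r_gx * r_gx + r_gy * r_gy) / 2.0
    f = (1.0 - r_xy) / (2.0 * (1.0 - rm2))
    h = (1.0 - f * rm2) / (1.0 - rm2)
    if h <= 0.0:
        raise DegenerateInputError(
            "correlation triple does not form a positive-definite matrix; "
            "the correlated-correlations variance term is undefined"
        )
    z = (z_gx - z_gy) * math.sqrt((n - 3) / (2.0 * (1.0 - r_xy) * h))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        z_stat=z,
        p_steiger=max(p, np.finfo(float).tiny),
        direction=_direction_from_z(z),
        r_gx=r_gx,
        r_gy=r_gy,
        mode="one_sample",
    )


def steiger_two_sample(obs: ObservedCorrelations) -> SteigerResult:
    """Fisher-z test of two independent correlations (two-sample setting).

        Z = (z_gx - z_gy) / sqrt(1/(N1 - 3) + 1/(N2 - 3))

    No trait-trait correlation is needed and N1 may differ from N2.
    """
    if obs.mode != "two_sample":
        raise ValidationError("steiger_two_sample requires two-sample correlations")
    n1, n2 = obs.n1, obs.n2
    assert n1 is not None and n2 is not None
    if n1 <= 3 or n2 <= 3:
        raise DomainError("two-sample Steiger test requires N1, N2 >= 4")
    r_gx = abs(obs.r_gx)
    r_gy = abs(obs.r_gy)
    z = (fisher_z(r_gx) - fisher_z(r_gy)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        z_stat=z,
        p_steiger=max(p, np.finfo(float).tiny),
        direction=_direction_from_z(z),
        r_gx=r_gx,
        r_gy=r_gy,
        mode="two_sample",
    )


def aggregate_instruments(r_values: Sequence[float]) -> float:
    """Combine per-SNP correlation magnitudes of independent instruments.

    Under independence the variances explained add, so the combined
    correlation is sqrt(sum r_i^2).  Raises if the instruments would
    jointly explain more than 100% of the variance.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise ValidationError("need at least one instrument correlation")
    if np.any(np.abs(r) > 1.0):
        raise ValidationError("each |r| must be <= 1")
    total = float(np.sum(r * r))
    if total > 1.0 + 1e-12:
        raise ValidationError(
            f"independent instruments cannot jointly explain > 100% of variance "
            f"(sum r^2 = {total:.6g})"
        )
    return math.sqrt(min(total, 1.0))


def infer_direction(
    p_mr: float, steiger: SteigerResult, alpha: float = 0.05
) -> DirectionCall:
    """Combine the MR causal test and the Steiger direction test.

    A directional call requires both p_MR < alpha and p_Steiger < alpha;
    the direction is then taken from the sign of the Steiger Z.  Otherwise
    no model is accepted.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha!r}")
    if (
        steiger.p_steiger < alpha
        and p_mr < alpha
        and steiger.direction != "undetermined"
    ):
        outcome = steiger.direction
    else:
        outcome = "no_call"
    return DirectionCall(outcome=outcome, p_mr=p_mr, steiger=steiger, alpha=alpha)
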