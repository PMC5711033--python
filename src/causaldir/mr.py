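"""Mendelian-randomisation effect estimation with a single instrument.

Two estimators of the causal effect of an exposure on an outcome are
provided: the Wald ratio for summary data and two-stage least squares
(2SLS) for individual-level data.  With one instrument the two coincide:
the just-identified IV estimate equals the ratio of the marginal
regression slopes, cov(g, y) / cov(g, x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError
from .summary_io import SummaryAssociation, harmonise

__all__ = ["MRResult", "wald_ratio", "tsls", "mr_pvalue_symmetry_check"]


@dataclass(frozen=True)
class MRResult:
    """A causal-effect estimate (outcome units per exposure unit)."""

    beta_mr: float
    se_mr: float
    p_mr: float
    method: Literal["wald_ratio", "tsls"]
    direction_tested: str = "x->y"


def wald_ratio(
    exposure: SummaryAssociation, outcome: SummaryAssociation
) -> MRResult:
    """Wald ratio estimate beta_out / beta_exp from harmonised summary stats.

    The standard error uses the first-order delta method se_out / |beta_exp|
    and the p-value the normal approximation, the usual summary-data
    convention for large GWAS samples.
    """
    exposure, outcome = harmonise(exposure, outcome)
    if exposure.beta is None or outcome.beta is None or outcome.se is None:
        raise ValidationError("wald_ratio needs beta for both records and se for the outcome")
    if exposure.beta == 0:
        raise DegenerateInputError("exposure effect is zero: instrument is degenerate")
    beta = outcome.beta / exposure.beta
    se = outcome.se / abs(exposure.beta)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MRResult(
        beta_mr=beta,
        se_mr=se,
        p_mr=max(p, np.finfo(float).tiny),
        method="wald_ratio",
        direction_tested=f"{exposure.trait_id}->{outcome.trait_id}",
    )


def tsls(g: np.ndarray, x: np.ndarray, y: np.ndarray) -> MRResult:
    """Two-stage least squares with a single instrument (with intercept).

    Stage 1 regresses x on g; stage 2 regresses y on the fitted exposure.
    The standard error is the IV sandwich form, with residuals computed
    against the *observed* exposure:

        var(b) = sigma^2 * S_gg / S_gx^2,   sigma^2 = RSS / (n - 2)

    where S are centred sums of squares/products.  The point estimate is
    exactly cov(g, y) / cov(g, x).
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (g.shape == x.shape == y.shape) or g.ndim != 1:
        raise ValidationError("g, x, y must be 1-d arrays of equal length")
    n = g.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    gc = g - g.mean()
    xc = x - x.mean()
    yc = y - y.mean()
    s_gg = float(gc @ gc)
    if s_gg == 0.0:
        raise DegenerateInputError("instrument has zero variance")
    s_gx = float(gc @ xc)
    if s_gx == 0.0:
        raise DegenerateInputError("zero first-stage slope: instrument is degenerate")
    s_gy = float(gc @ yc)
    beta = s_gy / s_gx
    resid = yc - beta * xc
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    se = math.sqrt(sigma2 * s_gg) / abs(s_gx)
    if se == 0.0:
        p = float(np.finfo(float).tiny) if beta != 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(beta) / se, n - 2))
    return MRResult(
        beta_mr=beta,
        se_mr=se,
        p_mr=max(p, np.finfo(float).tiny),
        method="tsls",
    )


def mr_pvalue_symmetry_check(
    g: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """p_MR for both orientations of the same instrumented pair.

    With a shared instrument the MR test p-value is essentially unchanged
    when the roles of exposure and outcome are (possibly erroneously)
    swapped; this helper returns both values so callers and tests can
    assert the near-equality.
    """
    forward = tsls(g, x, y)
    reverse = tsls(g, y, x)
    return forward.p_mr, reverse.p_mr
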