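"""Shared fixtures and simulation helpers for the test suite."""

import numpy as np
import pytest
from scipy import stats

import causaldir as cd


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def causal_dataset(n, var_xy=0.2, sigma2_mx=0.0, sigma2_my=0.0, var_gx=0.1, seed=0):
    cfg = cd.SimulationConfig(
        n=n, var_gx=var_gx, var_xy=var_xy, sigma2_mx=sigma2_mx, sigma2_my=sigma2_my
    )
    return cd.simulate_causal(cfg, np.random.default_rng(seed))


def two_sample_direction_call(cfg, seed, alpha=0.05):
    """End-to-end two-sample pipeline on in-memory cohorts.

    Simulates two independent cohorts, computes marginal associations,
    recovers correlations from (p, n), and combines the Wald ratio with the
    two-sample Steiger test into a direction call.
    """
    rng = np.random.default_rng(seed)
    cohort1 = cd.simulate(cfg, rng)
    cohort2 = cd.simulate(cfg, rng)
    tiny = np.finfo(float).tiny
    f1 = stats.linregress(cohort1.g, cohort1.x_o)
    f2 = stats.linregress(cohort2.g, cohort2.y_o)
    exp = cd.SummaryAssociation(
        "exposure", "rs1", max(float(f1.pvalue), tiny), cfg.n,
        beta=float(f1.slope), se=float(f1.stderr),
    )
    out = cd.SummaryAssociation(
        "outcome", "rs1", max(float(f2.pvalue), tiny), cfg.n,
        beta=float(f2.slope), se=float(f2.stderr),
    )
    obs = cd.ObservedCorrelations(
        r_gx=cd.r_from_pn(exp.pval, exp.n),
        r_gy=cd.r_from_pn(out.pval, out.n),
        n1=exp.n,
        n2=out.n,
    )
    steiger = cd.steiger_two_sample(obs)
    mr = cd.wald_ratio(exp, out)
    return cd.infer_direction(mr.p_mr, steiger, alpha)
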