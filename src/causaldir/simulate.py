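"""Generative models for benchmarking causal-direction inference.

Two data-generating processes are provided, matching the evaluation set-up
for the direction tests in this package:

* ``causal``:   g -> x -> y, with the instrument g drawn Binomial(2, maf)
  and the traits standardised so the configured variances explained,
  cor(g,x)^2 and cor(x,y)^2, hold exactly in the population;
* ``noncausal``: g -> x and g -> y through separate paths, so the traits
  are correlated but *not* causally related (genetic confounding); the
  population partial correlation of x and y given g is zero.

Non-differential measurement error is applied to each trait as
``t_o = alpha_m + beta_m * t + N(0, sigma2_m)``: a scale component
(alpha, beta) and an imprecision component (sigma2).  Residual variances
are solved in closed form on unit-variance traits, so population
quantities such as the d statistic are exact functions of the
configuration.

The module doubles as the fixture generator for the summary-statistics
pipeline: ``make_fixture_summary_tables`` simulates two independent
cohorts and writes per-trait association tables with a sidecar manifest
recording the true direction.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cit import cit_bidirectional
from .exceptions import ConfigurationError, DomainError
from .mr import tsls
from .steiger import infer_direction, steiger_one_sample
from .summary_io import (
    SummaryAssociation,
    correlations_from_individual,
    write_summary_table,
)

__all__ = [
    "SimulationConfig",
    "SimulationDataset",
    "simulate_causal",
    "simulate_noncausal",
    "simulate",
    "population_d",
    "default_grid",
    "run_grid",
    "make_fixture_summary_tables",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``var_gx`` and ``var_xy`` are the target population cor(g,x)^2 and
    cor(x,y)^2; ``sigma2_mx``/``sigma2_my`` the measurement-imprecision
    variances; ``alpha_m*``/``beta_m*`` the scale-error intercepts/slopes.
    """

    n: int = 1000
    var_gx: float = 0.1
    var_xy: float = 0.2
    sigma2_mx: float = 0.0
    sigma2_my: float = 0.0
    alpha_mx: float = 0.0
    beta_mx: float = 1.0
    alpha_my: float = 0.0
    beta_my: float = 1.0
    model: Literal["causal", "noncausal"] = "causal"
    maf: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigurationError(f"n must be >= 4, got {self.n}")
        for name in ("var_gx", "var_xy"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v!r}")
        for name in ("sigma2_mx", "sigma2_my"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 < self.maf < 1.0:
            raise ConfigurationError(f"maf must be in (0, 1), got {self.maf!r}")
        if self.model not in ("causal", "noncausal"):
            raise ConfigurationError(f"unknown model {self.model!r}")

    @property
    def var_g(self) -> float:
        return 2.0 * self.maf * (1.0 - self.maf)


@dataclass(frozen=True)
class SimulationDataset:
    """One realisation: instrument, true traits and observed traits."""

    g: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_o: np.ndarray
    y_o: np.ndarray
    config: SimulationConfig


def _measure(t: np.ndarray, alpha: float, beta: float, sigma2: float,
             rng: np.random.Generator) -> np.ndarray:
    if sigma2 == 0.0:
        out = alpha + beta * t
        return out if (alpha, beta) != (0.0, 1.0) else t.copy()
    return alpha + beta * t + rng.normal(0.0, math.sqrt(sigma2), t.size)


def _draw_instrument(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, cfg.maf, cfg.n).astype(float)


def simulate_causal(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationDataset:
    """Simulate the causal chain g -> x -> y with measurement error.

    x and y have unit population variance; the genetic effect is
    sqrt(var_gx / var(g)) and the causal effect sqrt(var_xy), with residual
    variances 1 - var_gx and 1 - var_xy, so the configured variances
    explained hold exactly in the population.
    """
    if config.model != "causal":
        raise ConfigurationError("simulate_causal requires model='causal'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = _draw_instrument(config, rng)
    beta_g = math.sqrt(config.var_gx / config.var_g)
    beta_x = math.sqrt(config.var_xy)
    x = beta_g * (g - 2.0 * config.maf) + rng.normal(
        0.0, math.sqrt(1.0 - config.var_gx), config.n
    )
    y = beta_x * x + rng.normal(0.0, math.sqrt(1.0 - config.var_xy), config.n)
    x_o = _measure(x, config.alpha_mx, config.beta_mx, config.sigma2_mx, rng)
    y_o = _measure(y, config.alpha_my, config.beta_my, config.sigma2_my, rng)
    return SimulationDataset(g=g, x=x, y=y, x_o=x_o, y_o=y_o, config=config)


def simulate_noncausal(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationDataset:
    """Simulate genetic confounding: g -> x and g -> y, no x -> y effect.

    The direct g -> y path is sized so the marginal g-y association matches
    the causal model with the same configuration
    (cor(g,y)^2 = var_gx * var_xy); the population cor(x, y | g) is zero.
    """
    if config.model != "noncausal":
        raise ConfigurationError("simulate_noncausal requires model='noncausal'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = _draw_instrument(config, rng)
    gc = g - 2.0 * config.maf
    var_gy = config.var_gx * config.var_xy
    beta_g = math.sqrt(config.var_gx / config.var_g)
    beta_gy = math.sqrt(var_gy / config.var_g)
    x = beta_g * gc + rng.normal(0.0, math.sqrt(1.0 - config.var_gx), config.n)
    y = beta_gy * gc + rng.normal(0.0, math.sqrt(1.0 - var_gy), config.n)
    x_o = _measure(x, config.alpha_mx, config.beta_mx, config.sigma2_mx, rng)
    y_o = _measure(y, config.alpha_my, config.beta_my, config.sigma2_my, rng)
    return SimulationDataset(g=g, x=x, y=y, x_o=x_o, y_o=y_o, config=config)


def simulate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationDataset:
    """Dispatch on ``config.model``."""
    if config.model == "causal":
        return simulate_causal(config, rng)
    return simulate_noncausal(config, rng)


def population_d(config: SimulationConfig) -> float:
    """Exact population d = rho_x,xo - rho_xy * rho_y,yo implied by a config.

    Defined for the causal model only (d presumes a true causal chain).
    With unit-variance traits, rho_t,to = beta_m / sqrt(beta_m^2 + sigma2_m).
    """
    if config.model != "causal":
        raise DomainError("population_d is defined for the causal model")
    rho_xxo = abs(config.beta_mx) / math.sqrt(config.beta_mx**2 + config.sigma2_mx)
    rho_yyo = abs(config.beta_my) / math.sqrt(config.beta_my**2 + config.sigma2_my)
    rho_xy = math.sqrt(config.var_xy)
    return rho_xxo - rho_xy * rho_yyo


def default_grid(
    n: Sequence[int] = (100, 1000, 10000),
    var_xy: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    sigma2_mx: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    sigma2_my: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    var_gx: float = 0.1,
    model: str = "causal",
) -> list[SimulationConfig]:
    """The default evaluation grid: 4 x 6 x 6 x 3 = 432 parameter combinations."""
    cells = []
    for nn in n:
        for vxy in var_xy:
            for s2x in sigma2_mx:
                for s2y in sigma2_my:
                    cells.append(
                        SimulationConfig(
                            n=nn, var_gx=var_gx, var_xy=vxy,
                            sigma2_mx=s2x, sigma2_my=s2y, model=model,  # type: ignore[arg-type]
                        )
                    )
    return cells


def _cell_seed(master_seed: int, config: SimulationConfig) -> int:
    """Stable per-cell seed: adding cells never perturbs other cells' streams."""
    key = json.dumps(
        {k: v for k, v in asdict(config).items() if k != "seed"}, sort_keys=True
    )
    digest = hashlib.sha256(f"{master_seed}|{key}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _classify_mr_steiger(ds: SimulationDataset, alpha: float) -> str:
    res = tsls(ds.g, ds.x_o, ds.y_o)
    st = steiger_one_sample(correlations_from_individual(ds.g, ds.x_o, ds.y_o))
    call = infer_direction(res.p_mr, st, alpha)
    if call.outcome == "no_call":
        return "no_call"
    if ds.config.model == "noncausal":
        return "wrong"  # no causal relationship exists; any call is wrong
    return "correct" if call.outcome == "x_causes_y" else "wrong"


def _classify_cit(ds: SimulationDataset, alpha: float, n_null: int, seed: int) -> str:
    call = cit_bidirectional(
        ds.g, ds.x_o, ds.y_o, alpha=alpha, n_null=n_null, seed=seed
    )
    if call.outcome_code in ("no_evidence", "no_call_confounding"):
        return "no_call"
    if ds.config.model == "noncausal":
        return "wrong"
    return "correct" if call.outcome_code == "model1_accepted" else "wrong"


def run_grid(
    cells: Iterable[SimulationConfig],
    reps: int = 100,
    methods: Sequence[str] = ("mr_steiger", "cit"),
    seed: int = 0,
    alpha: float = 0.05,
    n_null: int = 500,
) -> pd.DataFrame:
    """Run the method-comparison experiment over a grid of configurations.

    For each cell and replicate the configured model is simulated and each
    method classified as making a correct-direction call, a wrong-direction
    call, or no call.  Returns one row per (cell, method) with the three
    rates (summing to 1), the replicate count, and the population d value
    of the cell (NaN for non-causal cells).  Deterministic given ``seed``.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    unknown = set(methods) - {"mr_steiger", "cit"}
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
    rows = []
    for cfg in cells:
        cseed = _cell_seed(seed, cfg)
        counts = {m: {"correct": 0, "wrong": 0, "no_call": 0} for m in methods}
        for rep in range(reps):
            rng = np.random.default_rng([cseed, rep])
            ds = simulate(cfg, rng)
            if "mr_steiger" in methods:
                counts["mr_steiger"][_classify_mr_steiger(ds, alpha)] += 1
            if "cit" in methods:
                cit_seed = int(rng.integers(0, 2**31 - 1))
                counts["cit"][_classify_cit(ds, alpha, n_null, cit_seed)] += 1
        d_pop = population_d(cfg) if cfg.model == "causal" else float("nan")
        for m in methods:
            c = counts[m]
            rows.append(
                {
                    "model": cfg.model,
                    "n": cfg.n,
                    "var_gx": cfg.var_gx,
                    "var_xy": cfg.var_xy,
                    "sigma2_mx": cfg.sigma2_mx,
                    "sigma2_my": cfg.sigma2_my,
                    "method": m,
                    "rate_correct": c["correct"] / reps,
                    "rate_wrong": c["wrong"] / reps,
                    "rate_no_call": c["no_call"] / reps,
                    "reps": reps,
                    "d_population": d_pop,
                }
            )
    return pd.DataFrame(rows)


def _marginal_association(
    trait: np.ndarray, g: np.ndarray, trait_id: str, snp_id: str = "rs1"
) -> SummaryAssociation:
    fit = stats.linregress(g, trait)
    return SummaryAssociation(
        trait_id=trait_id,
        snp_id=snp_id,
        beta=float(fit.slope),
        se=float(fit.stderr),
        pval=max(float(fit.pvalue), float(np.finfo(float).tiny)),
        n=int(g.size),
        effect_allele="A",
    )


def make_fixture_summary_tables(
    config: SimulationConfig, out_dir, seed: int | None = None
) -> tuple[Path, Path, Path]:
    """Simulate a two-sample design and write paired summary-stat tables.

    Two independent cohorts are drawn from ``config``; the exposure is
    regressed on the instrument in cohort 1 and the outcome in cohort 2.
    Writes ``exposure.tsv``, ``outcome.tsv`` and ``manifest.json`` (the
    true direction and generating parameters) and returns the three paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort1 = simulate(config, rng)
    cohort2 = simulate(config, rng)
    exp = _marginal_association(cohort1.x_o, cohort1.g, trait_id="exposure")
    out = _marginal_association(cohort2.y_o, cohort2.g, trait_id="outcome")
    exp_path = out_dir / "exposure.tsv"
    out_path = out_dir / "outcome.tsv"
    write_summary_table([exp], exp_path)
    write_summary_table([out], out_path)
    manifest = {
        "true_direction": (
            "none" if config.model == "causal" and config.var_xy == 0.0
            else "x->y" if config.model == "causal" else "confounded"
        ),
        "config": asdict(config),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return exp_path, out_path, manifest_path
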