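"""Reading, writing and converting GWAS-style summary statistics.

The Steiger direction test operates on instrument-trait *correlations*,
but public summary statistics typically report an effect size, standard
error, p-value and sample size per SNP-trait pair.  This module holds the
record types for both representations and the conversions between them.

The correlation magnitude is recovered from the p-value and sample size by
inverting the two-sided t-test of a simple-regression slope::

    t   = t_quantile(1 - p/2, df = n - 2)
    |r| = t / sqrt(t^2 + n - 2)

which is exact for a single-SNP linear association test and requires no
allele-frequency information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    ValidationError,
)

__all__ = [
    "SummaryAssociation",
    "ObservedCorrelations",
    "DEFAULT_DIALECT",
    "read_summary_table",
    "write_summary_table",
    "r_from_pn",
    "correlations_from_individual",
    "harmonise",
]

#: Canonical field -> column name mapping used when reading/writing tables.
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp": "snp",
    "trait": "trait",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "effect_allele": "effect_allele",
}

_REQUIRED_FIELDS = ("snp", "trait", "pval", "n")
_OPTIONAL_FIELDS = ("beta", "se", "effect_allele")


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP-trait association from a summary-statistics table.

    ``beta``/``se`` are optional: the instrument-trait correlation needed by
    the Steiger test can be recovered from ``pval`` and ``n`` alone.
    """

    trait_id: str
    snp_id: str
    pval: float
    n: int
    beta: float | None = None
    se: float | None = None
    effect_allele: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(
                f"pval must be in (0, 1], got {self.pval!r} "
                f"for {self.trait_id}/{self.snp_id}"
            )
        if self.n < 4:
            raise ValidationError(
                f"sample size must be >= 4 (Fisher z needs N - 3 > 0), got {self.n}"
            )
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"se must be > 0 when provided, got {self.se!r}")

    @property
    def r(self) -> float:
        """Correlation magnitude implied by (pval, n)."""
        return r_from_pn(self.pval, self.n)


@dataclass(frozen=True)
class ObservedCorrelations:
    """The correlation triple entering the Steiger tests.

    Exactly one of ``n`` (one-sample mode) or ``n1``/``n2`` (two-sample
    mode) must be populated.  ``r_xy`` is the correlation between the two
    trait measurements and is only available (and only needed) in the
    one-sample setting.
    """

    r_gx: float
    r_gy: float
    r_xy: float | None = None
    n: int | None = None
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        for name in ("r_gx", "r_gy", "r_xy"):
            val = getattr(self, name)
            if val is not None and not -1.0 <= val <= 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1], got {val!r}")
        one_sample = self.n is not None
        two_sample = self.n1 is not None or self.n2 is not None
        if one_sample == two_sample:
            raise ValidationError(
                "exactly one of {n} or {n1, n2} must be given "
                "(one- vs two-sample mode)"
            )
        if two_sample and (self.n1 is None or self.n2 is None):
            raise ValidationError("two-sample mode needs both n1 and n2")
        for name in ("n", "n1", "n2"):
            val = getattr(self, name)
            if val is not None and val < 4:
                raise ValidationError(f"{name} must be >= 4, got {val}")

    @property
    def mode(self) -> str:
        return "one_sample" if self.n is not None else "two_sample"


def r_from_pn(pval: float, n: int) -> float:
    """Correlation magnitude |r| recovered from a two-sided p-value and n.

    Inverts the t-test of a simple-regression slope; monotone decreasing in
    ``pval`` at fixed ``n``, with ``r_from_pn(1, n) == 0``.
    """
    if not 0.0 < pval <= 1.0:
        raise DomainError(f"pval must be in (0, 1], got {pval!r}")
    if n < 4:
        raise DomainError(f"n must be >= 4, got {n}")
    t = stats.t.isf(pval / 2.0, n - 2)
    if t <= 0.0:  # pval == 1 gives the median of the t distribution
        return 0.0
    return float(t / math.sqrt(t * t + n - 2))


def correlations_from_individual(
    g: np.ndarray, x: np.ndarray, y: np.ndarray
) -> ObservedCorrelations:
    """Pearson correlation triple from individual-level data (one-sample)."""
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (g.shape == x.shape == y.shape) or g.ndim != 1:
        raise ValidationError("g, x, y must be 1-d arrays of equal length")
    if g.size < 4:
        raise ValidationError("need at least 4 observations")
    for name, v in (("g", g), ("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"{name} has zero variance")
    c = np.corrcoef(np.vstack([g, x, y]))
    return ObservedCorrelations(
        r_gx=float(c[0, 1]), r_gy=float(c[0, 2]), r_xy=float(c[1, 2]), n=int(g.size)
    )


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str]
) -> dict[str, str]:
    mapping = dict(DEFAULT_DIALECT)
    mapping.update(dialect or {})
    missing = [mapping[f] for f in _REQUIRED_FIELDS if mapping[f] not in columns]
    if missing:
        raise ConfigurationError(
            f"summary table is missing required column(s) {missing}; "
            f"present: {list(columns)}"
        )
    return mapping


def read_summary_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[SummaryAssociation]:
    """Read a delimited summary-statistics table into records.

    The delimiter (tab or comma) is auto-detected.  ``dialect`` maps the
    canonical field names (``snp, trait, beta, se, pval, n, effect_allele``)
    to the column names actually present.  Rows with unparseable or invalid
    required fields are rejected with row-indexed messages.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    mapping = _resolve_columns(df.columns, dialect or {})
    records: list[SummaryAssociation] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        try:
            kwargs = dict(
                trait_id=str(row[mapping["trait"]]),
                snp_id=str(row[mapping["snp"]]),
                pval=float(row[mapping["pval"]]),
                n=int(row[mapping["n"]]),
            )
            for field in _OPTIONAL_FIELDS:
                col = mapping[field]
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[field] = (
                        str(row[col]) if field == "effect_allele" else float(row[col])
                    )
            records.append(SummaryAssociation(**kwargs))
        except (ValueError, TypeError) as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if bad_rows:
        raise ValidationError(
            "invalid rows in summary table:\n" + "\n".join(bad_rows)
        )
    return records


def write_summary_table(
    records: Sequence[SummaryAssociation],
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> None:
    """Write records as a delimited table, floats at 10 significant digits."""
    mapping = dict(DEFAULT_DIALECT)
    mapping.update(dialect or {})
    rows = []
    for rec in records:
        rows.append(
            {
                mapping["snp"]: rec.snp_id,
                mapping["trait"]: rec.trait_id,
                mapping["beta"]: rec.beta,
                mapping["se"]: rec.se,
                mapping["pval"]: rec.pval,
                mapping["n"]: rec.n,
                mapping["effect_allele"]: rec.effect_allele,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.10g")


def harmonise(
    exposure: SummaryAssociation, outcome: SummaryAssociation
) -> tuple[SummaryAssociation, SummaryAssociation]:
    """Align the effect alleles of two associations sharing a SNP.

    If the two records report different effect alleles, the outcome beta has
    its sign flipped.  Correlations are used in absolute value downstream,
    so harmonisation affects only the sign of reported effect sizes (and
    hence the sign of the Wald ratio).
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValidationError(
            f"cannot harmonise different SNPs: {exposure.snp_id} vs {outcome.snp_id}"
        )
    if (
        exposure.effect_allele is None
        or outcome.effect_allele is None
        or exposure.effect_allele == outcome.effect_allele
    ):
        return exposure, outcome
    if outcome.beta is None:
        raise ValidationError(
            "effect alleles differ but the outcome record has no beta to flip"
        )
    return exposure, replace(outcome, beta=-outcome.beta)
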