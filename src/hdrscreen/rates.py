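"""Descriptive statistics for pooled transgenesis screens.

Implements the "minimum integration rate" (positive pools / surviving G0,
as a percentage), rounded proportion utilities, exact Clopper-Pearson
confidence intervals, and the exact binomial test used for all construct
and donor comparisons.

Conventions
-----------
* Percentages round half away from zero (so 13/271 -> 4.80%, not 4.8%),
  matching how screening results are conventionally reported.
* The two-sided binomial test defaults to the minimum-likelihood
  ("minlike") definition: the p-value sums P(X = j) over every outcome j
  no more probable than the observed one. A "central" (doubled one-sided)
  definition is available as an option.
* In construct comparisons the null proportion is the comparator's point
  estimate k_ref / n_ref. Both conventions are explicit keyword arguments
  because reported p-values depend on them.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateEstimate",
    "TestResult",
    "round_half_away",
    "minimum_integration_rate",
    "proportion_pct",
    "exact_binomial_test",
    "clopper_pearson_ci",
    "compare_constructs",
    "construct_counts",
]

Alternative = Literal["two_sided", "less", "greater"]

#: relative tolerance when comparing pmf values for the minlike p-value;
#: outcomes whose probability ties the observed one within this factor count.
PMF_REL_TOL = 1e-7


def round_half_away(x: float, dp: int = 2) -> float:
    """Round to `dp` decimals with ties going away from zero.

    Python's built-in round() is banker's rounding; screening percentages
    are conventionally reported with 0.5 rounding up, so 2.25 stays 2.25
    and 4.795 -> 4.80.
    """
    q = decimal.Decimal(1).scaleb(-dp)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEstimate:
    """A screening proportion with its exact confidence interval.

    ``pct`` is 100*k/n rounded half-away-from-zero to ``dp`` decimals.
    ``is_lower_bound`` marks minimum integration rates: one positive pool
    may hide several independent insertions, so the true per-founder rate
    can only be higher.
    """

    k: int
    n: int
    pct: float
    ci_low: float
    ci_high: float
    dp: int = 2
    level: float = 0.95
    is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0.0 <= self.ci_low <= self.k / self.n <= self.ci_high <= 1.0):
            raise ValueError("confidence bounds must bracket k/n in [0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Outcome of an exact binomial test of k/n against a null proportion."""

    k: int
    n: int
    p0: float
    alternative: Alternative
    p_value: float
    construct: str | None = None
    method: str = "minlike"


def minimum_integration_rate(k: int, n: int, dp: int = 2,
                             level: float = 0.95) -> RateEstimate:
    """Minimum integration rate: positive pools over surviving G0, as %.

    Parameters
    ----------
    k : number of G0 pools with at least one transgenic G1
    n : number of surviving injected G0
    dp : decimals for the rounded percentage
    level : confidence level for the exact (Clopper-Pearson) interval

    The estimate is a lower bound on the per-founder integration rate:
    pooling censors multiple independent insertions within one pool.
    """
    if n <= 0:
        raise ValueError("n (surviving G0) must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = clopper_pearson_ci(k, n, level)
    return RateEstimate(k=k, n=n, pct=round_half_away(100.0 * k / n, dp),
                        ci_low=lo, ci_high=hi, dp=dp, level=level,
                        is_lower_bound=True)


def proportion_pct(k: int, n: int, dp: int = 0) -> float:
    """100*k/n rounded half away from zero to `dp` decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return round_half_away(100.0 * k / n, dp)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95
                       ) -> tuple[float, float]:
    """Exact central confidence interval for a binomial proportion.

    Beta-quantile form; the lower bound is 0 when k = 0 and the upper
    bound is 1 when k = n. Coverage is at least `level` by construction.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def exact_binomial_test(k: int, n: int, p0: float,
                        alternative: Alternative = "two_sided",
                        method: str = "minlike") -> TestResult:
    """Exact binomial test of observing k successes in n trials under p0.

    One-sided p-values are exact tail sums. For ``alternative="two_sided"``
    the default ``method="minlike"`` sums P(X = j | n, p0) over every j
    whose probability does not exceed P(k) (with a small relative
    tolerance for floating-point ties). ``method="central"`` doubles the
    smaller one-sided p-value and caps at 1.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    if method not in ("minlike", "central"):
        raise ValueError(f"unknown two-sided method {method!r}")

    dist = stats.binom(n, p0)
    p_less = float(dist.cdf(k))
    p_greater = float(dist.sf(k - 1))
    if alternative == "less":
        pval = p_less
    elif alternative == "greater":
        pval = p_greater
    elif alternative == "two_sided":
        if p0 in (0.0, 1.0):
            # degenerate null: the only possible outcome has probability 1
            pval = 1.0 if k == (0 if p0 == 0.0 else n) else 0.0
        elif method == "central":
            pval = min(1.0, 2.0 * min(p_less, p_greater))
        else:
            pmf = dist.pmf(np.arange(n + 1))
            pval = float(pmf[pmf <= pmf[k] * (1.0 + PMF_REL_TOL)].sum())
        pval = min(pval, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(k=k, n=n, p0=p0, alternative=alternative,
                      p_value=pval, method=method)


def construct_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a pool-level experiment table to per-construct counts.

    Returns one row per construct with ``k`` (positive pools), ``n_pools``,
    ``n`` (total surviving G0, the denominator of the minimum integration
    rate) and ``donor_type``.
    """
    rows = []
    for construct, grp in table.groupby("construct", sort=False):
        totals = grp["g0_survivors_total"].unique()
        if len(totals) != 1:
            raise ValueError(
                f"construct {construct!r} has inconsistent g0_survivors_total")
        rows.append({
            "construct": construct,
            "donor_type": grp["donor_type"].iloc[0],
            "k": int(grp["positive"].sum()),
            "n_pools": int(len(grp)),
            "n": int(totals[0]),
        })
    return pd.DataFrame(rows)


def compare_constructs(table: pd.DataFrame, reference_construct_id: str,
                       alternative: Alternative = "two_sided",
                       method: str = "minlike") -> list[TestResult]:
    """Exact binomial tests of every construct against a reference.

    For each non-reference construct c, tests k_c positive pools out of
    n_c surviving G0 against the null proportion k_ref / n_ref (the
    reference's point estimate). The reference tested against itself
    gives p = 1 by construction.
    """
    counts = construct_counts(table).set_index("construct")
    if reference_construct_id not in counts.index:
        raise ValueError(
            f"reference construct {reference_construct_id!r} not in table")
    ref = counts.loc[reference_construct_id]
    if ref["k"] == 0:
        warnings.warn(
            f"reference {reference_construct_id!r} has zero positive pools; "
            "all comparisons are against a degenerate null p0 = 0",
            stacklevel=2)
    p0 = ref["k"] / ref["n"]
    results = []
    for construct, row in counts.iterrows():
        if construct == reference_construct_id:
            continue
        res = exact_binomial_test(int(row["k"]), int(row["n"]), p0,
                                  alternative=alternative, method=method)
        results.append(TestResult(**{**res.__dict__, "construct": construct}))
    return results
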