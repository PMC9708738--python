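"""Group-level significance tests and effect sizes.

Implements the statistics applied to the derived perceptual measures:
one-sample t-tests with Cohen's d (regression index and offset against 0)
and the Wilcoxon-Mann-Whitney rank test for between-group comparisons of
medians (Weber fraction, control metrics).  The statistics are computed
from first principles (only the t distribution function comes from scipy)
so that printed values can be audited from summary statistics alone.

Mann-Whitney details: U counts, for every (x, y) pair, 1 when x > y and
0.5 on a tie.  For n1 + n2 <= 12 the two-sided p-value is obtained by
exact enumeration of all group assignments of the pooled sample; larger
samples use the normal approximation with tie-corrected variance and a
0.5 continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "one_sample_t",
    "one_sample_t_from_summary",
    "mann_whitney",
    "EXACT_ENUMERATION_MAX_N",
]

#: Largest pooled sample size for which the Mann-Whitney p-value is exact.
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    """One test result: statistic, p-value and effect size."""

    method: str  # "one_sample_t" | "mann_whitney"
    statistic_name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    df: float | None = None
    n1: int | None = None
    n2: int | None = None
    z: float | None = None
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu0: float = 0.0, alternative: str = "two-sided"
) -> GroupComparison:
    """One-sample t-test from summary statistics (sample SD, n-1 df).

    t = (M - mu0) / (SD / sqrt(n)), df = n - 1, Cohen's d = (M - mu0) / SD.
    This is the route used to audit printed statistics against reported
    group means and SDs.
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    if not sd > 0:
        raise ValueError(f"sample SD must be positive, got {sd}")
    se = sd / math.sqrt(n)
    t = (mean - mu0) / se
    d = (mean - mu0) / sd
    df = n - 1
    p = _t_pvalue(t, df, alternative)
    return GroupComparison(
        method="one_sample_t",
        statistic_name="t",
        statistic=float(t),
        p_value=float(p),
        effect_size=float(d),
        df=float(df),
        n1=n,
        alternative=alternative,
    )


def one_sample_t(values, mu0: float = 0.0, alternative: str = "two-sided") -> GroupComparison:
    """One-sample t-test of ``values`` against ``mu0`` with Cohen's d."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("sample SD is zero: t statistic undefined")
    return one_sample_t_from_summary(float(np.mean(x)), sd, x.size, mu0, alternative)


def _t_pvalue(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return 2.0 * sps.t.sf(abs(t), df)
    if alternative == "less":
        return sps.t.cdf(t, df)
    if alternative == "greater":
        return sps.t.sf(t, df)
    raise ValueError(f"unknown alternative: {alternative!r}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: pairwise wins plus half-credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y, alternative: str = "two-sided") -> GroupComparison:
    """Wilcoxon-Mann-Whitney rank test for two independent samples.

    Reports U for the first sample, the tie-corrected continuity-corrected
    normal z, and a p-value that is exact (full enumeration) when
    n1 + n2 <= 12 and normal-approximate otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative != "two-sided":
        raise ValueError("only two-sided Mann-Whitney is implemented")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)

    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var > 0:
        # continuity correction shrinks |U - mu| by 0.5
        z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
    else:
        z = 0.0

    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_mw_pvalue(pooled, n1, u)
    else:
        p = float(2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0
    return GroupComparison(
        method="mann_whitney",
        statistic_name="U",
        statistic=float(u),
        p_value=float(min(p, 1.0)),
        df=None,
        n1=n1,
        n2=n2,
        z=float(z),
        alternative=alternative,
    )


def _exact_mw_pvalue(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) group assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1; ties in the
    pooled data are handled naturally because U is recomputed per
    assignment on the actual values.
    """
    n = pooled.size
    idx = range(n)
    total = math.comb(n, n1)
    le = ge = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)
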