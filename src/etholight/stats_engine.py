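"""Two-sample testing with a normality-gated decision tree.

The procedure mirrors common practice for cohort comparisons: assess each
group with the D'Agostino-Pearson omnibus normality test; if both pass,
compare variances with a two-tailed F-test and run either the unpaired
Student t test (equal variances) or the unpaired t test with Welch correction
(unequal variances); otherwise fall back to the Mann-Whitney test. All
reported p values are two-tailed. Groups too small for the normality test
(n < 8) route directly to Mann-Whitney. Every gate taken is recorded in the
report's ``decision_trace``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_GATE_ALPHA = 0.05
NORMALITY_MIN_N = 8
#: exact Mann-Whitney enumeration cap: number of group assignments
EXACT_MW_MAX_ASSIGNMENTS = 200_000

STAR_THRESHOLDS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


class InsufficientSamples(ValueError):
    """A test's sample-size precondition is not met."""


@dataclass(frozen=True)
class SampleGroup:
    """One group of measurements to compare."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a sample group needs at least two values")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class StatReport:
    """Outcome of one gated two-sample comparison."""

    test_name: str  # "t" | "welch_t" | "mann_whitney"
    statistic: float
    df: float | None
    p_two_tailed: float
    stars: str
    decision_trace: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p value outside [0, 1]")
        if self.stars != star_annotation(self.p_two_tailed):
            raise ValueError("stars inconsistent with p value")
        if not self.decision_trace:
            raise ValueError("decision trace must not be empty")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_two_tailed": self.p_two_tailed,
            "stars": self.stars,
            "decision_trace": list(self.decision_trace),
        }


def star_annotation(p: float) -> str:
    """Boundary-inclusive star annotation: * p<=0.05, ** p<=0.01,
    *** p<=0.001, **** p<=0.0001; otherwise 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p value outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def dagostino_pearson(sample: SampleGroup) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus K2 normality test.

    Combines skewness and kurtosis z-transforms; p from chi-square(2).
    Requires n >= 8 for the component transforms to be defined.
    """
    if sample.n < NORMALITY_MIN_N:
        raise InsufficientSamples(
            f"insufficient n for normality test (n={sample.n} < {NORMALITY_MIN_N})"
        )
    k2, p = stats.normaltest(sample.values)
    return float(k2), float(p)


def variance_f_test(x: SampleGroup, y: SampleGroup) -> tuple[float, float]:
    """Two-tailed F-test of equal variances, F = larger s^2 / smaller s^2."""
    vx = float(np.var(x.values, ddof=1))
    vy = float(np.var(y.values, ddof=1))
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both groups have zero variance; F undefined")
    if vx >= vy:
        num_var, den_var, dfn, dfd = vx, vy, x.n - 1, y.n - 1
    else:
        num_var, den_var, dfn, dfd = vy, vx, y.n - 1, x.n - 1
    if den_var == 0.0:
        return float("inf"), 0.0
    f = num_var / den_var
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return f, float(min(p, 1.0))


def _u_from_ranksum(rank_sum: float, n: int) -> float:
    return rank_sum - n * (n + 1) / 2.0


def exact_mann_whitney(
    x: SampleGroup | Sequence[float], y: SampleGroup | Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with an exact two-tailed p for small samples.

    The exact branch enumerates every C(n+m, n) assignment of the pooled
    values (midranks, so ties are handled exactly) and returns
    p = min(1, 2 * min(P(U <= u), P(U >= u))). When the assignment count
    exceeds ``EXACT_MW_MAX_ASSIGNMENTS`` the normal approximation with tie
    correction and continuity correction is used instead.

    Returns (U of the first group, two-tailed p).
    """
    xv = x.values if isinstance(x, SampleGroup) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, SampleGroup) else np.asarray(y, dtype=float)
    n, m = xv.size, yv.size
    if n < 1 or m < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([xv, yv])
    ranks = stats.rankdata(pooled)
    u_x = _u_from_ranksum(float(ranks[:n].sum()), n)

    if math.comb(n + m, n) <= EXACT_MW_MAX_ASSIGNMENTS:
        total = 0
        le = 0
        ge = 0
        offset = n * (n + 1) / 2.0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if u <= u_x + 1e-12:
                le += 1
            if u >= u_x - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_x, p

    res = stats.mannwhitneyu(xv, yv, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    x: SampleGroup | Sequence[float],
    y: SampleGroup | Sequence[float],
    gate_alpha: float = DEFAULT_GATE_ALPHA,
) -> StatReport:
    """Run the gated two-sample comparison and report the decision path.

    Gates (each at ``gate_alpha``):

    1. normality of each group (D'Agostino-Pearson); either group n < 8 or
       non-normal -> Mann-Whitney;
    2. F-test of variances; equal -> unpaired Student t, unequal ->
       unpaired t with Welch correction (Welch-Satterthwaite df).
    """
    if not isinstance(x, SampleGroup):
        x = SampleGroup(np.asarray(x, dtype=float), label="x")
    if not isinstance(y, SampleGroup):
        y = SampleGroup(np.asarray(y, dtype=float), label="y")
    trace: list[dict] = []

    if min(x.n, y.n) < NORMALITY_MIN_N:
        trace.append(
            {
                "gate": "normality",
                "outcome": "insufficient_n",
                "p": None,
                "detail": f"min group n = {min(x.n, y.n)} < {NORMALITY_MIN_N}",
            }
        )
        u, p = exact_mann_whitney(x, y)
        trace.append({"gate": "test", "outcome": "mann_whitney", "p": p})
        return StatReport(
            test_name="mann_whitney",
            statistic=u,
            df=None,
            p_two_tailed=p,
            stars=star_annotation(p),
            decision_trace=tuple(trace),
        )

    normal = True
    for grp in (x, y):
        _, p_norm = dagostino_pearson(grp)
        passed = p_norm >= gate_alpha
        trace.append(
            {
                "gate": "normality",
                "outcome": "normal" if passed else "non_normal",
                "p": p_norm,
                "detail": grp.label or None,
            }
        )
        normal = normal and passed

    if not normal:
        u, p = exact_mann_whitney(x, y)
        trace.append({"gate": "test", "outcome": "mann_whitney", "p": p})
        return StatReport(
            test_name="mann_whitney",
            statistic=u,
            df=None,
            p_two_tailed=p,
            stars=star_annotation(p),
            decision_trace=tuple(trace),
        )

    _, p_var = variance_f_test(x, y)
    equal_var = p_var >= gate_alpha
    trace.append(
        {
            "gate": "variance_f",
            "outcome": "equal" if equal_var else "unequal",
            "p": p_var,
        }
    )

    res = stats.ttest_ind(x.values, y.values, equal_var=equal_var)
    t_stat = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    name = "t" if equal_var else "welch_t"
    trace.append({"gate": "test", "outcome": name, "p": p})
    return StatReport(
        test_name=name,
        statistic=t_stat,
        df=df,
        p_two_tailed=p,
        stars=star_annotation(p),
        decision_trace=tuple(trace),
    )
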