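"""Construct-validity statistics.

Construct validity here means the ability of a per-trial metric to
separate surgeon groups of known different expertise.  The analysis has
three stages:

1. **Group comparisons** — per exercise x metric: group means/SDs and
   the three pairwise two-sample t-tests (new vs intermediate, new vs
   experienced, intermediate vs experienced), Student's pooled-variance
   variant by default.
2. **Discrimination** — per metric, the per-exercise group means of the
   two extreme groups are min-max normalized over their pooled set
   (x_i^n = (x_i − x_min)/(x_max − x_min), shared bounds so the groups
   stay comparable), and the discrimination index is
   d = |mean(new) − mean(experienced)| of the normalized means across
   exercises.  Metrics are ranked by d; metric-vs-metric differences are
   paired t-tests on the per-exercise |differences|, paired by exercise.
3. **Correlations** — Pearson r of each camera metric against
   completion time and overall score over all surgeons pooled, with the
   two-sided p from t = r·sqrt((n−2)/(1−r²)).

Missing metric values (e.g. CDur of a zero-episode trial) are excluded
pairwise and every statistic carries its effective n.  No
multiple-testing correction is applied; reports carry the comparison
count so users can apply their own.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .telemetry import GROUPS
from .metrics import CAMERA_METRICS, METRIC_NAMES

__all__ = [
    "TTestResult",
    "GroupComparison",
    "NormalizedMetricVector",
    "DiscriminationResult",
    "CorrelationResult",
    "two_sample_t",
    "group_comparisons",
    "minmax_normalize",
    "discrimination",
    "pearson_with_p",
    "metric_target_correlations",
    "validity_summary",
    "GROUP_PAIRS",
]

logger = logging.getLogger(__name__)

#: The three pairwise group comparisons, in report order.
GROUP_PAIRS = (
    ("new", "intermediate"),
    ("new", "experienced"),
    ("intermediate", "experienced"),
)


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome; ``ok=False`` flags not-computable."""

    t: float
    df: float
    p: float
    n_a: int
    n_b: int
    ok: bool = True

    @classmethod
    def not_computable(cls, n_a: int = 0, n_b: int = 0) -> "TTestResult":
        return cls(t=math.nan, df=math.nan, p=math.nan, n_a=n_a, n_b=n_b, ok=False)


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def two_sample_t(a, b, variant: str = "student") -> TTestResult:
    """Two-sided two-sample t-test after pairwise missing-value removal.

    ``variant="student"``: pooled variance, df = n_a + n_b − 2 (the
    classical test).  ``variant="welch"``: unequal variances with
    Welch–Satterthwaite df.  Degenerate inputs (either sample smaller
    than 2, or zero variance in both samples) are flagged
    not-computable rather than raising.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a, b = _clean(a), _clean(b)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        return TTestResult.not_computable(n_a, n_b)
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return TTestResult.not_computable(n_a, n_b)
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_a=n_a,
        n_b=n_b,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Group means/SDs and the three pairwise tests for one exercise x metric."""

    exercise_id: str
    metric: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    ns: Mapping[str, int]
    tests: Mapping[tuple[str, str], TTestResult]


def group_comparisons(
    table: pd.DataFrame,
    metric: str,
    exercise_id: str,
    variant: str = "student",
) -> GroupComparison:
    """Means/SDs per group (sample SD, n−1) and the three pairwise t-tests.

    Missing metric values are excluded per comparison; an absent or
    single-surgeon group flags its comparisons not-computable.
    """
    sub = table[table["exercise_id"] == exercise_id]
    if sub.empty:
        raise ValueError(f"exercise {exercise_id!r} not in table")
    vals = {g: _clean(sub.loc[sub["group"] == g, metric]) for g in GROUPS}
    means = {g: (float(np.mean(v)) if len(v) else math.nan) for g, v in vals.items()}
    sds = {g: (float(np.std(v, ddof=1)) if len(v) > 1 else math.nan) for g, v in vals.items()}
    ns = {g: int(len(v)) for g, v in vals.items()}
    tests = {
        pair: two_sample_t(vals[pair[0]], vals[pair[1]], variant=variant)
        for pair in GROUP_PAIRS
    }
    return GroupComparison(
        exercise_id=exercise_id, metric=metric, means=means, sds=sds, ns=ns, tests=tests
    )


@dataclass(frozen=True)
class NormalizedMetricVector:
    """Min-max normalized per-exercise means with retained bounds."""

    metric: str
    normalized: np.ndarray
    x_min: float
    x_max: float
    degenerate: bool = False


def minmax_normalize(values, metric: str = "") -> NormalizedMetricVector:
    """Min-max normalize a vector of per-exercise means onto [0, 1].

    x_i^n = (x_i − x_min)/(x_max − x_min).  A constant vector yields
    all zeros with the ``degenerate`` flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in normalization input")
    x_min, x_max = float(x.min()), float(x.max())
    if x_max == x_min:
        return NormalizedMetricVector(
            metric=metric,
            normalized=np.zeros_like(x),
            x_min=x_min,
            x_max=x_max,
            degenerate=True,
        )
    return NormalizedMetricVector(
        metric=metric,
        normalized=(x - x_min) / (x_max - x_min),
        x_min=x_min,
        x_max=x_max,
    )


@dataclass(frozen=True)
class DiscriminationResult:
    """Discrimination of one metric between the two extreme groups.

    ``d`` is the absolute difference of the across-exercise means of
    the two groups' normalized per-exercise means; ``d_i`` the retained
    per-exercise absolute differences, ``sd`` their dispersion.
    ``pairwise_p`` maps other metric names to the paired-t p-value
    comparing this metric's d_i against theirs (paired by exercise).
    ``rank`` is 1 for the best-discriminating metric.
    """

    metric: str
    d: float
    d_i: np.ndarray
    sd: float
    rank: int = 0
    pairwise_p: Mapping[str, float] = field(default_factory=dict)


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    diff = x - y
    if np.allclose(diff, diff[0]):
        if diff[0] == 0.0:
            return 1.0  # identical vectors: no evidence of any difference
        return math.nan
    return float(stats.ttest_rel(x, y).pvalue)


def discrimination(
    table: pd.DataFrame,
    metrics: Sequence[str] = ("cfrq", "cdur", "cint", "comp_time", "eom", "mwr"),
    group_pair: tuple[str, str] = ("new", "experienced"),
    paired: bool = True,
) -> list[DiscriminationResult]:
    """Rank metrics by their normalized new-vs-experienced difference.

    For each metric the per-exercise means of both groups are pooled
    and min-max normalized with shared bounds (per-group normalization
    would force both groups onto [0, 1] and destroy the between-group
    difference being measured).  Output is sorted by ``d`` descending
    (rank 1 = best discriminator).  A metric whose group means are not
    computable for more than half of the exercises is excluded with a
    warning.  ``paired=False`` switches the metric-vs-metric tests to
    unpaired two-sample t-tests.
    """
    exercises = sorted(table["exercise_id"].unique())
    if len(exercises) < 2:
        raise ValueError("discrimination needs at least 2 exercises")
    g1, g2 = group_pair
    per_metric: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for m in metrics:
        m1, m2 = [], []
        for ex in exercises:
            sub = table[table["exercise_id"] == ex]
            v1 = _clean(sub.loc[sub["group"] == g1, m])
            v2 = _clean(sub.loc[sub["group"] == g2, m])
            m1.append(np.mean(v1) if len(v1) else math.nan)
            m2.append(np.mean(v2) if len(v2) else math.nan)
        m1, m2 = np.asarray(m1), np.asarray(m2)
        bad = ~(np.isfinite(m1) & np.isfinite(m2))
        if bad.sum() > len(exercises) / 2:
            logger.warning(
                "metric %r has group means for only %d/%d exercises; excluded",
                m,
                int((~bad).sum()),
                len(exercises),
            )
            continue
        per_metric[m] = (m1[~bad], m2[~bad]) if bad.any() else (m1, m2)

    results: list[DiscriminationResult] = []
    d_vectors: dict[str, np.ndarray] = {}
    for m, (m1, m2) in per_metric.items():
        norm = minmax_normalize(np.concatenate([m1, m2]), metric=m)
        k = len(m1)
        n1, n2 = norm.normalized[:k], norm.normalized[k:]
        d_i = np.abs(n1 - n2)
        d = abs(float(np.mean(n1) - np.mean(n2)))
        d_vectors[m] = d_i
        results.append(
            DiscriminationResult(
                metric=m, d=d, d_i=d_i, sd=float(np.std(d_i, ddof=1))
            )
        )
    results.sort(key=lambda r: -r.d)
    ranked: list[DiscriminationResult] = []
    for rank, r in enumerate(results, start=1):
        pairwise = {}
        for other, dv in d_vectors.items():
            if other == r.metric:
                continue
            if paired and len(dv) == len(r.d_i):
                pairwise[other] = _paired_p(r.d_i, dv)
            else:
                res = two_sample_t(r.d_i, dv)
                pairwise[other] = res.p if res.ok else math.nan
        ranked.append(
            DiscriminationResult(
                metric=r.metric,
                d=r.d,
                d_i=r.d_i,
                sd=r.sd,
                rank=rank,
                pairwise_p=pairwise,
            )
        )
    return ranked


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one metric against one target."""

    exercise_id: str
    metric: str
    target: str
    r: float
    p: float
    n: int
    ok: bool = True


def pearson_with_p(x, y) -> tuple[float, float, int, bool]:
    """Pearson r with the two-sided p from t = r·sqrt((n−2)/(1−r²)).

    Pairwise-complete observations only; returns ``(r, p, n, ok)`` with
    ``ok=False`` (NaNs) for n < 3 or zero variance.  For |r| = 1 the
    p-value degenerates to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return (math.nan, math.nan, n, False)
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return (float(np.sign(r)), 0.0, n, True)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return (r, p, n, True)


def metric_target_correlations(
    table: pd.DataFrame,
    camera_metrics: Sequence[str] = CAMERA_METRICS,
    targets: Sequence[str] = ("comp_time", "overall_score"),
) -> list[CorrelationResult]:
    """Per exercise x camera metric x target, over all groups pooled."""
    results = []
    for ex in sorted(table["exercise_id"].unique()):
        sub = table[table["exercise_id"] == ex]
        for m in camera_metrics:
            for tgt in targets:
                r, p, n, ok = pearson_with_p(sub[m], sub[tgt])
                if not ok:
                    logger.warning(
                        "correlation %s vs %s on %r not computable (n=%d)",
                        m,
                        tgt,
                        ex,
                        n,
                    )
                results.append(
                    CorrelationResult(
                        exercise_id=ex, metric=m, target=tgt, r=r, p=p, n=n, ok=ok
                    )
                )
    return results


def validity_summary(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRIC_NAMES,
    pair: tuple[str, str] = ("new", "experienced"),
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Headline construct-validity declaration per metric.

    For each metric: the number of exercises whose ``pair`` comparison
    is significant at ``alpha``, the number computable, and the
    declaration ``valid`` when a majority of computable exercises are
    significant — the whole-battery analogue of reporting "significant
    in k of N exercises".
    """
    rows = []
    exercises = sorted(table["exercise_id"].unique())
    for m in metrics:
        n_sig = n_ok = 0
        for ex in exercises:
            res = group_comparisons(table, m, ex, variant=variant).tests[pair]
            if res.ok:
                n_ok += 1
                if res.p < alpha:
                    n_sig += 1
        rows.append(
            {
                "metric": m,
                "pair": f"{pair[0]}_vs_{pair[1]}",
                "n_exercises": len(exercises),
                "n_computable": n_ok,
                "n_significant": n_sig,
                "valid": bool(n_ok > 0 and n_sig > n_ok / 2),
            }
        )
    return pd.DataFrame(rows)
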