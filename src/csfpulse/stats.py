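"""Group-level statistics of the pulsation study.

Pairwise pooled two-sample t-tests (from raw samples or published summary
statistics), Fisher's exact test for gender tables, OLS age
residualization of the pulsation measure, percentile-bootstrap pairwise
comparisons, one-way ANOVA with Bonferroni-corrected post-hoc t-tests, and
Pearson correlations.  Thin, convention-pinning wrappers around
scipy.stats so every comparison in the pipeline reports the same record
type with explicit zero-variance behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "GroupComparison",
    "two_sample_t",
    "fisher_exact_2x2",
    "residualize_age",
    "bootstrap_pairwise",
    "anova_bonferroni",
    "pearson_corr",
]

GROUP_LABELS = ("HC", "PDD-L", "PDD-H")


@dataclass
class SubjectRecord:
    """Demographics, group label and derived pulsation measures of a subject."""

    subject_id: str
    group: str
    age: float
    gender: str
    education: float | None = None
    mmse: float | None = None
    duration: float | None = None
    updrs: float | None = None
    mean_pulse: float | None = None
    abs_z_mean: float | None = None
    positive_ratio: float | None = None
    n_voxels: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"group must be one of {GROUP_LABELS}, got {self.group!r}"
            )


@dataclass(frozen=True)
class GroupComparison:
    """One statistical comparison between two groups (or an omnibus test)."""

    measure: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("confidence interval bounds out of order")


def two_sample_t(
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    *,
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    equal_var: bool = True,
    measure: str = "",
    groups: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided two-sample t-test from raw samples or (mean, sd, n) summaries.

    Pooled variance by default (Welch via ``equal_var=False``).  Zero
    pooled variance is handled by convention: p = 1 for equal means,
    p = 0 otherwise.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("both summaries are required")
        m1, s1, n1 = summary_a
        m2, s2, n2 = summary_b
    else:
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
        m1, s1, n1 = float(xa.mean()), float(xa.std(ddof=1)), xa.size
        m2, s2, n2 = float(ya.mean()), float(ya.std(ddof=1)), ya.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0.0 and s2 == 0.0:
        p = 1.0 if m1 == m2 else 0.0
        stat = 0.0 if m1 == m2 else float(np.sign(m1 - m2)) * float("inf")
        return GroupComparison(
            measure=measure, group_a=groups[0], group_b=groups[1],
            statistic=stat, p_value=p, method="t_test", n_a=n1, n_b=n2,
        )
    res = sps.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=equal_var
    )
    return GroupComparison(
        measure=measure, group_a=groups[0], group_b=groups[1],
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="t_test" if equal_var else "welch_t_test", n_a=n1, n_b=n2,
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]],
    *,
    measure: str = "gender",
    groups: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 count table.

    Rows are groups, columns categories.  The two-sided p sums the
    hypergeometric probabilities of all tables (at fixed margins) no more
    probable than the observed one.  A zero margin is degenerate: p = 1
    with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: test degenerate, p = 1",
                      stacklevel=2)
        return GroupComparison(
            measure=measure, group_a=groups[0], group_b=groups[1],
            statistic=float("nan"), p_value=1.0, method="fisher_exact",
            n_a=int(t[0].sum()), n_b=int(t[1].sum()),
        )
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        measure=measure, group_a=groups[0], group_b=groups[1],
        statistic=float(odds), p_value=float(p), method="fisher_exact",
        n_a=int(t[0].sum()), n_b=int(t[1].sum()),
    )


def residualize_age(records: pd.DataFrame, measure: str) -> pd.Series:
    """Age-adjusted measure: OLS residual plus grand mean, pooled cohort.

    Regresses the measure on age across all subjects (single covariate,
    groups pooled) and returns residual + grand mean, so the pooled mean is
    preserved exactly and group labels are untouched.  Constant age makes
    the adjustment impossible; the measure is returned unchanged with a
    warning.
    """
    sub = records[["age", measure]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 subjects with age and measure")
    age = sub["age"].to_numpy(dtype=float)
    y = sub[measure].to_numpy(dtype=float)
    if np.ptp(age) == 0.0:
        warnings.warn("constant age: adjustment skipped", stacklevel=2)
        return records[measure].copy()
    design = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    adjusted = records[measure].copy()
    adjusted.loc[sub.index] = y - design @ coef + y.mean()
    return adjusted


def bootstrap_pairwise(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 10_000,
    seed: int | None = None,
    *,
    measure: str = "",
    groups: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Percentile-bootstrap comparison of two group means.

    Resamples each group with replacement ``B`` times; reports the 95%
    percentile CI of the mean difference (x - y) and a two-sided p value
    ``min(1, 2 * min(P(diff <= 0), P(diff >= 0)))``.  The seed is required
    for reproducibility.
    """
    if B < 1000:
        raise ValueError(f"B must be >= 1000 for stable percentiles, got {B}")
    if seed is None:
        raise ValueError("a seed is required for a reproducible bootstrap")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(seed)
    bx = rng.integers(0, xa.size, size=(B, xa.size))
    by = rng.integers(0, ya.size, size=(B, ya.size))
    diffs = xa[bx].mean(axis=1) - ya[by].mean(axis=1)
    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = min(1.0, 2.0 * min(float(np.mean(diffs <= 0)), float(np.mean(diffs >= 0))))
    return GroupComparison(
        measure=measure, group_a=groups[0], group_b=groups[1],
        statistic=float(xa.mean() - ya.mean()), p_value=p, method="bootstrap",
        n_a=xa.size, n_b=ya.size, ci_low=float(ci_low), ci_high=float(ci_high),
    )


def anova_bonferroni(
    groups: dict[str, Sequence[float]],
    *,
    measure: str = "",
) -> tuple[GroupComparison, list[GroupComparison]]:
    """One-way ANOVA omnibus plus Bonferroni-corrected pairwise t-tests.

    Pairwise two-sample t-test p values are multiplied by the number of
    pairs and capped at 1, so an adjusted p is never below the raw one.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA with post-hoc needs >= 3 groups")
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = sps.f_oneway(*samples)
    omnibus = GroupComparison(
        measure=measure, group_a="all", group_b="all",
        statistic=float(f_stat), p_value=float(p_omni),
        method="anova", n_a=sum(s.size for s in samples), n_b=0,
    )
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            raw = two_sample_t(
                groups[a], groups[b], measure=measure, groups=(a, b)
            )
            pairwise.append(
                GroupComparison(
                    measure=measure, group_a=a, group_b=b,
                    statistic=raw.statistic,
                    p_value=min(1.0, raw.p_value * n_pairs),
                    method="anova_bonferroni", n_a=raw.n_a, n_b=raw.n_b,
                )
            )
    return omnibus, pairwise


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform), requiring variance in both."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValueError("correlation undefined for a zero-variance sample")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)
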