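"""Group-comparison statistics used throughout the study pipeline.

Two-sample comparisons are gated on normality: Shapiro-Wilk on each
group, then an unpaired two-sided t-test when both groups look normal
(Welch by default) and a two-sided Mann-Whitney U otherwise, with the
exact small-sample null where feasible.  Responder fractions are
compared with Fisher's exact test (probability-ordering two-sided
definition), and multiple testing is adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .iolib import ValidationError

__all__ = [
    "GroupComparison",
    "FisherResult",
    "compare_groups",
    "fisher_exact_2x2",
    "bh_fdr",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a normality-gated two-sample comparison."""

    test_used: str  # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float


def compare_groups(
    a, b, alpha: float = 0.05, equal_var: bool = False
) -> GroupComparison:
    """Compare two independent samples with the normality gate.

    Shapiro-Wilk is applied to each group; if both p-values exceed
    ``alpha`` an unpaired two-sided t-test is used (Welch unless
    ``equal_var``), otherwise a two-sided Mann-Whitney U.  A constant
    group (where the normality test is undefined) routes to
    Mann-Whitney with a note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("need at least 3 observations per group")
    note = ""
    try:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("constant input")
        p_norm_a = float(sps.shapiro(a).pvalue)
        p_norm_b = float(sps.shapiro(b).pvalue)
    except ValueError:
        p_norm_a = p_norm_b = 0.0
        note = "constant group: normality test undefined, using Mann-Whitney"
    if p_norm_a > alpha and p_norm_b > alpha:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(
            "t_test", float(res.statistic), float(res.pvalue),
            len(a), len(b), p_norm_a, p_norm_b, alpha, note,
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(
        "mann_whitney", float(res.statistic), float(res.pvalue),
        len(a), len(b), p_norm_a, p_norm_b, alpha, note,
    )


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test by the probability-ordering rule.

    The two-sided p-value sums the hypergeometric probabilities of every
    table with the observed margins whose probability does not exceed
    the observed table's (a relative slack of 1e-12 absorbs floating-
    point ties).  This matches the common software default; the
    alternative "double the one-sided p" definition differs and is not
    used.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0):
        raise ValidationError("cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValidationError("at least one margin must be positive")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(sps.hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return FisherResult(
        table=((a, b), (c, d)), p_two_sided=min(1.0, p),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    ``q_(i) = min_{j >= i} ( m * p_(j) / j )`` on the sorted p-values,
    mapped back to the input order; monotone in p-rank and >= p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
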