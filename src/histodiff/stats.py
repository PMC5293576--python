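"""Closed-form test statistics used across the pipeline.

The two-sample tests are written out from their closed forms (with
``scipy.special`` supplying the distribution functions) so they can be
cross-checked against an independent statistical implementation rather than
delegating to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special


def poisson_upper_tail(lam: float, k: float) -> float:
    """Upper-tail Poisson probability ``P(X >= ceil(k))`` for ``X ~ Poisson(lam)``.

    The inclusive tail is the standard enrichment convention.  Non-integer
    ``k`` is rounded up (a region containing "at least k" reads).  For
    ``lam == 0`` the distribution is a point mass at zero, so the tail is
    1 for ``k == 0`` and 0 otherwise.

    Computed through the regularized lower incomplete gamma function,
    ``P(X >= k) = P(k, lam)``, which is stable for large ``k``.
    """
    if lam < 0 or k < 0:
        raise ValueError("lam and k must be non-negative")
    k_int = math.ceil(k)
    if k_int == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(special.gammainc(k_int, lam))


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float


def welch_ttest(a, b) -> TTestResult:
    """Two-sample Welch (unequal-variance) t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs >= 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        # identical constant samples: no evidence of difference
        return TTestResult(0.0, float(na + nb - 2), 1.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return TTestResult(float(t), float(df), p)


def pooled_ttest(a, b) -> TTestResult:
    """Two-sample Student t-test with pooled variance, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se2 = sp2 * (1.0 / na + 1.0 / nb)
    if se2 == 0:
        return TTestResult(0.0, float(df), 1.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return TTestResult(float(t), float(df), p)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # standard normal z
    p_value: float


def ranksum_test(a, b) -> RankSumResult:
    """Wilcoxon rank-sum test, two-sided, normal approximation.

    Uses midranks for ties and no continuity or tie correction, matching
    the classical large-sample form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    r1 = ranks[:na].sum()
    expected = na * (na + nb + 1) / 2.0
    sd = math.sqrt(na * nb * (na + nb + 1) / 12.0)
    z = (r1 - expected) / sd
    p = 2.0 * float(special.ndtr(-abs(z)))
    return RankSumResult(float(z), p)


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN when either variable has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)
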