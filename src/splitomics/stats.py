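"""Statistical primitives shared by every analysis stage.

Exact hypergeometric over-representation tails, two-sample and k-group
location tests, multiplicity corrections and the critical Pearson
correlation threshold used to filter chemometric loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st
from scipy.special import logsumexp

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "hypergeometric_tail",
    "fold_enrichment",
    "welch_t_test",
    "one_way_anova",
    "adjust_pvalues",
    "critical_r",
]

_ADJUST_METHODS = ("benjamini_hochberg", "sidak", "bonferroni")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a location test.

    ``df`` is the Welch–Satterthwaite value for the t-test and the
    ``(between, within)`` pair for the one-way ANOVA.
    """

    statistic: float
    p_value: float
    df: float | tuple[float, float]


@dataclass(frozen=True)
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.adjusted):
            raise ValueError("raw and adjusted must have equal length")


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(
            f"overlap k out of hypergeometric support: k={k}, K={K}, n={n}, N={N}"
        )


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    One-sided over-representation probability of drawing at least ``k``
    of the ``K`` marked items in ``n`` draws without replacement from a
    population of ``N``.  Summed in log space so that extreme tails
    (down to ~1e-300) remain representable.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    _validate_counts(k, K, n, N)
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = _st.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Ratio of observed to expected overlap fraction, (k/n)/(K/N)."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    _validate_counts(k, K, n, N)
    if n == 0 or K == 0:
        raise ValueError(f"fold enrichment undefined for n={n}, K={K}")
    return (k / n) / (K / N)


def _as_sample(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 values, got {arr.size}")
    return arr


def welch_t_test(xs: Sequence[float], ys: Sequence[float]) -> TestResult:
    """Two-tailed Welch (unequal-variance) t-test.

    The statistic's sign follows ``mean(xs) - mean(ys)``.  Two constant,
    equal samples return p = 1 by convention; constant unequal samples
    return p = 0 (infinite separation on zero variance).
    """
    xs = _as_sample(xs, "xs")
    ys = _as_sample(ys, "ys")
    vx, vy = xs.var(ddof=1), ys.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xs.mean() == ys.mean():
            return TestResult(0.0, 1.0, float(xs.size + ys.size - 2))
        sign = np.sign(xs.mean() - ys.mean())
        return TestResult(float(sign * np.inf), 0.0, float(xs.size + ys.size - 2))
    res = _st.ttest_ind(xs, ys, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F-test across k groups."""
    if len(groups) < 2:
        raise ValueError("one_way_anova needs at least 2 groups")
    arrs = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    n_total = sum(a.size for a in arrs)
    df = (float(len(arrs) - 1), float(n_total - len(arrs)))
    if all(a.var(ddof=1) == 0.0 for a in arrs):
        means = {a.mean() for a in arrs}
        if len(means) == 1:
            return TestResult(0.0, 1.0, df)
        return TestResult(float(np.inf), 0.0, df)
    res = _st.f_oneway(*arrs)
    return TestResult(float(res.statistic), float(res.pvalue), df)


def adjust_pvalues(
    raw: Sequence[float],
    method: str = "benjamini_hochberg",
    m: int | None = None,
) -> AdjustedPValues:
    """Multiplicity-adjust p-values, preserving input order.

    ``m`` overrides the family size (defaults to ``len(raw)``); it is
    useful when only a subset of a larger comparison family is supplied.
    """
    p = np.asarray(raw, dtype=float).ravel()
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_ADJUST_METHODS}")
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("family size m cannot be smaller than len(raw)")
    if method == "bonferroni":
        adj = np.minimum(1.0, m * p)
    elif method == "sidak":
        adj = 1.0 - (1.0 - p) ** m
    else:  # Benjamini-Hochberg step-up
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        # enforce monotonicity from the largest p downwards
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.minimum(1.0, stepped)
    adj = np.maximum(adj, p)  # an adjustment never helps
    return AdjustedPValues(raw=p, adjusted=adj, method=method)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |Pearson r| significant two-tailed at level alpha, df = n - 2.

    r* = t* / sqrt(t*^2 + n - 2) with t* the two-tailed t critical value.
    """
    n = int(n)
    if n < 3:
        raise ValueError("critical_r requires n >= 3 (df = n - 2 > 0)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    df = n - 2
    t_star = _st.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / np.sqrt(t_star**2 + df))
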