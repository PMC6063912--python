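"""Two-group differential expression on log2 intensity matrices.

The expression matrix is a genes x samples :class:`pandas.DataFrame` of
log2 intensities; the design is a sample -> group mapping with exactly
two levels.  Fold change is computed treated-minus-reference on the log2
scale and each gene is tested with a Welch t-test, yielding the up /
down / unchanged dichotomy used by the enrichment and network stages.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.base import BaseEstimator

from .stats import adjust_pvalues

__all__ = ["DifferentialExpression", "compute_fold_change", "call_degs", "validate_design"]


def validate_design(
    expr: pd.DataFrame, groups: Mapping[str, str] | pd.Series, reference: str | None
) -> tuple[pd.Series, str, str]:
    """Check the two-group design and return (groups, reference, treated)."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    missing = [s for s in expr.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    groups = groups.loc[expr.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not among {levels}")
    treated = next(l for l in levels if l != reference)
    for level in levels:
        if (groups == level).sum() < 2:
            raise ValueError(f"group {level!r} has fewer than 2 samples")
    return groups, reference, treated


def compute_fold_change(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    gene: str,
    reference: str | None = None,
) -> tuple[float, float]:
    """Linear and log2 fold change (treated minus reference) for one gene."""
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    groups, reference, treated = validate_design(expr, groups, reference)
    row = expr.loc[gene]
    log2fc = float(row[groups == treated].mean() - row[groups == reference].mean())
    return 2.0**log2fc, log2fc


class DifferentialExpression(BaseEstimator):
    """Welch-t DEG caller with a symmetric fold-change filter.

    A gene is called significant when the chosen p-value (raw or
    BH-adjusted) is below ``p_threshold`` AND ``max(FC, 1/FC)`` is at
    least ``fc_threshold``; significant genes split into ``up`` and
    ``down`` by the sign of the log2 fold change.

    Parameters
    ----------
    p_threshold : float
        Significance cut-off in (0, 1).
    fc_threshold : float
        Symmetric linear fold-change cut-off, >= 1 (1 disables the filter).
    use_adjusted : bool
        Gate significance on the BH-adjusted p instead of the raw p.
        Both columns are always reported.
    reference : str or None
        Reference (control) group level; defaults to the
        lexicographically first level.  Fold change is treated minus
        reference.

    Attributes
    ----------
    table_ : pandas.DataFrame
        Per-gene columns ``log2fc, fc, p, p_bh, direction``.
    up_, down_, unchanged_ : set of str
        The dichotomy; the three sets partition the gene universe.
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        fc_threshold: float = 1.5,
        use_adjusted: bool = False,
        reference: str | None = None,
    ):
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.use_adjusted = use_adjusted
        self.reference = reference

    def fit(self, X: pd.DataFrame, y: Mapping[str, str] | pd.Series):
        """Fit on a genes x samples log2 matrix ``X`` with design ``y``."""
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1 (symmetric linear FC)")
        groups, reference, treated = validate_design(X, y, self.reference)
        a = X.loc[:, (groups == reference).values].to_numpy(float)
        b = X.loc[:, (groups == treated).values].to_numpy(float)
        log2fc = b.mean(axis=1) - a.mean(axis=1)
        res = _st.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: p undefined under Welch; treat equal
        # means as null (p = 1) and unequal as maximally significant
        degenerate = np.isnan(p)
        p[degenerate & (log2fc == 0.0)] = 1.0
        p[degenerate & (log2fc != 0.0)] = 0.0
        p_bh = adjust_pvalues(p, "benjamini_hochberg").adjusted
        gate = p_bh if self.use_adjusted else p
        fc = 2.0**log2fc
        sig = (gate < self.p_threshold) & (
            np.maximum(fc, 1.0 / fc) >= self.fc_threshold
        )
        direction = np.where(~sig, "unchanged", np.where(log2fc > 0, "up", "down"))
        self.table_ = pd.DataFrame(
            {"log2fc": log2fc, "fc": fc, "p": p, "p_bh": p_bh, "direction": direction},
            index=X.index.copy(),
        )
        self.reference_, self.treated_ = reference, treated
        self.up_ = set(self.table_.index[direction == "up"])
        self.down_ = set(self.table_.index[direction == "down"])
        self.unchanged_ = set(self.table_.index[direction == "unchanged"])
        return self


def call_degs(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    use_adjusted: bool = False,
    reference: str | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialExpression`."""
    model = DifferentialExpression(p_threshold, fc_threshold, use_adjusted, reference)
    return model.fit(expr, groups).table_
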