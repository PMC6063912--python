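"""Chemometrics for binned 1H-NMR spectra.

Unit-variance scaling, PCA, single-response orthogonal PLS (O-PLS)
discriminant analysis with stratified k-fold Q2Y, Y-permutation
significance, back-scaled correlation loadings filtered at the critical
Pearson correlation, spectral-region integration and multiplicity-
corrected group comparison of the integrals.

The O-PLS model follows the classical single-y algorithm: the predictive
weight vector is proportional to X'y, and each orthogonal component is
extracted from the predictive loading after removing its projection on
the predictive weight, then deflated from X.  With zero orthogonal
components the model reduces exactly to one-component NIPALS PLS1.
Matrices are expected column-centred (and typically unit-variance
scaled) before fitting; cross-validation refits the scaling inside each
training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

from .stats import TestResult, adjust_pvalues, critical_r, one_way_anova, welch_t_test

__all__ = [
    "Spectra",
    "SpectraScaler",
    "OPLS",
    "PermutationResult",
    "encode_dummy",
    "pca",
    "cross_validated_q2",
    "permutation_test",
    "correlation_loadings",
    "integrate_region",
    "compare_integrals",
    "total_area_normalise",
]


@dataclass
class Spectra:
    """Binned spectra: samples x chemical-shift bins with a ppm axis.

    ``ppm`` is strictly descending (plotting convention); ``intensities``
    rows are samples, columns are bins; ``labels`` optionally maps each
    sample to its class/group.
    """

    ppm: np.ndarray
    intensities: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float).ravel()
        if self.ppm.size != self.intensities.shape[1]:
            raise ValueError(
                f"ppm axis length {self.ppm.size} != bin count "
                f"{self.intensities.shape[1]}"
            )
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")
        if self.intensities.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        if self.labels is not None:
            missing = [s for s in self.intensities.index if s not in self.labels.index]
            if missing:
                raise ValueError(f"samples without a class label: {missing}")
            self.labels = self.labels.loc[self.intensities.index]

    @property
    def X(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)


def encode_dummy(labels: Sequence) -> tuple[np.ndarray, tuple]:
    """Encode two class labels as a -1/+1 dummy response.

    Levels are sorted; the first maps to -1, the second to +1.  Returns
    the dummy vector and the (minus, plus) level pair.
    """
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly two classes required, found {levels}")
    y = np.where(labels == levels[1], 1.0, -1.0)
    return y, (levels[0], levels[1])


class SpectraScaler(BaseEstimator, TransformerMixin):
    """Column mean-centring and unit-variance scaling with exact inverse.

    Zero-variance bins are dropped from the transformed output and
    recorded in ``dropped_``; ``inverse_transform`` restores the full
    bin set (dropped bins are constant, so the round trip is exact).
    """

    def __init__(self, center: bool = True, uv: bool = True):
        self.center = center
        self.uv = uv

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 samples")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.kept_ = self.scale_ > 0.0
        self.dropped_ = np.flatnonzero(~self.kept_)
        if not self.kept_.any():
            raise ValueError("all bins have zero variance; no usable data")
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = X[:, self.kept_]
        if self.center:
            Z = Z - self.mean_[self.kept_]
        if self.uv:
            Z = Z / self.scale_[self.kept_]
        return Z

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        X = np.empty((Z.shape[0], self.kept_.size), dtype=float)
        W = Z * self.scale_[self.kept_] if self.uv else Z.copy()
        if self.center:
            W = W + self.mean_[self.kept_]
        X[:, self.kept_] = W
        X[:, ~self.kept_] = self.mean_[~self.kept_]
        return X


class OPLS(BaseEstimator, RegressorMixin):
    """Single-response orthogonal PLS with one predictive component.

    Parameters
    ----------
    n_orth : int
        Number of y-orthogonal components removed from X before the
        predictive component is extracted.  0 gives plain NIPALS PLS1.

    Attributes
    ----------
    weights_ : (p,) predictive weight vector (unit norm).
    scores_ : (n,) predictive scores t.
    loadings_ : (p,) predictive loadings.
    q_ : float, regression coefficient of centred y on t.
    W_orth_, P_orth_ : (p, n_orth) orthogonal weights / loadings.
    T_orth_ : (n, n_orth) orthogonal scores (zero correlation with y).
    residual_ : (n, p) matrix left after predictive + orthogonal parts.
    r2y_ : float, fraction of y variance explained on training data.
    """

    def __init__(self, n_orth: int = 1):
        self.n_orth = n_orth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if np.unique(y).size < 2:
            raise ValueError("y must contain both classes (two distinct values)")
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_
        Xd = X.copy()
        w = Xd.T @ yc
        w = w / np.linalg.norm(w)
        W_o, P_o, T_o = [], [], []
        for _ in range(self.n_orth):
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:  # no orthogonal variation left
                break
            w_o /= norm
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)
        t = Xd @ w
        tt = t @ t
        if tt <= 0.0:
            raise ValueError("predictive score has zero variance")
        self.weights_ = w
        self.scores_ = t
        self.loadings_ = Xd.T @ t / tt
        self.q_ = float(yc @ t / tt)
        self.W_orth_ = np.column_stack(W_o) if W_o else np.empty((X.shape[1], 0))
        self.P_orth_ = np.column_stack(P_o) if P_o else np.empty((X.shape[1], 0))
        self.T_orth_ = np.column_stack(T_o) if T_o else np.empty((X.shape[0], 0))
        self.residual_ = Xd - np.outer(t, self.loadings_)
        y_fit = t * self.q_ + self.y_mean_
        ss = float(yc @ yc)
        self.r2y_ = 1.0 - float(np.sum((y - y_fit) ** 2)) / ss if ss > 0 else 0.0
        return self

    def _filter(self, X: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal components from new data."""
        Xd = np.asarray(X, dtype=float).copy()
        for j in range(self.T_orth_.shape[1]):
            t_o = Xd @ self.W_orth_[:, j]
            Xd -= np.outer(t_o, self.P_orth_[:, j])
        return Xd

    def transform(self, X) -> np.ndarray:
        """Predictive score of new (already scaled) samples."""
        return self._filter(X) @ self.weights_

    def predict(self, X) -> np.ndarray:
        """Continuous prediction of the -1/+1 dummy response."""
        return self.transform(X) * self.q_ + self.y_mean_


def pca(X, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a scaled matrix.

    Returns (scores, loadings, explained variance fractions); loadings
    are orthonormal columns.
    """
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must lie in [1, {limit}]")
    model = _SkPCA(n_components=n_components)
    scores = model.fit_transform(X)
    return scores, model.components_.T, model.explained_variance_ratio_


def _check_folds(y: np.ndarray, k_folds: int) -> None:
    counts = pd.Series(y).value_counts()
    if k_folds < 2 or k_folds > counts.min():
        raise ValueError(
            f"k_folds={k_folds} incompatible with class counts {counts.to_dict()}; "
            "every training fold must contain both classes"
        )


def cross_validated_q2(
    X,
    y,
    n_orth: int = 1,
    k_folds: int = 8,
    fold_seed: int = 0,
    center: bool = True,
    uv: bool = True,
) -> float:
    """Q2Y = 1 - PRESS/SS from stratified k-fold cross-validation.

    ``X`` is the raw (unscaled) matrix: centring/scaling is refit on
    each training fold so no information leaks into the held-out
    samples.  Deterministic for a fixed ``fold_seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_folds(y, k_folds)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=fold_seed)
    press = 0.0
    for train, test in skf.split(X, y):
        scaler = SpectraScaler(center=center, uv=uv).fit(X[train])
        model = OPLS(n_orth=n_orth).fit(scaler.transform(X[train]), y[train])
        y_hat = model.predict(scaler.transform(X[test]))
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    q2_observed: float
    q2_permuted: np.ndarray


def permutation_test(
    X,
    y,
    n_orth: int = 1,
    n_permutations: int = 1000,
    seed: int = 0,
    k_folds: int = 8,
    center: bool = True,
    uv: bool = True,
) -> PermutationResult:
    """Y-permutation significance of the cross-validated Q2Y.

    The class dummy is permuted ``n_permutations`` times and Q2Y is
    recomputed for each; p = (1 + #{Q2_perm >= Q2_obs}) / (B + 1), which
    can never return zero.  Deterministic for a fixed ``seed`` (also
    used to seed the fold assignment).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    kwargs = dict(n_orth=n_orth, k_folds=k_folds, fold_seed=seed, center=center, uv=uv)
    q2_obs = cross_validated_q2(X, y, **kwargs)
    rng = np.random.default_rng(seed)
    q2_perm = np.empty(n_permutations)
    for b in range(n_permutations):
        q2_perm[b] = cross_validated_q2(X, rng.permutation(y), **kwargs)
    p = (1.0 + np.count_nonzero(q2_perm >= q2_obs)) / (n_permutations + 1.0)
    return PermutationResult(float(p), float(q2_obs), q2_perm)


def correlation_loadings(
    model: OPLS,
    X_raw,
    ppm: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Back-scaled correlation loadings of the fitted predictive score.

    Per bin: Pearson r between the raw intensities and the predictive
    score, its square, and the back-scaled coefficient r * sd(bin) —
    covariance-shaped so the trace keeps the spectral line shape and the
    sign of the association.  ``significant`` flags |r| above the
    critical correlation for the model's sample count at level alpha.
    Zero-variance bins get r = 0 and are never significant.
    """
    X = np.asarray(X_raw, dtype=float)
    t = model.scores_
    if X.shape[0] != t.size:
        raise ValueError("X_raw must contain the samples the model was fitted on")
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    cov = Xc.T @ tc / (t.size - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sd > 0, cov / (sd * t.std(ddof=1)), 0.0)
    r = np.clip(r, -1.0, 1.0)
    r_star = critical_r(t.size, alpha)
    out = pd.DataFrame(
        {
            "r": r,
            "r2": r**2,
            "backscaled": r * sd,
            "significant": np.abs(r) > r_star,
        }
    )
    if ppm is not None:
        out.insert(0, "ppm", np.asarray(ppm, dtype=float))
    out.attrs["critical_r"] = r_star
    return out


def _region_slice(ppm: np.ndarray, ppm_hi: float, ppm_lo: float) -> np.ndarray:
    if ppm_hi <= ppm_lo:
        raise ValueError("require ppm_hi > ppm_lo")
    idx = np.flatnonzero((ppm <= ppm_hi) & (ppm >= ppm_lo))
    if idx.size < 2:
        raise ValueError(
            f"region [{ppm_lo}, {ppm_hi}] covers {idx.size} bins; need >= 2"
        )
    return idx


def integrate_region(spectra: Spectra, ppm_hi: float, ppm_lo: float) -> pd.Series:
    """Trapezoidal area of each sample over [ppm_lo, ppm_hi] (positive)."""
    idx = _region_slice(spectra.ppm, ppm_hi, ppm_lo)
    x = spectra.ppm[idx][::-1]  # ascending for integration
    Y = spectra.X[:, idx][:, ::-1]
    areas = np.trapezoid(Y, x, axis=1)
    return pd.Series(areas, index=spectra.intensities.index, name="area")


def compare_integrals(
    areas: pd.Series,
    groups: Mapping[str, str] | pd.Series,
    comparisons: Iterable[tuple[str, str]],
    method: str = "sidak",
    alpha: float = 0.05,
) -> tuple[TestResult, pd.DataFrame]:
    """Omnibus ANOVA plus adjusted pairwise Welch tests on named pairs."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[areas.index]
    levels = list(pd.unique(groups))
    comparisons = list(comparisons)
    for a, b in comparisons:
        if a not in levels or b not in levels:
            raise ValueError(f"comparison ({a!r}, {b!r}) names an unknown group")
    omnibus = one_way_anova([areas[groups == g].to_numpy() for g in levels])
    raw = [
        welch_t_test(areas[groups == a].to_numpy(), areas[groups == b].to_numpy()).p_value
        for a, b in comparisons
    ]
    adj = adjust_pvalues(raw, method).adjusted
    table = pd.DataFrame(
        {
            "group_a": [a for a, _ in comparisons],
            "group_b": [b for _, b in comparisons],
            "p": raw,
            "p_adjusted": adj,
            "significant": adj < alpha,
        }
    )
    return omnibus, table


def total_area_normalise(spectra: Spectra) -> Spectra:
    """Scale each spectrum to unit total (trapezoidal) area.

    Optional utility for removing sample-level dilution; off by default
    in every pipeline entry point.
    """
    x = spectra.ppm[::-1]
    areas = np.trapezoid(spectra.X[:, ::-1], x, axis=1)
    if np.any(areas <= 0):
        raise ValueError("non-positive total area; cannot normalise")
    scaled = spectra.intensities.div(areas, axis=0)
    return Spectra(spectra.ppm.copy(), scaled, spectra.labels)
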