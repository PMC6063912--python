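"""Chemometrics: scaling, PCA, O-PLS definitional properties, Q2Y,
permutation significance, correlation loadings and region integration."""

import dataclasses as dc

import numpy as np
import pandas as pd
import pytest

from splitomics import (
    OPLS,
    Spectra,
    SpectraScaler,
    compare_integrals,
    correlation_loadings,
    critical_r,
    cross_validated_q2,
    encode_dummy,
    integrate_region,
    pca,
    permutation_test,
    total_area_normalise,
)
from splitomics.simulate import default_spectra_truth, generate_spectra


def nipals_pls1(X, y):
    """Independent one-component PLS1 oracle (textbook NIPALS)."""
    yc = y - y.mean()
    w = X.T @ yc
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = yc @ t / (t @ t)
    return w, t, p, q


@pytest.fixture
def random_Xy():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(20, 100))
    X -= X.mean(axis=0)
    y = np.repeat([-1.0, 1.0], 10)
    return X, y


class TestSpectraScaler:
    def test_round_trip(self, random_Xy):
        X, _ = random_Xy
        scaler = SpectraScaler().fit(X)
        assert scaler.inverse_transform(scaler.transform(X)) == pytest.approx(
            X, abs=1e-10
        )

    def test_centred_and_unit_variance(self, random_Xy):
        X, _ = random_Xy
        Z = SpectraScaler().fit(X).transform(X)
        assert Z.mean(axis=0) == pytest.approx(0.0, abs=1e-12)
        assert Z.std(axis=0, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_already_centred_sd_only(self, random_Xy):
        X, _ = random_Xy
        Z = SpectraScaler(center=False).fit(X).transform(X)
        assert Z.mean(axis=0) == pytest.approx(X.mean(axis=0) / X.std(axis=0, ddof=1))

    def test_constant_bin_dropped_and_recorded(self, random_Xy):
        X, _ = random_Xy
        X = X.copy()
        X[:, 7] = 3.14
        scaler = SpectraScaler().fit(X)
        assert list(scaler.dropped_) == [7]
        assert scaler.transform(X).shape[1] == X.shape[1] - 1
        assert scaler.inverse_transform(scaler.transform(X)) == pytest.approx(
            X, abs=1e-10
        )

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            SpectraScaler().fit(np.ones((5, 4)))


class TestPCA:
    def test_rank_one_explains_everything(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=12), rng.normal(size=30))
        _, _, evr = pca(X - X.mean(axis=0), 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_orthonormal_loadings(self, random_Xy):
        X, _ = random_Xy
        _, loadings, _ = pca(X, 5)
        assert loadings.T @ loadings == pytest.approx(np.eye(5), abs=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 30))
        Xc = X - X.mean(axis=0)
        scores, loadings, evr = pca(X, 3)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            # agreement within sign
            assert abs(loadings[:, j] @ evecs[:, j]) == pytest.approx(1.0, abs=1e-8)
        assert evr == pytest.approx(evals[:3] / evals.sum(), abs=1e-10)

    def test_component_limit(self, random_Xy):
        X, _ = random_Xy
        with pytest.raises(ValueError):
            pca(X, 25)

    def test_pc1_separates_classes_when_effect_dominates(self):
        """With a dominant planted effect (quadrupled metabolite, no
        dilution nuisance) PC1 of the scaled spectra tracks class."""
        truth = dc.replace(
            default_spectra_truth(effects={"bile_acid": 4.0}),
            dilution_range=(1.0, 1.0),
        )
        spectra, _ = generate_spectra(truth=truth, seed=11)
        y, _ = encode_dummy(spectra.labels.values)
        Z = SpectraScaler().fit(spectra.X).transform(spectra.X)
        scores, _, _ = pca(Z, 2)
        assert abs(np.corrcoef(scores[:, 0], y)[0, 1]) > 0.7


class TestOPLS:
    def test_north_zero_reduces_to_nipals_pls1(self, random_Xy):
        X, y = random_Xy
        model = OPLS(n_orth=0).fit(X, y)
        w, t, p, q = nipals_pls1(X, y)
        assert model.scores_ == pytest.approx(t, abs=1e-10)
        assert model.weights_ == pytest.approx(w, abs=1e-10)
        assert model.loadings_ == pytest.approx(p, abs=1e-10)
        assert model.q_ == pytest.approx(q, abs=1e-10)

    @pytest.mark.parametrize("n_orth", [1, 2, 3])
    def test_orthogonal_scores_uncorrelated_with_y(self, random_Xy, n_orth):
        X, y = random_Xy
        model = OPLS(n_orth=n_orth).fit(X, y)
        yc = y - y.mean()
        for j in range(model.T_orth_.shape[1]):
            t_o = model.T_orth_[:, j]
            r = abs(t_o @ yc) / (np.linalg.norm(t_o) * np.linalg.norm(yc))
            assert r < 1e-8

    def test_deflation_conserves_X(self, random_Xy):
        X, y = random_Xy
        model = OPLS(n_orth=2).fit(X, y)
        recon = (
            model.T_orth_ @ model.P_orth_.T
            + np.outer(model.scores_, model.loadings_)
            + model.residual_
        )
        assert recon == pytest.approx(X, abs=1e-8)

    def test_orthogonal_confounder_removed_exactly(self):
        """A y-orthogonal structured component added to a predictive
        structure leaves the predictive loadings unchanged once one
        orthogonal component is removed — the defining O-PLS property."""
        rng = np.random.default_rng(3)
        y = np.repeat([-1.0, 1.0], 10)
        yc = y - y.mean()
        t = yc + rng.normal(0, 0.3, 20)
        t -= t.mean()
        w_true = rng.normal(size=100)
        w_true /= np.linalg.norm(w_true)
        X = np.outer(t, w_true)  # pure predictive structure
        c = rng.normal(size=20)
        c -= (c @ yc) / (yc @ yc) * yc  # confounder scores exactly y-orthogonal
        c -= c.mean()
        v = rng.normal(size=100)
        v -= (v @ w_true) * w_true  # confounder profile off the predictive axis
        base = OPLS(n_orth=0).fit(X, y)
        cleaned = OPLS(n_orth=1).fit(X + np.outer(c, v) * 5.0, y)
        assert abs(base.weights_ @ cleaned.weights_) == pytest.approx(1.0, abs=1e-10)
        assert cleaned.loadings_ == pytest.approx(base.loadings_, abs=1e-6)

    def test_confounder_weights_invariant_on_random_data(self, random_Xy):
        """On arbitrary data the predictive weight vector is untouched by a
        y-orthogonal confounder (w is proportional to X'y)."""
        X, y = random_Xy
        rng = np.random.default_rng(4)
        yc = y - y.mean()
        c = rng.normal(size=20)
        c -= (c @ yc) / (yc @ yc) * yc
        X_conf = X + np.outer(c, rng.normal(size=100)) * 5.0
        base = OPLS(n_orth=0).fit(X, y)
        cleaned = OPLS(n_orth=1).fit(X_conf, y)
        assert abs(base.weights_ @ cleaned.weights_) == pytest.approx(1.0, abs=1e-6)

    def test_perfect_separation_r2y_one(self):
        X = np.zeros((10, 5))
        X[5:, 0] = 1.0
        X -= X.mean(axis=0)
        y = np.repeat([-1.0, 1.0], 5)
        assert OPLS(n_orth=0).fit(X, y).r2y_ == pytest.approx(1.0)

    def test_single_class_rejected(self, random_Xy):
        X, _ = random_Xy
        with pytest.raises(ValueError):
            OPLS().fit(X, np.ones(20))


class TestCrossValidation:
    def test_single_informative_bin_q2_near_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 50)) * 1e-9  # negligible background
        y = np.repeat([-1.0, 1.0], 8)
        X[:, 10] = y * 2.0
        q2 = cross_validated_q2(X, y, n_orth=0, k_folds=8, fold_seed=0, uv=False)
        assert q2 == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_fold_seed(self, random_Xy):
        X, y = random_Xy
        a = cross_validated_q2(X + 5.0, y, fold_seed=3)
        b = cross_validated_q2(X + 5.0, y, fold_seed=3)
        assert a == b

    def test_planted_effect_strong_q2(self):
        spectra, truth = generate_spectra(
            truth=None, seed=0
        )
        y, _ = encode_dummy(spectra.labels.values)
        q2 = cross_validated_q2(spectra.X, y, n_orth=1, fold_seed=0)
        assert q2 > 0.5

    def test_permuted_labels_low_q2(self):
        spectra, _ = generate_spectra(seed=1)
        y, _ = encode_dummy(spectra.labels.values)
        rng = np.random.default_rng(5)
        q2s = [
            cross_validated_q2(spectra.X, rng.permutation(y), fold_seed=0)
            for _ in range(20)
        ]
        assert np.mean(q2s) < 0.1

    def test_fold_validation(self, random_Xy):
        X, y = random_Xy
        with pytest.raises(ValueError):
            cross_validated_q2(X, y, k_folds=11)


class TestPermutation:
    def test_minimum_p_forced_by_formula(self):
        spectra, _ = generate_spectra(seed=0)
        y, _ = encode_dummy(spectra.labels.values)
        res = permutation_test(spectra.X, y, n_permutations=49, seed=0)
        if not np.any(res.q2_permuted >= res.q2_observed):
            assert res.p_value == pytest.approx(1.0 / 50.0)
        assert res.p_value >= 1.0 / 50.0

    def test_deterministic_given_seed(self):
        spectra, _ = generate_spectra(n_per_class=8, n_bins=250, seed=2)
        y, _ = encode_dummy(spectra.labels.values)
        a = permutation_test(spectra.X, y, n_permutations=20, seed=7)
        b = permutation_test(spectra.X, y, n_permutations=20, seed=7)
        assert a.p_value == b.p_value
        assert a.q2_permuted == pytest.approx(b.q2_permuted)

    def test_invalid_b(self, random_Xy):
        X, y = random_Xy
        with pytest.raises(ValueError):
            permutation_test(X, y, n_permutations=0)


class TestCorrelationLoadings:
    def test_bin_identical_to_score_r_one(self, random_Xy):
        X, y = random_Xy
        model = OPLS(n_orth=0).fit(X, y)
        X_aug = X.copy()
        X_aug[:, 0] = model.scores_
        table = correlation_loadings(model, X_aug)
        assert table.loc[0, "r"] == pytest.approx(1.0)
        assert bool(table.loc[0, "significant"])

    def test_backscaled_is_r_times_sd(self, random_Xy):
        X, y = random_Xy
        model = OPLS(n_orth=1).fit(X, y)
        table = correlation_loadings(model, X)
        sd = X.std(axis=0, ddof=1)
        assert table["backscaled"].to_numpy() == pytest.approx(
            table["r"].to_numpy() * sd
        )

    def test_zero_variance_bin_not_significant(self, random_Xy):
        X, y = random_Xy
        X = X.copy()
        X[:, 3] = 0.0
        model = OPLS(n_orth=0).fit(SpectraScaler().fit(X).transform(X), y)
        # loadings computed against raw X including the flat bin
        table = correlation_loadings(model, X)
        assert table.loc[3, "r"] == 0.0 and not bool(table.loc[3, "significant"])

    def test_threshold_matches_critical_r(self, random_Xy):
        X, y = random_Xy
        model = OPLS(n_orth=0).fit(X, y)
        table = correlation_loadings(model, X, alpha=0.05)
        r_star = critical_r(20, 0.05)
        assert table.attrs["critical_r"] == pytest.approx(r_star)
        assert (
            (table["r"].abs() > r_star) == table["significant"]
        ).all()


class TestIntegration:
    def _flat_spectra(self, c=2.0):
        ppm = np.linspace(5.0, 1.0, 401)
        X = pd.DataFrame(np.full((3, 401), c), index=["s1", "s2", "s3"])
        return Spectra(ppm, X)

    def test_constant_area(self):
        spectra = self._flat_spectra(c=2.0)
        areas = integrate_region(spectra, 4.0, 3.0)
        assert areas.to_numpy() == pytest.approx(2.0 * 1.0)

    def test_adjacent_regions_additive(self):
        spectra, _ = generate_spectra(seed=3)
        # split exactly at a bin centre so the union shares a grid point
        mid = float(spectra.ppm[150])  # ~5.8 ppm
        whole = integrate_region(spectra, 8.0, 2.0)
        left = integrate_region(spectra, 8.0, mid)
        right = integrate_region(spectra, mid, 2.0)
        assert (left + right).to_numpy() == pytest.approx(whole.to_numpy(), rel=1e-9)

    def test_empty_overlap_rejected(self):
        spectra = self._flat_spectra()
        with pytest.raises(ValueError):
            integrate_region(spectra, 9.0, 8.0)
        with pytest.raises(ValueError):
            integrate_region(spectra, 2.0, 3.0)

    def test_total_area_normalise_removes_dilution(self):
        spectra, _ = generate_spectra(seed=4)
        normed = total_area_normalise(spectra)
        areas = integrate_region(normed, float(normed.ppm[0]), float(normed.ppm[-1]))
        assert areas.to_numpy() == pytest.approx(1.0, rel=1e-9)


class TestCompareIntegrals:
    def _areas(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(shift, 1, 8), rng.normal(0, 1, 8)]
        )
        idx = [f"s{i}" for i in range(24)]
        groups = pd.Series(["g1"] * 8 + ["g2"] * 8 + ["g3"] * 8, index=idx)
        return pd.Series(vals, index=idx), groups

    def test_shifted_group_flagged(self):
        areas, groups = self._areas(shift=5.0)
        omnibus, table = compare_integrals(
            areas, groups, [("g1", "g2"), ("g1", "g3")], method="sidak"
        )
        assert omnibus.p_value < 1e-6
        row = table.set_index(["group_a", "group_b"])
        assert bool(row.loc[("g1", "g2"), "significant"])
        assert not bool(row.loc[("g1", "g3"), "significant"])

    def test_single_comparison_sidak_identity(self):
        areas, groups = self._areas(shift=1.0)
        _, table = compare_integrals(areas, groups, [("g1", "g2")], method="sidak")
        assert table.loc[0, "p_adjusted"] == pytest.approx(table.loc[0, "p"])

    def test_null_calibration(self):
        hits = 0
        for seed in range(40):
            areas, groups = self._areas(shift=0.0, seed=seed)
            _, table = compare_integrals(
                areas, groups, [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
            )
            hits += int(table["significant"].any())
        # familywise alpha=0.05 over 40 null runs: generous binomial bound
        assert hits <= 7

    def test_unknown_group_rejected(self):
        areas, groups = self._areas()
        with pytest.raises(ValueError):
            compare_integrals(areas, groups, [("g1", "nope")])
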