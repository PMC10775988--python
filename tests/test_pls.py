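import numpy as np
import pytest

from mrpl import standardize
from mrpl.pls import (cross_validate_components, fit_pls, jackknife_snp_test,
                      pls_predict)


def _nipals_oracle(G, X, r):
    """Power-iteration NIPALS reference: same recursion, different solver."""
    Gd, Xd = G.copy(), X.copy()
    P = []
    Gamma = []
    for _ in range(r):
        A = Gd.T @ Xd
        rho = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
        for _ in range(2000):
            new = A @ (A.T @ rho)
            new /= np.linalg.norm(new)
            if np.linalg.norm(new - rho) < 1e-14 or np.linalg.norm(new + rho) < 1e-14:
                rho = new
                break
            rho = new
        theta = np.linalg.norm(A.T @ rho)
        gamma = A.T @ rho / theta
        u = Gd @ rho
        nu = u @ u
        sigma = Gd.T @ u / nu
        tau = Xd.T @ u / nu
        Gd = Gd - np.outer(u, sigma)
        Xd = Xd - np.outer(u, tau)
        P.append(rho)
        Gamma.append(gamma)
    return np.array(P).T, np.array(Gamma).T


class TestFitPls:
    def test_single_snp_single_exposure_is_ols(self, rng):
        G = standardize(rng.normal(size=(50, 1)))
        X = standardize(0.6 * G + rng.normal(size=(50, 1)))
        fit = fit_pls(G, X, r=1)
        slope = np.linalg.lstsq(G, X, rcond=None)[0].item()
        assert abs(fit.C.item() - slope) < 1e-10

    def test_full_rank_equals_ols_projection(self, rng):
        G = standardize(rng.normal(size=(40, 5)))
        X = standardize(rng.normal(size=(40, 3)) + G[:, :2] @ rng.normal(size=(2, 3)))
        fit = fit_pls(G, X, r=5)
        ols = G @ np.linalg.lstsq(G, X, rcond=None)[0]
        assert np.abs(G @ fit.C - ols).max() < 1e-8

    def test_matches_nipals_power_iteration_oracle(self, rng):
        G = standardize(rng.normal(size=(30, 4)))
        X = standardize(rng.normal(size=(30, 2)) + G[:, :2] @ rng.normal(size=(2, 2)))
        fit = fit_pls(G, X, r=3)
        P_o, Gamma_o = _nipals_oracle(G, X, 3)
        for i in range(3):  # loadings agree up to sign
            assert (np.abs(fit.P[:, i] - P_o[:, i]).max() < 1e-6
                    or np.abs(fit.P[:, i] + P_o[:, i]).max() < 1e-6)

    def test_loadings_unit_norm_and_sign_fixed(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=3)
        assert np.allclose(np.linalg.norm(fit.P, axis=0), 1.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(fit.Gamma, axis=0), 1.0, atol=1e-10)
        for i in range(fit.r):
            assert fit.P[np.argmax(np.abs(fit.P[:, i])), i] > 0

    def test_scores_mutually_orthogonal(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=4)
        gram = fit.U.T @ fit.U
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * small_data.n

    def test_coefficient_formula_reproduced(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=3)
        core = np.linalg.pinv(fit.Sigma.T @ fit.P, rcond=1e-10)
        assert np.abs(fit.C - fit.P @ core @ fit.T.T).max() < 1e-8

    def test_explained_variance_non_decreasing_in_r(self, small_data):
        sse = []
        fit = fit_pls(small_data.G, small_data.X, r=5)
        for r in range(1, 6):
            resid = small_data.X - small_data.G @ fit.coefficients(r)
            sse.append(np.sum(resid ** 2))
        assert np.all(np.diff(sse) <= 1e-8)

    def test_rank_exhaustion_truncates_with_warning(self, rng):
        base = standardize(rng.normal(size=(40, 2)))
        G = np.hstack([base, base])            # rank 2
        X = standardize(rng.normal(size=(40, 3)) + base @ rng.normal(size=(2, 3)))
        with pytest.warns(UserWarning, match="truncated"):
            fit = fit_pls(G, X, r=4)
        assert fit.r == 2

    def test_r_out_of_range_rejected(self, small_data):
        with pytest.raises(ValueError):
            fit_pls(small_data.G, small_data.X, r=small_data.n + 5)


class TestCrossValidation:
    def test_noise_free_low_rank_recovered(self, rng):
        # instruments span a 3-dimensional space; exposures are exact
        # linear functions of it, so CV error vanishes from r = 3 on and
        # the tie rule picks r = 3
        base = standardize(rng.normal(size=(60, 3)))
        G = np.hstack([base, base])
        X = base @ rng.normal(size=(3, 4))
        with pytest.warns(UserWarning, match="truncated"):
            r_opt, curve = cross_validate_components(G, X, folds=10, max_r=5, seed=0)
        assert r_opt == 3
        assert curve[2] < 1e-6

    def test_same_seed_reproducible(self, small_data):
        a = cross_validate_components(small_data.G, small_data.X, seed=7)
        b = cross_validate_components(small_data.G, small_data.X, seed=7)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])

    def test_too_few_folds_rejected(self, small_data):
        with pytest.raises(ValueError):
            cross_validate_components(small_data.G, small_data.X, folds=1)


class TestPredict:
    def test_training_matrix_reproduces_fit(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=2)
        assert np.allclose(pls_predict(fit, small_data.G),
                           small_data.G @ fit.C)

    def test_zero_row_predicts_zero(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=2)
        assert np.allclose(pls_predict(fit, np.zeros(small_data.m)), 0.0)

    def test_snp_mismatch_rejected(self, small_data):
        fit = fit_pls(small_data.G, small_data.X, r=2,
                      snp_ids=[f"s{i}" for i in range(small_data.m)])
        with pytest.raises(ValueError, match="dimension"):
            pls_predict(fit, small_data.G[:, :-1])
        permuted = list(reversed([f"s{i}" for i in range(small_data.m)]))
        with pytest.raises(ValueError, match="identifier"):
            pls_predict(fit, small_data.G, snp_ids=permuted)


class TestJackknife:
    def test_variance_matches_textbook_formula(self, rng):
        n = 30
        G = standardize(rng.normal(size=(n, 3)))
        X = standardize(0.5 * G[:, :2] @ rng.normal(size=(2, 2))
                        + rng.normal(size=(n, 2)))
        out = jackknife_snp_test(G, X, r=2)
        # brute-force oracle over explicit leave-one-out refits
        mask = np.ones(n, dtype=bool)
        cs = []
        for i in range(n):
            mask[i] = False
            cs.append(fit_pls(G[mask], X[mask], r=2).C)
            mask[i] = True
        cs = np.stack(cs)
        var_oracle = (n - 1) / n * np.sum((cs - cs.mean(axis=0)) ** 2, axis=0)
        assert np.abs(out["se"] ** 2 - var_oracle).max() < 1e-10

    def test_degenerate_variance_flagged(self, rng):
        G = standardize(rng.normal(size=(25, 1)))
        X = 0.7 * G              # exact linear relation, slope constant
        out = jackknife_snp_test(G, X, r=1)
        assert out["degenerate"][0, 0]
        assert out["p"][0, 0] == 0.0

    def test_large_n_requires_override(self, rng):
        G = standardize(rng.normal(size=(40, 2)))
        X = standardize(rng.normal(size=(40, 2)))
        with pytest.raises(ValueError, match="cap"):
            jackknife_snp_test(G, X, r=1, max_n=20)
        out = jackknife_snp_test(G, X, r=1, max_n=20, force=True)
        assert out["p"].shape == (2, 2)
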