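import numpy as np
import pytest

from mrpl import lasso_fit, standardize
from mrpl.comparators import (multi_2sls, mv_iwas_like, pls_penalty_variant,
                              prs_2sls, uni_2sls)


@pytest.fixture
def iv_data(rng):
    """Exposures genuinely instrumented by disjoint SNP groups."""
    n, m = 300, 9
    G = standardize(rng.binomial(2, 0.3, size=(n, m)).astype(float))
    u = rng.normal(size=n)
    X = np.column_stack([
        G[:, 0:3] @ [0.5, 0.4, 0.3] + 0.5 * u + 0.5 * rng.normal(size=n),
        G[:, 3:6] @ [0.5, 0.4, 0.3] + 0.5 * u + 0.5 * rng.normal(size=n),
        G[:, 6:9] @ [0.5, 0.4, 0.3] + 0.5 * u + 0.5 * rng.normal(size=n),
    ])
    X = standardize(X)
    Y = standardize(X @ np.array([0.4, 0.0, -0.3]) + 0.6 * u + rng.normal(size=n))
    mask = np.zeros((m, 3), dtype=bool)
    for j in range(3):
        mask[3 * j:3 * (j + 1), j] = True
    return G, X, Y, mask


class TestMulti2sls:
    def test_closed_form_equals_two_step_ols(self, iv_data):
        G, X, Y, _ = iv_data
        res = multi_2sls(G, X, Y)
        # Eq-style closed form as independent oracle
        P = G @ np.linalg.inv(G.T @ G) @ G.T
        oracle = np.linalg.solve(X.T @ P @ X, X.T @ P @ Y)
        assert np.abs(res.beta - oracle).max() < 1e-8

    def test_saturated_first_stage_is_ols(self, rng):
        # square invertible G: the first-stage projection is the identity
        G = rng.normal(size=(6, 6)) + np.eye(6)
        X = G.copy()
        Y = rng.normal(size=6)
        res = multi_2sls(G, X, Y)
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.abs(res.beta - ols).max() < 1e-8

    def test_consistent_without_confounding(self, rng):
        errs = []
        beta = np.array([0.5, -0.3])
        for i in range(50):
            r = np.random.default_rng(i)
            G = standardize(r.binomial(2, 0.3, size=(400, 4)).astype(float))
            X = standardize(G @ r.normal(size=(4, 2)))
            Y = X @ beta + 0.5 * r.normal(size=400)
            errs.append(multi_2sls(G, X, Y).beta - beta)
        errs = np.stack(errs)
        mc_se = errs.std(axis=0) / np.sqrt(len(errs))
        assert np.all(np.abs(errs.mean(axis=0)) < 2 * mc_se + 1e-3)


class TestUni2sls:
    def test_single_instrument_is_wald_ratio(self, iv_data):
        G, X, Y, _ = iv_data
        mask = np.zeros((G.shape[1], 3), dtype=bool)
        mask[0, 0] = True
        res = uni_2sls(G, X, Y, mask)
        g = G[:, 0]
        wald = np.cov(g, Y)[0, 1] / np.cov(g, X[:, 0])[0, 1]
        assert res.beta[0] == pytest.approx(wald, rel=1e-8)

    def test_agrees_with_multi_for_one_exposure(self, rng):
        G = standardize(rng.normal(size=(100, 4)))
        X = standardize(G @ rng.normal(size=(4, 1)))
        Y = standardize(X[:, 0] + rng.normal(size=100))
        mask = np.ones((4, 1), dtype=bool)
        assert uni_2sls(G, X, Y, mask).beta[0] == pytest.approx(
            multi_2sls(G, X, Y).beta[0], rel=1e-10)

    def test_exposure_without_instruments_skipped(self, iv_data):
        G, X, Y, mask = iv_data
        mask = mask.copy()
        mask[:, 1] = False
        with pytest.warns(UserWarning, match="no instruments"):
            res = uni_2sls(G, X, Y, mask)
        assert np.isnan(res.beta[1]) and np.isfinite(res.beta[0])


class TestPrs2sls:
    def test_one_instrument_equals_uni(self, iv_data):
        G, X, Y, _ = iv_data
        mask = np.zeros((G.shape[1], 3), dtype=bool)
        mask[2, 0] = True
        assert prs_2sls(G, X, Y, mask).beta[0] == pytest.approx(
            uni_2sls(G, X, Y, mask).beta[0], rel=1e-10)

    def test_duplicated_instrument_columns_equivalent(self, rng):
        G0 = standardize(rng.normal(size=(150, 1)))
        G = np.hstack([G0, G0])
        X = standardize(0.6 * G0 + rng.normal(size=(150, 1)))
        Y = standardize(0.5 * X[:, 0] + rng.normal(size=150))
        single = np.array([[True], [False]])
        both = np.array([[True], [True]])
        assert prs_2sls(G, X, Y, both).beta[0] == pytest.approx(
            prs_2sls(G, X, Y, single).beta[0], rel=1e-10)


class TestMvIwas:
    def test_complete_mask_reduces_to_multi(self, iv_data):
        G, X, Y, _ = iv_data
        full = np.ones((G.shape[1], X.shape[1]), dtype=bool)
        assert np.abs(mv_iwas_like(G, X, Y, full).beta
                      - multi_2sls(G, X, Y).beta).max() < 1e-8

    def test_block_orthogonal_first_stage_is_per_exposure_ols(self, rng):
        # orthogonalized instrument blocks: each first stage equals OLS of
        # the exposure on its own block
        n = 200
        Q, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        G = Q * np.sqrt(n)
        X = standardize(np.column_stack([
            G[:, :3] @ [0.5, 0.3, 0.2] + rng.normal(size=n),
            G[:, 3:] @ [0.5, 0.3, 0.2] + rng.normal(size=n)]))
        Y = standardize(X @ np.array([0.3, -0.2]) + rng.normal(size=n))
        mask = np.zeros((6, 2), dtype=bool)
        mask[:3, 0] = mask[3:, 1] = True
        res = mv_iwas_like(G, X, Y, mask)
        Xhat = np.column_stack([
            G[:, :3] @ np.linalg.lstsq(G[:, :3], X[:, 0], rcond=None)[0],
            G[:, 3:] @ np.linalg.lstsq(G[:, 3:], X[:, 1], rcond=None)[0]])
        oracle = np.linalg.lstsq(Xhat, Y, rcond=None)[0]
        assert np.abs(res.beta - oracle).max() < 1e-8


class TestPenaltyVariants:
    def test_ridge_recovers_ols_on_clean_full_rank_design(self, rng):
        X = standardize(rng.normal(size=(300, 3)))
        beta = np.array([0.5, -0.4, 0.3])
        Y = X @ beta          # noise-free: CV picks the weakest penalty
        res = pls_penalty_variant(X, Y, "ridge", seed=0)
        assert np.abs(res.beta - beta).max() < 1e-3

    def test_elasticnet_mixing_one_equals_lasso(self, rng):
        X = standardize(rng.normal(size=(120, 4)))
        Y = standardize(X @ np.array([0.5, 0.0, -0.3, 0.0]) + rng.normal(size=120))
        enet = pls_penalty_variant(X, Y, "elasticnet", seed=3,
                                   l1_ratio_grid=[1.0])
        lasso = lasso_fit(X, Y, seed=3)
        assert enet.extra["lambda_opt"] == lasso.lambda_opt
        assert np.abs(enet.beta - lasso.beta).max() < 1e-8

    def test_lars_recovers_ols_on_clean_design(self, rng):
        X = standardize(rng.normal(size=(200, 3)))
        beta = np.array([0.4, -0.2, 0.1])
        Y = X @ beta
        res = pls_penalty_variant(X, Y, "lars", seed=1)
        assert np.abs(res.beta - beta).max() < 1e-6

    def test_unknown_penalty_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown penalty"):
            pls_penalty_variant(np.eye(4), np.ones(4), "bridge")


@pytest.mark.parametrize("estimator", ["multi", "uni", "mviwas"])
def test_sign_flip_equivariance(estimator, iv_data):
    G, X, Y, mask = iv_data
    flipped = X.copy()
    flipped[:, 0] *= -1
    if estimator == "multi":
        a, b = multi_2sls(G, X, Y), multi_2sls(G, flipped, Y)
    elif estimator == "uni":
        a, b = uni_2sls(G, X, Y, mask), uni_2sls(G, flipped, Y, mask)
    else:
        a, b = mv_iwas_like(G, X, Y, mask), mv_iwas_like(G, flipped, Y, mask)
    assert b.beta[0] == pytest.approx(-a.beta[0], rel=1e-8)
    assert b.beta[1:] == pytest.approx(a.beta[1:], rel=1e-6)
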