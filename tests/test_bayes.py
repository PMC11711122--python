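import numpy as np
import pandas as pd
import pytest

import multikern as mk
from multikern import bayes
from multikern.bayes import (MCMCConfig, eigendecompose, gblup_oracle,
                             gibbs_fit, predict, variance_partition)
from multikern.kernels import KernelMatrix, linear_kernel


def random_psd_kernel(rng, n, rank=None, labels=None):
    rank = rank or n
    A = rng.normal(size=(n, rank))
    labels = labels or [f"o{i}" for i in range(n)]
    return KernelMatrix(labels, A @ A.T / rank)


def quick_cfg(**kw):
    base = dict(n_iter=2500, burn_in=500, thin=2, seed=7)
    base.update(kw)
    return MCMCConfig(**base)


class TestEigendecompose:
    def test_identity_kernel(self):
        lam, V = eigendecompose(np.eye(5))
        assert np.allclose(lam, 1.0)
        assert np.allclose(V @ V.T, np.eye(5), atol=1e-12)

    def test_rank_one(self, rng):
        v = rng.normal(size=6)
        lam, V = eigendecompose(np.outer(v, v))
        assert len(lam) == 1
        assert np.allclose(lam[0] * np.outer(V[:, 0], V[:, 0]),
                           np.outer(v, v), atol=1e-10)

    def test_reconstruction(self, rng):
        K = random_psd_kernel(rng, 20)
        lam, V = eigendecompose(K, tol=0.0)
        assert np.linalg.norm(V @ np.diag(lam) @ V.T - K.values) < 1e-10

    def test_nonsymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(rng.normal(size=(4, 4)))


class TestGibbsFit:
    def test_null_signal_shrinks_heritability(self, rng):
        # pure noise with an unrelated-lines kernel: the genomic share of
        # variance should stay small (p < n so the genomic subspace is a
        # strict subspace and the component is identifiable from noise)
        ratios = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            n, p = 200, 80
            X = r.binomial(1, 0.3, size=(n, p)) * 2.0
            G = linear_kernel(X, labels=[f"l{i}" for i in range(n)], kind="G")
            y = pd.Series(r.normal(size=n), index=G.labels)
            fit = gibbs_fit(y, [("g", G)], quick_cfg(seed=seed))
            vc = fit.variance_components["mean"]
            ratios.append(vc["g"] / (vc["g"] + vc["residual"]))
        assert np.mean(ratios) < 0.25

    def test_antisymmetric_response_centers_mu_at_zero(self):
        c = 3.0
        y = pd.Series([c, -c] * 5, index=[f"o{i}" for i in range(10)])
        K = KernelMatrix(list(y.index), np.eye(10))
        fit = gibbs_fit(y, [("g", K)], quick_cfg())
        mc_se = fit.samples["mu"].std() / np.sqrt(len(fit.samples) / 10)
        assert abs(fit.mu_mean) < 3 * max(mc_se, 0.1)

    def test_masked_values_never_read(self, rng):
        K = random_psd_kernel(rng, 40)
        y = pd.Series(rng.normal(size=40), index=K.labels)
        y_masked = y.copy()
        y_masked.iloc[30:] = np.nan
        y_garbage = y_masked.copy()
        y_garbage.iloc[30:] = 1e9  # then re-mask
        y_garbage.iloc[30:] = np.nan
        f1 = gibbs_fit(y_masked, [("g", K)], quick_cfg(seed=11))
        f2 = gibbs_fit(y_garbage, [("g", K)], quick_cfg(seed=11))
        assert np.allclose(f1.predictions, f2.predictions)
        assert np.allclose(f1.samples, f2.samples)

    def test_reproducible_given_seed(self, rng):
        K = random_psd_kernel(rng, 30)
        y = pd.Series(rng.normal(size=30), index=K.labels)
        f1 = gibbs_fit(y, [("g", K)], quick_cfg(seed=5))
        f2 = gibbs_fit(y, [("g", K)], quick_cfg(seed=5))
        pd.testing.assert_frame_equal(f1.samples, f2.samples)

    def test_input_validation(self, rng):
        K = random_psd_kernel(rng, 12)
        y = pd.Series(np.ones(12), index=K.labels)
        with pytest.raises(ValueError, match="constant"):
            gibbs_fit(y, [("g", K)], quick_cfg())
        with pytest.raises(ValueError, match="at least one kernel"):
            gibbs_fit(y, [], quick_cfg())
        short = pd.Series(rng.normal(size=12), index=K.labels)
        short.iloc[4:] = np.nan
        with pytest.raises(ValueError, match="observed"):
            gibbs_fit(short, [("g", K)], quick_cfg())
        bad = KernelMatrix([f"x{i}" for i in range(12)], K.values)
        with pytest.raises(ValueError, match="labels"):
            gibbs_fit(pd.Series(rng.normal(size=12), index=K.labels),
                      [("g", bad)], quick_cfg())

    def test_heritability_recovery_moderate(self, rng):
        n, p = 250, 500
        X = rng.binomial(1, rng.uniform(0.1, 0.5, p), size=(n, p)) * 2.0
        G = linear_kernel(X, labels=[f"l{i}" for i in range(n)], kind="G")
        Xs = (X - X.mean(0)) / X.std(0)
        g = Xs @ rng.normal(size=p)
        g = (g - g.mean()) / g.std()
        y = pd.Series(g + rng.normal(size=n), index=G.labels)  # h2 = 0.5
        fit = gibbs_fit(y, [("g", G)], quick_cfg(n_iter=3000, burn_in=500))
        vc = fit.variance_components["mean"]
        h2 = vc["g"] / (vc["g"] + vc["residual"])
        assert 0.35 <= h2 <= 0.65


class TestOracleEquivalence:
    def test_ridge_limit_zero_variance(self, rng):
        K = random_psd_kernel(rng, 25)
        y = pd.Series(rng.normal(5.0, 1.0, 25), index=K.labels)
        out = gblup_oracle(y, [("g", K)], {"g": 1e-12, "residual": 1.0})
        assert np.allclose(out["effects"]["g"], 0.0, atol=1e-8)
        assert np.allclose(out["predictions"], y.mean(), atol=1e-6)

    def test_interpolation_limit(self, rng):
        K = random_psd_kernel(rng, 20)
        K.values += 0.1 * np.eye(20)  # full rank
        y = pd.Series(rng.normal(size=20), index=K.labels)
        out = gblup_oracle(y, [("g", K)], {"g": 1.0, "residual": 1e-10})
        assert np.allclose(out["predictions"], y, atol=1e-4)

    def test_gibbs_matches_oracle_with_clamped_variances(self, rng):
        K1 = random_psd_kernel(rng, 100, rank=40)
        K2 = random_psd_kernel(rng, 100, rank=40, labels=K1.labels)
        u = np.linalg.cholesky(K1.values + 1e-8 * np.eye(100)) @ rng.normal(size=100)
        y = pd.Series(1.0 + u + rng.normal(0, 0.8, 100), index=K1.labels)
        y.iloc[80:] = np.nan
        variances = {"a": 1.0, "b": 0.5, "residual": 0.64}
        oracle = gblup_oracle(y, [("a", K1), ("b", K2)], variances)
        fit = gibbs_fit(y, [("a", K1), ("b", K2)],
                        quick_cfg(n_iter=9000, burn_in=1000, seed=3),
                        fixed_variances=variances)
        for term in ("a", "b"):
            c = np.corrcoef(oracle["effects"][term],
                            fit.term_effects[term])[0, 1]
            assert c > 0.999


class TestPredict:
    def test_duplicate_kernel_row_tracks_training_line(self, rng):
        n = 30
        A = rng.normal(size=(n, 15))
        A[-1] = A[0]  # target duplicates line 0
        K = linear_kernel(A, labels=[f"o{i}" for i in range(n)],
                          standardize=False)
        u = np.linalg.cholesky(K.values + 1e-6 * np.eye(n)) @ rng.normal(size=n)
        y = pd.Series(u + rng.normal(0, 0.3, n), index=K.labels)
        y.iloc[-1] = np.nan
        fit = gibbs_fit(y, [("g", K)], quick_cfg())
        assert fit.predictions.iloc[0] == pytest.approx(
            fit.fitted.iloc[0], abs=0.2)

    def test_disconnected_target_predicted_at_intercept(self, rng):
        n = 25
        V = np.zeros((n, n))
        V[: n - 1, : n - 1] = random_psd_kernel(rng, n - 1).values
        K = KernelMatrix([f"o{i}" for i in range(n)], V)
        u = np.zeros(n)
        y = pd.Series(5.0 + rng.normal(size=n), index=K.labels)
        y.iloc[-1] = np.nan
        fit = gibbs_fit(y, [("g", K)], quick_cfg())
        with pytest.warns(UserWarning, match="disconnected"):
            out = predict(fit, [K.labels[-1]])
        assert out.iloc[0] == pytest.approx(fit.mu_mean, abs=1e-8)

    def test_unknown_label_rejected(self, rng):
        K = random_psd_kernel(rng, 15)
        y = pd.Series(rng.normal(size=15), index=K.labels)
        fit = gibbs_fit(y, [("g", K)], quick_cfg())
        with pytest.raises(KeyError):
            predict(fit, ["nope"])


class TestVariancePartition:
    def test_single_term_share_is_one(self, rng):
        K = random_psd_kernel(rng, 30)
        y = pd.Series(rng.normal(size=30), index=K.labels)
        fit = gibbs_fit(y, [("g", K)], quick_cfg())
        shares = variance_partition(fit)
        assert shares["g"] == pytest.approx(1.0)

    def test_balanced_two_term_split(self, rng):
        n = 150
        K1 = random_psd_kernel(rng, n, rank=60)
        K2 = random_psd_kernel(rng, n, rank=60, labels=K1.labels)
        c1 = np.linalg.cholesky(K1.values + 1e-8 * np.eye(n))
        c2 = np.linalg.cholesky(K2.values + 1e-8 * np.eye(n))
        y = pd.Series(c1 @ rng.normal(size=n) + c2 @ rng.normal(size=n)
                      + rng.normal(0, 0.5, n), index=K1.labels)
        fit = gibbs_fit(y, [("a", K1), ("b", K2)], quick_cfg())
        shares = variance_partition(fit)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.2 < shares["a"] < 0.8  # neither term dominates


def test_chain_invariant_to_observation_permutation(rng):
    n = 60
    K = random_psd_kernel(rng, n, rank=30)
    u = np.linalg.cholesky(K.values + 1e-8 * np.eye(n)) @ rng.normal(size=n)
    y = pd.Series(u + rng.normal(0, 0.5, n), index=K.labels)
    fit1 = gibbs_fit(y, [("g", K)], quick_cfg(seed=1))
    perm = rng.permutation(n)
    y2 = y.iloc[perm]
    K2 = KernelMatrix([K.labels[i] for i in perm],
                      K.values[np.ix_(perm, perm)])
    fit2 = gibbs_fit(y2, [("g", K2)], quick_cfg(seed=2))
    v1 = fit1.variance_components["mean"]
    v2 = fit2.variance_components["mean"]
    sd1 = fit1.variance_components["sd"]
    for term in ("g", "residual"):
        assert abs(v1[term] - v2[term]) < 4 * sd1[term]
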