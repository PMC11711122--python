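import numpy as np
import pandas as pd
import pytest

from multikern import kernels
from multikern.kernels import (KernelMatrix, MODEL_SPECS, build_model_kernels,
                               environment_kernel, expand_kernel,
                               interaction_kernel, linear_kernel,
                               standardize_columns)


class TestStandardize:
    def test_hand_example_population_sd(self):
        out = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out[:, 0], [-1.224744871, 0.0, 1.224744871])

    def test_idempotent(self, rng):
        X = rng.normal(size=(30, 5))
        once = standardize_columns(X)
        twice = standardize_columns(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 20))
        out = standardize_columns(X)
        expect = np.empty_like(X)
        for j in range(X.shape[1]):
            col = X[:, j]
            expect[:, j] = (col - col.mean()) / col.std()
        assert np.allclose(out, expect, atol=1e-12)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize_columns(X)
        assert out.shape == (10, 1)
        with pytest.raises(ValueError):
            standardize_columns(np.ones((5, 3)))


class TestLinearKernel:
    def test_two_by_two_direct(self):
        M = np.array([[1.0, -1.0], [-1.0, 1.0]])
        K = linear_kernel(M, labels=["a", "b"], standardize=False)
        assert np.allclose(K.values, [[1, -1], [-1, 1]])

    def test_duplicated_rows_share_entries(self, rng):
        M = rng.normal(size=(4, 10))
        M[1] = M[0]
        K = linear_kernel(M, labels=list("abcd"), standardize=False)
        assert K.values[0, 0] == pytest.approx(K.values[0, 1])
        assert K.values[1, 1] == pytest.approx(K.values[0, 1])

    def test_brute_force_oracle(self, rng):
        M = rng.normal(size=(8, 30))
        K = linear_kernel(M, labels=[f"l{i}" for i in range(8)],
                          standardize=False)
        p = M.shape[1]
        for i in range(8):
            for j in range(8):
                expect = sum(M[i, k] * M[j, k] for k in range(p)) / p
                assert K.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_standardized_diag_near_one(self, rng):
        M = rng.normal(size=(40, 200))
        K = linear_kernel(M, labels=[f"l{i}" for i in range(40)])
        assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=0.15)
        assert K.min_eigenvalue() > -1e-8


class TestExpandKernel:
    def test_identity_expansion(self, rng):
        A = rng.normal(size=(3, 5))
        K = linear_kernel(A, labels=list("abc"), standardize=False)
        E = expand_kernel(K, ["a", "b", "c"], ["o1", "o2", "o3"])
        assert np.allclose(E.values, K.values)

    def test_repeated_line_block_constant(self, rng):
        A = rng.normal(size=(3, 5))
        K = linear_kernel(A, labels=list("abc"), standardize=False)
        E = expand_kernel(K, ["a", "a", "b"], ["o1", "o2", "o3"])
        assert E.values[0, 0] == E.values[0, 1] == E.values[1, 1]

    def test_lookup_oracle(self, rng):
        A = rng.normal(size=(3, 6))
        K = linear_kernel(A, labels=list("abc"), standardize=False)
        groups = ["a", "b", "c", "a", "b", "c"]
        E = expand_kernel(K, groups, [f"o{i}" for i in range(6)])
        pos = {"a": 0, "b": 1, "c": 2}
        for i in range(6):
            for j in range(6):
                assert E.values[i, j] == K.values[pos[groups[i]], pos[groups[j]]]

    def test_unmapped_observation_errors(self, rng):
        K = linear_kernel(rng.normal(size=(2, 4)), labels=["a", "b"],
                          standardize=False)
        with pytest.raises(KeyError, match="zzz"):
            expand_kernel(K, ["a", "zzz"])


class TestInteractionKernel:
    def test_hadamard_identity_with_ones(self, rng):
        A = linear_kernel(rng.normal(size=(4, 6)), labels=list("wxyz"),
                          standardize=False)
        ones = KernelMatrix(list("wxyz"), np.ones((4, 4)))
        out = interaction_kernel(A, ones)
        assert np.allclose(out.values, A.values)

    def test_diagonal_products(self):
        A = KernelMatrix(list("ab"), np.diag([2.0, 3.0]))
        B = KernelMatrix(list("ab"), np.diag([5.0, 7.0]))
        assert np.allclose(interaction_kernel(A, B).values, np.diag([10.0, 21.0]))

    def test_schur_product_stays_psd(self, rng):
        for _ in range(5):
            A = linear_kernel(rng.normal(size=(5, 8)), labels=list("abcde"),
                              standardize=False)
            B = linear_kernel(rng.normal(size=(5, 8)), labels=list("abcde"),
                              standardize=False)
            out = interaction_kernel(A, B)
            assert np.allclose(out.values, A.values * B.values, atol=1e-12)
            assert out.min_eigenvalue() >= -1e-10

    def test_label_mismatch(self, rng):
        A = KernelMatrix(list("ab"), np.eye(2))
        B = KernelMatrix(list("ba"), np.eye(2))
        with pytest.raises(ValueError):
            interaction_kernel(A, B)


class TestModelSpecs:
    def test_printed_term_lists(self):
        expect = {
            "M1": ("g",), "M2": ("H",), "M3": ("g", "H"),
            "M4": ("E", "g", "gE"), "M5": ("E", "H", "HE"),
            "M6": ("E", "g", "H", "HE", "gE"),
            "M7": ("E", "g", "w", "gw", "gE"),
            "M8": ("E", "H", "w", "HE", "Hw"),
            "M9": ("E", "g", "w", "H", "HE", "Hw", "gE", "gw"),
        }
        for name, terms in expect.items():
            assert MODEL_SPECS[name].terms == terms


class TestBuildModelKernels:
    @pytest.fixture()
    def toy(self, rng):
        obs = pd.DataFrame({
            "line": ["A", "B", "A", "B"],
            "env": ["e1", "e1", "e2", "e2"],
        }, index=["A@e1", "B@e1", "A@e2", "B@e2"])
        G = KernelMatrix(["A", "B"], np.array([[1.0, 0.3], [0.3, 1.0]]), "G")
        P = KernelMatrix(list(obs.index),
                         linear_kernel(rng.normal(size=(4, 6)),
                                       labels=list(obs.index)).values, "P")
        K = KernelMatrix(["e1", "e2"], np.array([[1.0, -0.5], [-0.5, 1.0]]), "K")
        return obs, G, P, K

    def test_m1_single_kernel_is_g(self, toy):
        obs, G, P, K = toy
        one_env = obs[obs["env"] == "e1"]
        out = build_model_kernels("M1", one_env, G=G)
        assert len(out) == 1 and out[0][0] == "g"
        assert np.allclose(out[0][1].values, G.values)

    def test_m9_returns_eight_kernels_in_order(self, toy):
        obs, G, P, K = toy
        out = build_model_kernels("M9", obs, G=G, P=P, K=K)
        assert [name for name, _ in out] == ["E", "g", "w", "H", "HE", "Hw",
                                             "gE", "gw"]

    def test_hand_worksheet_two_lines_two_envs(self, toy):
        obs, G, P, K = toy
        out = dict(build_model_kernels("M9", obs, G=G, P=P, K=K))
        gexp = np.array([[1.0, 0.3, 1.0, 0.3],
                         [0.3, 1.0, 0.3, 1.0],
                         [1.0, 0.3, 1.0, 0.3],
                         [0.3, 1.0, 0.3, 1.0]])
        E = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                      [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float)
        wexp = np.array([[1.0, 1.0, -0.5, -0.5],
                         [1.0, 1.0, -0.5, -0.5],
                         [-0.5, -0.5, 1.0, 1.0],
                         [-0.5, -0.5, 1.0, 1.0]])
        assert np.allclose(out["g"].values, gexp)
        assert np.allclose(out["E"].values, E)
        assert np.allclose(out["w"].values, wexp)
        assert np.allclose(out["gE"].values, gexp * E)
        assert np.allclose(out["gw"].values, gexp * wexp)
        assert np.allclose(out["HE"].values, P.values * E)
        assert np.allclose(out["Hw"].values, P.values * wexp)

    def test_missing_source_raises(self, toy):
        obs, G, P, K = toy
        with pytest.raises(ValueError, match="K"):
            build_model_kernels("M7", obs, G=G, P=P, K=None)

    def test_gw_literal_switch_uses_hyperspectral(self, toy):
        obs, G, P, K = toy
        out = dict(build_model_kernels("M7", obs, G=G, P=P, K=K,
                                       literal_gw_uses_H=True))
        wexp = expand_kernel(K, obs["env"], list(obs.index)).values
        assert np.allclose(out["gw"].values, P.values * wexp)


def test_permuting_observations_conjugates_kernels(rng):
    obs = pd.DataFrame({
        "line": ["A", "B", "C", "A", "B", "C"],
        "env": ["e1"] * 3 + ["e2"] * 3,
    }, index=[f"o{i}" for i in range(6)])
    G = linear_kernel(rng.normal(size=(3, 9)), labels=["A", "B", "C"])
    K = KernelMatrix(["e1", "e2"], np.array([[1.0, 0.2], [0.2, 1.0]]))
    P = linear_kernel(rng.normal(size=(6, 7)), labels=list(obs.index))
    base = build_model_kernels("M9", obs, G=G, P=P, K=K)
    perm = rng.permutation(6)
    obs_p = obs.iloc[perm]
    P_p = KernelMatrix([obs.index[i] for i in perm],
                       P.values[np.ix_(perm, perm)])
    out_p = build_model_kernels("M9", obs_p, G=G, P=P_p, K=K)
    for (n1, k1), (n2, k2) in zip(base, out_p):
        assert n1 == n2
        assert np.allclose(k2.values, k1.values[np.ix_(perm, perm)], atol=1e-12)


def test_kernel_csv_round_trip(tmp_path, rng):
    K = linear_kernel(rng.normal(size=(5, 8)), labels=[f"l{i}" for i in range(5)])
    path = tmp_path / "kernel.csv"
    K.save_csv(path)
    K2 = KernelMatrix.load_csv(path)
    assert K2.labels == K.labels
    assert np.allclose(K2.values, K.values, atol=1e-12)
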