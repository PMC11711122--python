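"""Benchmark recipes: the package's standard validation experiments.

Each function runs one self-contained experiment end to end — generating
synthetic trials, fitting models, and measuring the result — and returns
plain numbers. They power the acceptance checks and the worked examples.

Problem sizes are chosen to exercise the full pipeline on a single CPU in
minutes: three unbalanced years of 150/130/110 lines with partial overlap,
600-800 markers in 20-25 founder families, and a dozen wavebands. The
variance structure mirrors the default generator settings (plot yields
around 2500 kg/ha, within-year broad-sense heritability near 0.55).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes, evaluation, ioqc, kernels, pipeline, simdata

__all__ = [
    "forward_study_config", "within_year_study_config",
    "oracle_equivalence", "heritability_recovery", "kernel_bruteforce_check",
    "coincide_null_calibration", "forward_ordering", "cv2_ordering",
    "qc_refilter_check", "leakage_probe",
]


def forward_study_config(seed: int) -> simdata.SimConfig:
    """Three-year unbalanced trial for forward-prediction experiments."""
    return simdata.SimConfig(
        n_lines_per_year={"2021": 150, "2022": 130, "2023": 110},
        n_overlap={("2021", "2022"): 30, ("2022", "2023"): 28,
                   ("2021", "2023"): 10, ("2021", "2022", "2023"): 6},
        n_markers=800, n_families=20, n_bands=12, blocks_per_rep=5,
        band_genetic_corr=0.55, seed=seed)


def within_year_study_config(seed: int) -> simdata.SimConfig:
    """Single-year trial for within-year (CV2) experiments."""
    return simdata.SimConfig(
        n_lines_per_year={"2021": 140}, n_overlap={},
        n_markers=600, n_families=20, n_bands=12, blocks_per_rep=5,
        band_genetic_corr=0.55, var_gxe=0.0, var_year=0.0, seed=seed)


# ----------------------------------------------------------------------
def oracle_equivalence(n_instances: int = 20, seed: int = 0,
                       n_iter: int = 6000, burn_in: int = 1000) -> list:
    """Gibbs sampler vs closed-form BLUP at clamped variance components.

    Random single-kernel instances (varied size, rank, variance ratio,
    some with masked rows); returns the per-instance correlation between
    Gibbs posterior-mean effects and the exact mixed-model solution.
    """
    rng = np.random.default_rng(seed)
    corrs = []
    for i in range(n_instances):
        n = int(rng.integers(60, 200))
        rank = int(rng.integers(20, n))
        A = rng.normal(size=(n, rank))
        K = kernels.KernelMatrix([f"o{j}" for j in range(n)], A @ A.T / rank)
        sig_g = float(rng.uniform(0.5, 2.0))
        sig_e = float(rng.uniform(0.3, 1.5))
        u = np.linalg.cholesky(K.values + 1e-8 * np.eye(n)) @ rng.normal(size=n)
        y = pd.Series(rng.normal() + np.sqrt(sig_g) * u
                      + rng.normal(0, np.sqrt(sig_e), n), index=K.labels)
        if i % 2 == 0:
            y.iloc[-n // 5:] = np.nan
        variances = {"g": sig_g, "residual": sig_e}
        oracle = bayes.gblup_oracle(y, [("g", K)], variances)
        fit = bayes.gibbs_fit(
            y, [("g", K)],
            bayes.MCMCConfig(n_iter=n_iter, burn_in=burn_in, thin=2,
                             seed=int(rng.integers(2 ** 31))),
            fixed_variances=variances)
        corrs.append(float(np.corrcoef(oracle["effects"]["g"],
                                       fit.term_effects["g"])[0, 1]))
    return corrs


def heritability_recovery(ratios=(0.2, 0.5, 0.8), n: int = 300, p: int = 1000,
                          n_seeds: int = 10, seed: int = 0,
                          n_iter: int = 3000, burn_in: int = 500) -> dict:
    """Posterior-mean heritability of the single-kernel model vs truth.

    For each planted ratio h2, simulates y = g + e with g a standardized
    marker-driven genetic value over a family-structured inbred panel
    (related lines give the genomic kernel the eigenvalue spread that
    makes the variance ratio identifiable), fits the genomic-kernel
    model, and averages the posterior variance ratio over seeds.
    """
    out = {}
    for h2 in ratios:
        ests = []
        for s in range(n_seeds):
            rng = np.random.default_rng([seed, int(h2 * 100), s])
            cfg = simdata.SimConfig(
                n_lines_per_year={"2021": n}, n_overlap={}, n_markers=p,
                n_families=max(10, n // 10), var_gxe=0.0, var_year=0.0,
                seed=int(rng.integers(2 ** 31)))
            X = simdata.simulate_markers(cfg).dosages
            sd = X.std(axis=0)
            keep = sd > 0
            Xs = (X[:, keep] - X[:, keep].mean(0)) / sd[keep]
            G = kernels.KernelMatrix([f"l{j}" for j in range(n)],
                                     Xs @ Xs.T / keep.sum())
            g = Xs @ rng.normal(size=int(keep.sum()))
            g = (g - g.mean()) / g.std() * np.sqrt(h2)
            y = pd.Series(g + rng.normal(0, np.sqrt(1 - h2), n),
                          index=G.labels)
            fit = bayes.gibbs_fit(
                y, [("g", G)],
                bayes.MCMCConfig(n_iter=n_iter, burn_in=burn_in, thin=2,
                                 seed=int(rng.integers(2 ** 31))))
            vc = fit.variance_components["mean"]
            ests.append(float(vc["g"] / (vc["g"] + vc["residual"])))
        out[h2] = float(np.mean(ests))
    return out


def kernel_bruteforce_check(seed: int = 0, n: int = 8, p: int = 30) -> dict:
    """Max absolute error of every kernel recipe vs double-loop oracles."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, p))
    labels = [f"l{i}" for i in range(n)]
    K = kernels.linear_kernel(M, labels=labels, standardize=False)
    Ms = kernels.standardize_columns(M)
    Kstd = kernels.linear_kernel(M, labels=labels)
    err = 0.0
    for i in range(n):
        for j in range(n):
            err = max(err, abs(K.values[i, j]
                               - sum(M[i, k] * M[j, k] for k in range(p)) / p))
            err = max(err, abs(Kstd.values[i, j]
                               - sum(Ms[i, k] * Ms[j, k] for k in range(p)) / p))
    # expansion + Hadamard interaction vs lookup/product oracles
    obs_groups = [labels[i] for i in rng.integers(0, n, size=2 * n)]
    E = kernels.expand_kernel(K, obs_groups)
    pos = {l: i for i, l in enumerate(labels)}
    B = kernels.linear_kernel(rng.normal(size=(2 * n, p)),
                              labels=list(range(2 * n)), standardize=False)
    H = kernels.interaction_kernel(
        kernels.KernelMatrix(list(range(2 * n)), E.values), B)
    for i in range(2 * n):
        for j in range(2 * n):
            e_ij = K.values[pos[obs_groups[i]], pos[obs_groups[j]]]
            err = max(err, abs(E.values[i, j] - e_ij))
            err = max(err, abs(H.values[i, j] - e_ij * B.values[i, j]))
    min_eig = min(K.min_eigenvalue(), H.min_eigenvalue())
    return {"max_abs_error": float(err), "min_eigenvalue": float(min_eig)}


def coincide_null_calibration(n: int = 200, reps: int = 10000,
                              seed: int = 0) -> dict:
    """Monte-Carlo mean coincide index for independent rankings."""
    rng = np.random.default_rng(seed)
    obs = np.arange(float(n))
    vals = np.empty(reps)
    for b in range(reps):
        vals[b] = evaluation.coincide_index(rng.permutation(n).astype(float),
                                            obs)
    return {"mean": float(vals.mean()),
            "mc_se": float(vals.std(ddof=1) / np.sqrt(reps))}


def forward_ordering(n_seeds: int = 10, seed: int = 0,
                     models=("M1", "M5", "M9"),
                     n_iter: int = 3000, burn_in: int = 600) -> pd.DataFrame:
    """Forward prediction (2021+2022 -> 2023) accuracy per model and seed."""
    rows = []
    for s in range(n_seeds):
        cfg = forward_study_config(seed * 1000 + s)
        markers, plots, weather, _ = simdata.simulate_dataset(cfg)
        data = pipeline.prepare_dataset(markers, plots, weather)
        plan = evaluation.make_forward_plan(data.obs, ["2021", "2022"], "2023")
        rep = evaluation.run_benchmark(
            list(models), plan, data,
            mcmc=bayes.MCMCConfig(n_iter=n_iter, burn_in=burn_in, seed=s))
        row = rep.set_index("model")["rho_weighted"].to_dict()
        row.update({f"CI_{m}": v for m, v in
                    rep.set_index("model")["coincide_index"].items()})
        row["seed"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def cv2_ordering(n_seeds: int = 10, seed: int = 0, models=("M1", "M3"),
                 k: int = 10, n_iter: int = 1500,
                 burn_in: int = 300) -> pd.DataFrame:
    """Within-year 10-fold CV2 accuracy per model and seed."""
    rows = []
    for s in range(n_seeds):
        cfg = within_year_study_config(seed * 1000 + 500 + s)
        markers, plots, weather, _ = simdata.simulate_dataset(cfg)
        data = pipeline.prepare_dataset(markers, plots, weather)
        lines = list(data.obs["line"])
        plan = evaluation.make_cv2_plan(lines, k=k, seed=s)
        rep = evaluation.run_benchmark(
            list(models), plan, data, env="2021",
            mcmc=bayes.MCMCConfig(n_iter=n_iter, burn_in=burn_in, seed=s))
        row = rep.set_index("model")["rho_weighted"].to_dict()
        row["seed"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def qc_refilter_check(seed: int = 0) -> dict:
    """Marker QC vs an independent per-marker re-filter on planted violations."""
    cfg = simdata.SimConfig(n_lines_per_year={"2021": 100}, n_overlap={},
                            n_markers=400, seed=seed)
    m = simdata.simulate_markers(cfg, planted_missing=0.1,
                                 planted_low_maf=0.1, planted_high_het=0.1)
    kept, report = ioqc.marker_qc(m)
    expected = []
    for j, mid in enumerate(m.marker_ids):
        col = m.dosages[:, j]
        obs = col[~np.isnan(col)]
        miss = 1.0 - len(obs) / len(col)
        p = obs.mean() / 2.0 if len(obs) else 1.0
        het = float((obs == 1).mean()) if len(obs) else 0.0
        if miss <= 0.80 and min(p, 1 - p) >= 0.05 and het <= 0.10:
            expected.append(mid)
    return {"n_retained": report.n_retained,
            "n_expected": len(expected),
            "identical": kept.marker_ids == expected}


def leakage_probe(seed: int = 0, n_iter: int = 1200,
                  burn_in: int = 300) -> dict:
    """Corrupting masked test responses must change nothing downstream.

    Runs the forward pipeline twice — once with the test year's yields
    merely masked, once with the underlying values replaced by garbage
    before masking — and compares the Bayesian fit samples, predictions,
    and an ML model's chosen hyperparameters and predictions.
    """
    from . import ml

    cfg = forward_study_config(seed + 77)
    markers, plots, weather, _ = simdata.simulate_dataset(cfg)
    data = pipeline.prepare_dataset(markers, plots, weather)
    plan = evaluation.make_forward_plan(data.obs, ["2021", "2022"], "2023")
    train_labels, test_labels = plan.folds[0]

    def bayes_run(y):
        tk = kernels.build_model_kernels("M4", data.obs, G=data.G,
                                         P=data.P_obs, K=data.K_env)
        cfg_m = bayes.MCMCConfig(n_iter=n_iter, burn_in=burn_in, seed=seed)
        return bayes.gibbs_fit(y, tk, cfg_m)

    y1 = data.obs["y"].copy()
    y1.loc[test_labels] = np.nan
    y2 = data.obs["y"].copy()
    y2.loc[test_labels] = 1e12   # garbage...
    y2.loc[test_labels] = np.nan  # ...then masked, as the plan prescribes
    f1, f2 = bayes_run(y1), bayes_run(y2)
    bayes_identical = bool(np.allclose(f1.samples, f2.samples)
                           and np.allclose(f1.predictions, f2.predictions))

    spec = ml.GridSpec("RFR", grid={"model__n_estimators": [30, 60],
                                    "model__max_features": [1.0]},
                       inner_cv_folds=3,
                       feature_blocks=ml.FeatureBlockSpec(("G", "H")))
    feats = ml.assemble_features(spec.feature_blocks, data.obs,
                                 markers=data.markers_imputed,
                                 band_blues=data.band_blues)
    y_tr1 = data.obs.loc[train_labels, "y"]
    est1, rep1 = ml.tune_and_fit(spec, feats.loc[train_labels], y_tr1, seed=seed)
    obs_corrupt = data.obs.copy()
    obs_corrupt.loc[test_labels, "y"] = -9e9
    y_tr2 = obs_corrupt.loc[train_labels, "y"]
    est2, rep2 = ml.tune_and_fit(spec, feats.loc[train_labels], y_tr2, seed=seed)
    p1 = est1.predict(feats.loc[test_labels].to_numpy(float))
    p2 = est2.predict(feats.loc[test_labels].to_numpy(float))
    ml_identical = bool(rep1["chosen"] == rep2["chosen"]
                        and np.allclose(p1, p2))
    return {"bayes_identical": bayes_identical, "ml_identical": ml_identical}
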