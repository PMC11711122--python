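"""Evaluation machinery: CV2 folds, forward prediction, and ranking metrics.

Two validation designs are supported. CV2 predicts incomplete trials
within a year: 10-fold cross-validation with an 80/20 split, optionally
cluster-aware (folds are unions of whole genomic clusters so related lines
never straddle train and test). Forward prediction trains on earlier
years and masks the target year's yields only — hyperspectral and
environmental features of the target year stay available, since both are
measured on the validation-year trial itself.

Accuracy is the Pearson correlation rho between predicted and observed
values per environment; across environments the inverse-variance weighted
mean r_phi uses V(r_j) = (1 - r_j^2)/(n_j - 2). Fold-to-fold variability
is summarized with the Bouckaert-Frank corrected standard error
sqrt(s^2 (1/k + n_test/n_train)), which accounts for overlapping training
sets. The coincide index is the percentage overlap between the predicted
and observed top 25% of lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes, kernels, ml
from .pipeline import PreparedData

__all__ = ["SplitPlan", "EvalReport", "make_cv2_plan", "make_forward_plan",
           "pearson_rho", "weighted_rho", "corrected_se", "coincide_index",
           "genomic_clusters", "run_benchmark"]


@dataclass
class SplitPlan:
    scheme: str                  # cv2_random | cv2_cluster | forward
    folds: list                  # list of (train_labels, test_labels)
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    model: str
    scheme: str
    per_env_rho: dict
    n_per_env: dict
    rho_weighted: float
    se: float | None = None
    coincide_index: float | None = None
    seed: int | None = None

    def to_row(self) -> dict:
        return {"model": self.model, "scheme": self.scheme,
                "rho_weighted": self.rho_weighted, "se": self.se,
                "coincide_index": self.coincide_index,
                **{f"rho[{e}]": r for e, r in self.per_env_rho.items()}}


def make_cv2_plan(labels, k: int = 10, seed: int | None = None,
                  cluster_assignments: dict | None = None) -> SplitPlan:
    """k near-equal folds over labels; cluster-aware when clusters are given.

    With ``cluster_assignments`` (label -> cluster id), folds are unions of
    whole clusters (grouped k-fold, sizes balanced greedily), so no cluster
    straddles training and validation.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    if cluster_assignments is None:
        order = rng.permutation(len(labels))
        fold_of = np.empty(len(labels), dtype=int)
        for pos, idx in enumerate(order):
            fold_of[idx] = pos % k
        scheme = "cv2_random"
    else:
        clusters = {}
        for l in labels:
            clusters.setdefault(cluster_assignments[l], []).append(l)
        if k > len(clusters):
            raise ValueError(f"k={k} exceeds the number of clusters "
                             f"({len(clusters)})")
        sizes = np.zeros(k, dtype=int)
        fold_by_label = {}
        # seeded shuffle, then largest-first greedy bin packing into k folds
        cl_items = sorted(clusters.items(), key=lambda kv: str(kv[0]))
        cl_items = [cl_items[i] for i in rng.permutation(len(cl_items))]
        cl_items.sort(key=lambda kv: -len(kv[1]))
        for cid, members in cl_items:
            f = int(np.argmin(sizes))
            sizes[f] += len(members)
            for m in members:
                fold_by_label[m] = f
        fold_of = np.array([fold_by_label[l] for l in labels])
        scheme = "cv2_cluster"
    folds = []
    for f in range(k):
        test = [l for l, ff in zip(labels, fold_of) if ff == f]
        train = [l for l, ff in zip(labels, fold_of) if ff != f]
        folds.append((train, test))
    return SplitPlan(scheme=scheme, folds=folds, seed=seed,
                     metadata={"k": k})


def make_forward_plan(observations: pd.DataFrame, train_years,
                      test_year) -> SplitPlan:
    """Single train/test split by year; only the test year's GY is masked.

    Lines shared across years remain in training with their training-year
    records; the test year's hyperspectral and EC features are available
    to the model (they are measured in the validation year itself).
    """
    train_years = [str(y) for y in (train_years if isinstance(train_years, (list, tuple, set)) else [train_years])]
    test_year = str(test_year)
    if test_year in train_years:
        raise ValueError("test_year must not be among train_years")
    envs = observations["env"].astype(str)
    train = list(observations.index[envs.isin(train_years)])
    test = list(observations.index[envs == test_year])
    if not train or not test:
        raise ValueError("empty training or test set for the forward plan")
    return SplitPlan(scheme="forward", folds=[(train, test)],
                     metadata={"train_years": train_years,
                               "test_year": test_year})


def pearson_rho(pred, obs) -> float:
    """Pearson correlation between paired finite values (n >= 3)."""
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    ok = np.isfinite(p) & np.isfinite(o)
    if ok.sum() < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    return float(stats.pearsonr(p[ok], o[ok])[0])


def weighted_rho(per_env_rho, n_per_env) -> float:
    """Inverse-variance weighted mean correlation r_phi.

    Weights are 1/V(r_j) with V(r_j) = (1 - r_j^2)/(n_j - 2); a correlation
    of |r| = 1 has zero sampling variance, hence infinite weight — returned
    directly with a warning.
    """
    r = np.asarray(list(per_env_rho.values()) if isinstance(per_env_rho, dict)
                   else per_env_rho, float)
    n = np.asarray(list(n_per_env.values()) if isinstance(n_per_env, dict)
                   else n_per_env, float)
    if np.any(n < 3):
        raise ValueError("every environment needs n >= 3")
    exact = np.abs(r) >= 1.0
    if exact.any():
        warnings.warn("|rho| = 1 has infinite weight; returning it directly")
        return float(r[exact].mean())
    V = (1.0 - r ** 2) / (n - 2.0)
    w = 1.0 / V
    return float(np.sum(w * r) / np.sum(w))


def corrected_se(per_fold_scores, n_test: float, n_train: float) -> float:
    """Resampled-CV corrected SE: sqrt(s^2 (1/k + n_test/n_train))."""
    s = np.asarray(per_fold_scores, float)
    k = len(s)
    if k < 2:
        raise ValueError("need at least 2 fold scores")
    s2 = float(np.var(s, ddof=1))
    return float(np.sqrt(s2 * (1.0 / k + n_test / n_train)))


def coincide_index(pred, obs, top_fraction: float = 0.25) -> float:
    """Percentage overlap of the predicted and observed top fraction.

    Top sets contain ceil(top_fraction * n) entries; ties break by value
    then label order. Invariant under strictly monotone transforms of
    either ranking.
    """
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    if len(p) != len(o) or len(p) < 4:
        raise ValueError("need paired values with n >= 4")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("non-finite values")
    m = ceil(top_fraction * len(p))
    top_pred = set(np.lexsort((np.arange(len(p)), -p))[:m])
    top_obs = set(np.lexsort((np.arange(len(o)), -o))[:m])
    return 100.0 * len(top_pred & top_obs) / m


def genomic_clusters(markers: pd.DataFrame, n_clusters: int = 10,
                     n_pcs: int = 10, seed: int | None = 0) -> dict:
    """Cluster lines on the top genomic principal components (k-means).

    A pragmatic relatedness grouping for cluster-aware CV: PCA of centered
    dosages followed by k-means on the leading components.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = markers.to_numpy(float)
    X = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pcs)
    return {l: int(c) for l, c in zip(markers.index, km.labels_)}


# ----------------------------------------------------------------------
# benchmark orchestration


def _line_level_kernels(data: PreparedData, env: str):
    """Line-level G and P for a within-environment model run."""
    sub = data.obs[data.obs["env"].astype(str) == str(env)]
    lines = list(sub["line"])
    G = kernels.expand_kernel(data.G, lines, lines)
    G.kind = "G"
    bb = data.band_blues.loc[[(l, e) for l, e in zip(sub["line"], sub["env"])]]
    P = kernels.linear_kernel(
        pd.DataFrame(bb.to_numpy(float), index=lines, columns=bb.columns),
        kind="P").ensure_psd()
    return sub, G, P


def _fit_bayes_fold(model_name: str, data: PreparedData, obs: pd.DataFrame,
                    G, P, test_labels, mcmc: bayes.MCMCConfig):
    spec = kernels.MODEL_SPECS[model_name]
    term_kernels = kernels.build_model_kernels(
        spec, obs, G=G, P=P, K=data.K_env)
    y = obs["y"].copy()
    y.loc[list(test_labels)] = np.nan
    fit = bayes.gibbs_fit(y, term_kernels, mcmc)
    return bayes.predict(fit, list(test_labels))


def run_benchmark(models, plan: SplitPlan, data: PreparedData,
                  mcmc: bayes.MCMCConfig | None = None,
                  env: str | None = None, seed: int | None = 0) -> pd.DataFrame:
    """Evaluate models on identical folds and report the accuracy metrics.

    ``models`` mixes kernel-model names ("M1".."M9") and :class:`ml.GridSpec`
    instances; all are scored on the same folds. For within-environment
    (CV2) plans over a single year, pass that year as ``env``. Returns one
    row per model with per-environment rho, the weighted mean, the
    corrected SE (CV2), and the coincide index (forward).
    """
    if mcmc is None:
        mcmc = bayes.MCMCConfig(n_iter=3000, burn_in=500, thin=5, seed=seed)
    rows = []
    for model in models:
        name = model if isinstance(model, str) else model.model
        preds = {}
        fold_scores = []
        for train_labels, test_labels in plan.folds:
            if isinstance(model, str):
                if env is not None:
                    # within-year run: line-level kernels for that environment
                    obs, G, P = _line_level_kernels(data, env)
                    obs = obs.copy()
                    obs.index = list(obs["line"])
                else:
                    # line-by-environment observations; main-effect-only
                    # specs (M1-M3) are fitted on them with expanded kernels
                    obs, G, P = data.obs, data.G, data.P_obs
                fold_pred = _fit_bayes_fold(model, data, obs, G, P,
                                            test_labels, mcmc)
            else:
                if env is None:
                    obs = data.obs
                else:
                    obs = data.obs[data.obs["env"].astype(str) == str(env)].copy()
                    obs.index = list(obs["line"])
                feats = ml.assemble_features(
                    model.feature_blocks, obs,
                    markers=data.markers_imputed,
                    band_blues=data.band_blues,
                    ecs=data.ec_features)
                est, _rep = ml.tune_and_fit(
                    model, feats.loc[list(train_labels)],
                    obs.loc[list(train_labels), "y"], seed=seed)
                p = est.predict(feats.loc[list(test_labels)].to_numpy(float))
                fold_pred = pd.Series(p, index=list(test_labels))
            for lab, v in fold_pred.items():
                preds[lab] = float(v)
            y_ref = _reference_y(data, env)
            score_obs = y_ref.loc[list(test_labels)]
            if len(test_labels) >= 3 and score_obs.std() > 0:
                fold_scores.append(pearson_rho(fold_pred.to_numpy(),
                                               score_obs.to_numpy()))
        pred_ser = pd.Series(preds)
        y_ref = _reference_y(data, env)
        env_of = _env_of(data, env)
        per_env, n_per = {}, {}
        for e in sorted(set(env_of.loc[pred_ser.index])):
            sel = pred_ser.index[env_of.loc[pred_ser.index] == e]
            if len(sel) >= 3:
                per_env[e] = pearson_rho(pred_ser.loc[sel].to_numpy(),
                                         y_ref.loc[sel].to_numpy())
                n_per[e] = int(len(sel))
        rho_w = weighted_rho(per_env, n_per) if per_env else np.nan
        se = None
        ci = None
        if plan.scheme.startswith("cv2") and len(fold_scores) >= 2:
            n_test = np.mean([len(t) for _, t in plan.folds])
            n_train = np.mean([len(t) for t, _ in plan.folds])
            se = corrected_se(fold_scores, n_test, n_train)
        if plan.scheme == "forward":
            _, test_labels = plan.folds[0]
            ci = coincide_index(pred_ser.loc[list(test_labels)].to_numpy(),
                                y_ref.loc[list(test_labels)].to_numpy())
        rows.append(EvalReport(model=name, scheme=plan.scheme,
                               per_env_rho=per_env, n_per_env=n_per,
                               rho_weighted=rho_w, se=se, coincide_index=ci,
                               seed=seed).to_row())
    return pd.DataFrame(rows)


def _reference_y(data: PreparedData, env: str | None) -> pd.Series:
    if env is None:
        return data.obs["y"]
    sub = data.obs[data.obs["env"].astype(str) == str(env)]
    return pd.Series(sub["y"].to_numpy(), index=list(sub["line"]))


def _env_of(data: PreparedData, env: str | None) -> pd.Series:
    if env is None:
        return data.obs["env"].astype(str)
    sub = data.obs[data.obs["env"].astype(str) == str(env)]
    return pd.Series(str(env), index=list(sub["line"]))
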