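"""Multi-kernel Bayesian RKHS regression fitted by Gibbs sampling.

The model behind every kernel-based predictor here is

    y = 1 mu + sum_k u_k + eps,   u_k ~ N(0, sigma_k^2 K_k),
                                  eps ~ N(0, sigma_e^2 I)

with one labeled PSD kernel K_k per variance-component term (genomic,
hyperspectral, enviromic, and their reaction-norm interactions). Each
kernel is eigendecomposed once, u_k = V_k delta_k with independent
coefficients delta_kj ~ N(0, sigma_k^2 lambda_kj), so a full sweep costs
two matrix-vector products per term. Variance components carry scaled
inverse chi-square priors whose scales split a prior R^2 of the phenotypic
variance equally across terms; missing responses are handled by data
augmentation (sampled from the current predictive each sweep), which is
what makes cross-validation-style prediction a matter of masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

__all__ = ["MCMCConfig", "FitResult", "eigendecompose", "gibbs_fit",
           "gblup_oracle", "predict", "variance_partition"]


@dataclass
class MCMCConfig:
    """Chain and prior settings (defaults follow common BGLR-style practice)."""

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int | None = None
    prior_df: float = 5.0
    prior_R2: float = 0.5
    eig_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.prior_R2 < 1.0:
            raise ValueError("prior_R2 must be in (0, 1)")


@dataclass
class FitResult:
    """Posterior summaries, per-term effects and predictions for masked rows."""

    labels: list
    mu_mean: float
    term_effects: dict            # term -> posterior-mean effect vector (n,)
    variance_components: pd.DataFrame  # index term, cols mean/sd/q2.5/q97.5
    residual_variance: float
    predictions: pd.Series        # posterior predictive mean at masked rows
    fitted: pd.Series             # mu + sum of effects, all rows
    samples: pd.DataFrame         # thinned draws of mu and variances
    diagnostics: pd.DataFrame     # ESS and Geweke z per variance component
    masked: np.ndarray


def eigendecompose(K: KernelMatrix | np.ndarray, tol: float = 1e-8):
    """Truncated eigendecomposition of a symmetric PSD kernel.

    Returns (eigenvalues, eigenvectors) keeping eigenvalues > tol; the
    retained pairs reconstruct K to the truncation accuracy.
    """
    A = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("kernel must be symmetric")
    lam, V = np.linalg.eigh(A)
    keep = lam > tol
    return lam[keep], V[:, keep]


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(x)
    a, b = x[: int(first * n)], x[int((1 - last) * n):]
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


def _ess(x: np.ndarray) -> float:
    try:
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.ess(np.asarray(x)[None, :]))
    except Exception:  # pragma: no cover - arviz is a declared dependency
        return float(len(x))


def _align_kernels(y: pd.Series, kernels):
    named = []
    for i, item in enumerate(kernels):
        name, K = item if isinstance(item, tuple) else (f"k{i + 1}", item)
        if isinstance(K, KernelMatrix):
            if list(K.labels) != list(y.index):
                raise ValueError(
                    f"kernel {name!r} labels do not match the response index")
            named.append((name, K.values))
        else:
            A = np.asarray(K, float)
            if A.shape != (len(y), len(y)):
                raise ValueError(f"kernel {name!r} has wrong shape")
            named.append((name, A))
    return named


def gibbs_fit(y: pd.Series, kernels, config: MCMCConfig | None = None,
              fixed_variances: dict | None = None) -> FitResult:
    """Sample the posterior of the multi-kernel model; NaN responses are masked.

    Parameters
    ----------
    y
        Response indexed by observation labels; NaN marks rows to predict.
        Masked input values are never read — the sampler augments them from
        the posterior predictive each sweep.
    kernels
        Ordered list of ``(term_name, KernelMatrix)`` (or bare matrices)
        aligned to ``y``'s index.
    fixed_variances
        Optional map term -> variance (plus ``"residual"``) clamping those
        components instead of sampling them — used for oracle-equivalence
        checks against the closed-form mixed-model solution.
    """
    if config is None:
        config = MCMCConfig()
    if len(kernels) == 0:
        raise ValueError("need at least one kernel")
    y = pd.Series(y).astype(float)
    obs_mask = np.isfinite(y.to_numpy())
    n = len(y)
    n_obs = int(obs_mask.sum())
    if n_obs < 10:
        raise ValueError("need at least 10 observed responses")
    y_obs = y.to_numpy()[obs_mask]
    vy = float(np.var(y_obs))
    if vy == 0.0:
        raise ValueError("observed response is constant")
    named = _align_kernels(y, kernels)
    fixed_variances = fixed_variances or {}
    rng = np.random.default_rng(config.seed)

    terms = []
    for name, A in named:
        lam, V = eigendecompose(A, config.eig_tol)
        mean_diag = float(np.mean(np.diag(A)))
        terms.append({"name": name, "lam": lam, "V": V,
                      "mean_diag": mean_diag if mean_diag > 0 else 1.0})
    m = len(terms)

    df0 = config.prior_df
    R2 = config.prior_R2
    # prior scales: mode of each term's variance = R2*vy/m (on the kernel's
    # diagonal scale); residual mode = (1-R2)*vy
    S0 = [vy * R2 / m * (df0 + 2.0) / df0 / t["mean_diag"] for t in terms]
    S0_e = vy * (1.0 - R2) * (df0 + 2.0) / df0

    mu = float(np.mean(y_obs))
    sig = np.array([vy * R2 / m / t["mean_diag"] for t in terms])
    sig_e = vy * (1.0 - R2)
    for k, t in enumerate(terms):
        if t["name"] in fixed_variances:
            sig[k] = float(fixed_variances[t["name"]])
    if "residual" in fixed_variances:
        sig_e = float(fixed_variances["residual"])

    delta = [np.zeros(len(t["lam"])) for t in terms]
    u = [np.zeros(n) for t in terms]
    ycur = y.to_numpy().copy()
    ycur[~obs_mask] = mu

    n_kept = (config.n_iter - config.burn_in) // config.thin
    keep_mu = np.empty(n_kept)
    keep_sig = np.empty((n_kept, m))
    keep_sig_e = np.empty(n_kept)
    sum_u = [np.zeros(n) for _ in terms]
    sum_yhat = np.zeros(n)
    kept = 0

    for it in range(config.n_iter):
        e = ycur - mu - np.sum(u, axis=0)
        # intercept
        e += mu
        mu = rng.normal(np.mean(e), np.sqrt(sig_e / n))
        e -= mu
        # per-term eigencoefficients
        for k, t in enumerate(terms):
            lam, V = t["lam"], t["V"]
            e += u[k]
            r = V.T @ e
            prec = 1.0 / sig_e + 1.0 / (sig[k] * lam)
            post_var = 1.0 / prec
            post_mean = post_var * r / sig_e
            delta[k] = post_mean + rng.normal(size=len(lam)) * np.sqrt(post_var)
            u[k] = V @ delta[k]
            e -= u[k]
            if t["name"] not in fixed_variances:
                ss = float(np.sum(delta[k] ** 2 / lam))
                df_post = df0 + len(lam)
                sig[k] = (ss + df0 * S0[k]) / rng.chisquare(df_post)
        if "residual" not in fixed_variances:
            sse = float(e @ e)
            sig_e = (sse + df0 * S0_e) / rng.chisquare(df0 + n)
        # augment masked responses from the current predictive
        yhat = mu + np.sum(u, axis=0)
        miss = ~obs_mask
        if miss.any():
            ycur[miss] = yhat[miss] + rng.normal(size=int(miss.sum())) * np.sqrt(sig_e)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep_mu[kept] = mu
            keep_sig[kept] = sig
            keep_sig_e[kept] = sig_e
            for k in range(m):
                sum_u[k] += u[k]
            sum_yhat += yhat
            kept += 1

    keep_mu, keep_sig, keep_sig_e = keep_mu[:kept], keep_sig[:kept], keep_sig_e[:kept]
    term_names = [t["name"] for t in terms]
    vc_rows = []
    diag_rows = []
    for k, name in enumerate(term_names):
        s = keep_sig[:, k]
        vc_rows.append((name, s.mean(), s.std(ddof=1),
                        np.quantile(s, 0.025), np.quantile(s, 0.975)))
        diag_rows.append((name, _ess(s), _geweke_z(s)))
    vc_rows.append(("residual", keep_sig_e.mean(), keep_sig_e.std(ddof=1),
                    np.quantile(keep_sig_e, 0.025), np.quantile(keep_sig_e, 0.975)))
    diag_rows.append(("residual", _ess(keep_sig_e), _geweke_z(keep_sig_e)))

    fitted = pd.Series(sum_yhat / kept, index=y.index, name="fitted")
    samples = pd.DataFrame(
        np.column_stack([keep_mu, keep_sig, keep_sig_e]),
        columns=["mu"] + [f"var_{t}" for t in term_names] + ["var_residual"])
    return FitResult(
        labels=list(y.index),
        mu_mean=float(keep_mu.mean()),
        term_effects={name: sum_u[k] / kept for k, name in enumerate(term_names)},
        variance_components=pd.DataFrame(
            vc_rows, columns=["term", "mean", "sd", "q2.5", "q97.5"]
        ).set_index("term"),
        residual_variance=float(keep_sig_e.mean()),
        predictions=fitted[~obs_mask],
        fitted=fitted,
        samples=samples,
        diagnostics=pd.DataFrame(
            diag_rows, columns=["term", "ess", "geweke_z"]).set_index("term"),
        masked=~obs_mask,
    )


def gblup_oracle(y: pd.Series, kernels, variances: dict):
    """Closed-form BLUP at fixed variance components.

    Solves the generalized-least-squares mixed-model equations on the
    observed rows and propagates effects to all rows through the kernels:

        u_k = sigma_k^2 K_k[:, obs] V_obs^{-1} (y_obs - mu_hat)

    Exact up to linear-solver tolerance; serves as the correctness oracle
    for the Gibbs sampler.
    """
    y = pd.Series(y).astype(float)
    obs = np.isfinite(y.to_numpy())
    named = _align_kernels(y, kernels)
    sig_e = float(variances["residual"])
    n_obs = int(obs.sum())
    Voo = sig_e * np.eye(n_obs)
    for name, A in named:
        Voo = Voo + float(variances[name]) * A[np.ix_(obs, obs)]
    yo = y.to_numpy()[obs]
    Vi = np.linalg.inv(Voo)
    ones = np.ones(n_obs)
    mu = float(ones @ Vi @ yo) / float(ones @ Vi @ ones)
    alpha = Vi @ (yo - mu)
    effects = {}
    pred = np.full(len(y), mu)
    for name, A in named:
        u = float(variances[name]) * (A[:, obs] @ alpha)
        effects[name] = u
        pred = pred + u
    return {"mu": mu,
            "effects": effects,
            "predictions": pd.Series(pred, index=y.index, name="prediction")}


def predict(fit: FitResult, target_labels) -> pd.Series:
    """Posterior predictive means for masked/target observations.

    Targets must appear among the fit's observation labels (they enter the
    model as masked rows connected through kernel rows). A fully
    disconnected target is predicted at the intercept with a warning.
    """
    index = {l: i for i, l in enumerate(fit.labels)}
    missing = [t for t in target_labels if t not in index]
    if missing:
        raise KeyError(f"labels absent from the fit: {missing[:5]}")
    total_eff = np.sum(list(fit.term_effects.values()), axis=0)
    scale = max(float(np.abs(total_eff).max()), 1.0)
    flat = [t for t in target_labels
            if abs(total_eff[index[t]]) < 1e-12 * scale]
    if flat:
        warnings.warn(f"{len(flat)} disconnected target(s) predicted at the "
                      "intercept (zero kernel rows)")
    vals = [fit.fitted.iloc[index[t]] for t in target_labels]
    return pd.Series(vals, index=list(target_labels), name="prediction")


def variance_partition(fit: FitResult) -> pd.Series:
    """Share of the modeled (non-residual) variance attributed to each term."""
    vc = fit.variance_components["mean"].drop("residual")
    total = float(vc.sum())
    if total <= 0:
        raise ValueError("no modeled variance to partition")
    return vc / total
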