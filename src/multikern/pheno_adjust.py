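"""Stage-1 phenotypic adjustment: mixed-model BLUEs and heritability.

The plot model for a trait Y of genotype i in environment j, replicate k,
block l is

    Y_ijkl = mu + g_i + E_j + gE_ij + R_k + B_l(k,j) + e_ijkl

with blocking random and genotype fixed for BLUE runs; for heritability
runs every term except the mean is random and broad-sense heritability on
a line-mean basis is

    H2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r) * 100

computed separately per environment with r the replicate count.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations with Aitken acceleration (max 500 iterations, convergence when
the relative REML log-likelihood change drops below 1e-8). Negative
boundary estimates are clamped at zero and flagged. Days to heading (DTH)
can enter the BLUE model as a centered fixed covariate to deconfound
maturity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["AdjustmentModel", "MixedModelFit", "ConvergenceError",
           "fit_mixed_model", "compute_blues", "heritability",
           "h2_from_components",
           "band_blues_and_h2", "band_columns"]


class ConvergenceError(RuntimeError):
    """EM-REML failed to converge; carries the iteration trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class AdjustmentModel:
    """Declarative description of one mixed-model run."""

    response: str = "GY"
    genotype_fixed: bool = True       # False -> genotype random (H2 runs)
    dth_covariate: bool = False
    include_env: bool = False         # adds env fixed + genotype-x-env random
    random_terms: tuple = ("rep", "block")


@dataclass
class MixedModelFit:
    variance_components: dict
    fixed_effects: pd.Series
    fixed_cov: np.ndarray
    random_effects: dict
    loglik: float
    n_iter: int
    boundary_flags: list
    blues: pd.Series | None = None
    blue_se: pd.Series | None = None


def _dummies(values) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(values))
    idx = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    for r, v in enumerate(values):
        Z[r, idx[v]] = 1.0
    return Z, levels


def _check_connectivity(plots: pd.DataFrame) -> None:
    """Genotypes must form one connected component through shared blocks."""
    key = plots["env"].astype(str) + ":" + plots["rep"].astype(str) + ":" + \
        plots["block"].astype(str)
    g_levels = {g: i for i, g in enumerate(sorted(plots["line"].unique()))}
    b_levels = {b: i for i, b in enumerate(sorted(key.unique()))}
    ng = len(g_levels)
    rows = [g_levels[g] for g in plots["line"]]
    cols = [ng + b_levels[b] for b in key]
    n = ng + len(b_levels)
    data = np.ones(len(rows) * 2)
    adj = coo_matrix((data, (rows + cols, cols + rows)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"design is disconnected ({n_comp} components); genotype "
            "contrasts across components are not estimable")


class _MMEWorkspace:
    """Precomputed cross-products for EM-REML; reusable across responses.

    Designed for the per-band loop: the design (X and random-term Z's) is
    identical for every waveband within an environment, so X'X, X'Z and
    Z'Z are built once and only the response projections change.
    """

    def __init__(self, X: np.ndarray, Zs: dict[str, np.ndarray]):
        self.X = X
        self.Zs = Zs
        self.names = list(Zs)
        self.p = X.shape[1]
        self.q = [Zs[k].shape[1] for k in self.names]
        W = np.hstack([X] + [Zs[k] for k in self.names])
        self.W = W
        self.WtW = W.T @ W
        self.n = X.shape[0]
        # column rank of X (design built to be full rank; verify)
        self.rank_x = np.linalg.matrix_rank(self.X)
        if self.rank_x < self.p:
            raise ValueError("singular fixed-effects design (aliased levels)")
        self.offsets = np.cumsum([self.p] + self.q)

    def _ll_at(self, sig, sig_e, Wty, yty, floor):
        """REML log-likelihood (up to constant) at given components."""
        M = self.WtW.copy()
        for k in range(len(self.names)):
            a, b = self.offsets[k], self.offsets[k + 1]
            M[np.arange(a, b), np.arange(a, b)] += sig_e / max(sig[k], floor)
        cf = cho_factor(M)
        sol = cho_solve(cf, Wty)
        sse = yty - float(sol @ Wty)
        logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return -0.5 * ((self.n - self.rank_x) * np.log(sig_e)
                       + sum(qk * np.log(max(s, floor) / sig_e)
                             for qk, s in zip(self.q, sig))
                       + logdetM + sse / sig_e)

    def reml(self, y: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
             floor_frac: float = 1e-8):
        y = np.asarray(y, float)
        vy = y.var()
        if vy == 0.0:
            beta = np.zeros(self.p)
            beta[0] = y[0] if self.p else 0.0
            vc = {k: 0.0 for k in self.names}
            vc["residual"] = 0.0
            return {"vc": vc, "beta": beta, "u": {k: np.zeros(q) for k, q in
                    zip(self.names, self.q)},
                    "Cinv_xx": np.zeros((self.p, self.p)), "loglik": 0.0,
                    "n_iter": 0, "flags": ["constant response"]}
        floor = floor_frac * vy
        m = len(self.names)
        sig = np.full(m, vy / (m + 1.0))
        sig_e = vy / (m + 1.0)
        pinned = np.zeros(m, dtype=bool)   # boundary components held at floor
        shrinking = np.zeros(m, dtype=int)
        Wty = self.W.T @ y
        yty = float(y @ y)
        trace = []
        prev_sig = None
        prev_ll = -np.inf
        plateau = 0
        ll_hist = []
        flags = []
        converged = False
        for it in range(1, max_iter + 1):
            M = self.WtW.copy()
            for k in range(m):
                a, b = self.offsets[k], self.offsets[k + 1]
                lam = sig_e / max(sig[k], floor)
                M[np.arange(a, b), np.arange(a, b)] += lam
            cf = cho_factor(M)
            sol = cho_solve(cf, Wty)
            Minv = cho_solve(cf, np.eye(M.shape[0]))
            sse = yty - float(sol @ Wty)
            sig_e_new = sse / (self.n - self.rank_x)
            sig_new = np.empty(m)
            for k in range(m):
                if pinned[k]:
                    sig_new[k] = floor
                    continue
                a, b = self.offsets[k], self.offsets[k + 1]
                u_k = sol[a:b]
                tr = np.trace(Minv[a:b, a:b])
                sig_new[k] = (float(u_k @ u_k) + sig_e * tr) / self.q[k]
            # REML log-likelihood (up to a constant) at the *current* sig
            logdetM = 2.0 * np.sum(np.log(np.diag(cf[0])))
            ll = -0.5 * ((self.n - self.rank_x) * np.log(sig_e)
                         + sum(qk * np.log(max(s, floor) / sig_e)
                               for qk, s in zip(self.q, sig))
                         + logdetM + sse / sig_e)
            trace.append((it, ll, sig_e, tuple(sig)))
            # EM approaches a zero-boundary component sublinearly (~1/t);
            # after a long monotone shrink, test the boundary explicitly:
            # pin iff the REML criterion does not drop with the component
            # at the floor
            shrink_now = (sig_new < sig) & ~pinned
            shrinking = np.where(shrink_now, shrinking + 1, 0)
            for k in np.flatnonzero((shrinking >= 30) & (sig_new < 0.05 * vy)):
                sig_test = sig_new.copy()
                sig_test[k] = floor
                ll_test = self._ll_at(sig_test, sig_e_new, Wty, yty, floor)
                ll_cur = self._ll_at(sig_new, sig_e_new, Wty, yty, floor)
                if ll_test >= ll_cur - 1e-6 * (abs(ll_cur) + 1.0):
                    pinned[k] = True
                    sig_new[k] = floor
                shrinking[k] = 0
            free = ~pinned
            old = np.append(sig[free], sig_e)
            new = np.append(sig_new[free], sig_e_new)
            rel_change = (np.max(np.abs(new - old) / (old + floor))
                          if len(old) else
                          abs(sig_e_new - sig_e) / (sig_e + floor))
            # secondary stop: a sustained likelihood plateau (catches flat
            # ridges from collinear random terms, where individual
            # components drift without changing the fit)
            plateau = (plateau + 1
                       if abs(ll - prev_ll) <= 1e-9 * (abs(ll) + 1.0) else 0)
            prev_ll = ll
            ll_hist.append(ll)
            # windowed plateau: EM is monotone, so a tiny gain over 40
            # sweeps means the criterion surface is flat at the scale that
            # matters, even if individual components still crawl
            flat_window = (len(ll_hist) >= 45
                           and ll_hist[-1] - ll_hist[-41]
                           <= 2e-7 * (abs(ll) + 1.0))
            if rel_change < tol or plateau >= 10 or flat_window:
                if rel_change >= tol:
                    flags.append("converged on likelihood plateau "
                                 "(flat criterion surface)")
                sig, sig_e = sig_new, sig_e_new
                converged = True
                break
            # per-component Aitken acceleration every 4th step, accepted
            # only when it improves the REML criterion (EM alone is safe but
            # linearly slow for weakly identified components)
            if prev_sig is not None and it % 4 == 0:
                cur = np.append(sig, sig_e)
                nxt = np.append(sig_new, sig_e_new)
                d1 = nxt - cur
                d0 = cur - prev_sig
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(np.abs(d0) > 0, d1 / d0, 0.0)
                ok = (r > 0.0) & (r < 0.999)
                acc = np.maximum(np.where(ok, nxt + r / (1.0 - r) * d1, nxt),
                                 floor)
                if np.any(acc != nxt):
                    ll_acc = self._ll_at(acc[:-1], acc[-1], Wty, yty, floor)
                    ll_nxt = self._ll_at(nxt[:-1], nxt[-1], Wty, yty, floor)
                    if ll_acc > ll_nxt:
                        sig_new = np.where(free, acc[:-1], sig_new)
                        sig_e_new = float(acc[-1])
            prev_sig = np.append(sig, sig_e)
            sig, sig_e = np.maximum(sig_new, floor), max(sig_e_new, floor)
        else:
            raise ConvergenceError(
                f"EM-REML did not converge in {max_iter} iterations", trace)
        if not converged:  # pragma: no cover
            raise ConvergenceError("EM-REML did not converge", trace)
        sig[pinned] = floor
        # final solve at converged components
        M = self.WtW.copy()
        for k in range(m):
            a, b = self.offsets[k], self.offsets[k + 1]
            M[np.arange(a, b), np.arange(a, b)] += sig_e / max(sig[k], floor)
        cf = cho_factor(M)
        sol = cho_solve(cf, Wty)
        Minv = cho_solve(cf, np.eye(M.shape[0]))
        vc = {}
        for k, name in enumerate(self.names):
            val = sig[k]
            if val <= 2 * floor:
                flags.append(f"{name} variance at zero boundary")
                val = 0.0
            vc[name] = float(val)
        vc["residual"] = float(sig_e)
        u = {name: sol[self.offsets[k]:self.offsets[k + 1]]
             for k, name in enumerate(self.names)}
        return {"vc": vc, "beta": sol[:self.p], "u": u,
                "Cinv_xx": sig_e * Minv[:self.p, :self.p],
                "loglik": trace[-1][1], "n_iter": len(trace), "flags": flags}


def _build_design(plots: pd.DataFrame, model: AdjustmentModel):
    """Return X, fixed labels, BLUE contrast rows, and random-term Z's."""
    n = len(plots)
    fixed_cols = [np.ones((n, 1))]
    fixed_names = ["intercept"]
    Zg, g_levels = _dummies(plots["line"])

    if model.genotype_fixed:
        fixed_cols.append(Zg[:, 1:])  # treatment coding, first level reference
        fixed_names += [f"g[{g}]" for g in g_levels[1:]]

    env_levels = []
    if model.include_env:
        Ze, env_levels = _dummies(plots["env"])
        fixed_cols.append(Ze[:, 1:])
        fixed_names += [f"E[{e}]" for e in env_levels[1:]]

    if model.dth_covariate:
        dth = plots["DTH"].to_numpy(float)
        fixed_cols.append((dth - dth.mean())[:, None])
        fixed_names.append("DTH")

    X = np.hstack(fixed_cols)

    Zs: dict[str, np.ndarray] = {}
    levels: dict[str, list] = {"genotype": g_levels, "env": env_levels}
    if not model.genotype_fixed:
        Zs["genotype"] = Zg
    if "rep" in model.random_terms:
        key = plots["env"].astype(str) + ":" + plots["rep"].astype(str)
        Zs["rep"], levels["rep"] = _dummies(key)
    if "block" in model.random_terms:
        key = (plots["env"].astype(str) + ":" + plots["rep"].astype(str)
               + ":" + plots["block"].astype(str))
        Zs["block"], levels["block"] = _dummies(key)
    if model.include_env:
        key = plots["line"].astype(str) + ":" + plots["env"].astype(str)
        Zs["gxe"], levels["gxe"] = _dummies(key)
    return X, fixed_names, Zs, levels


def fit_mixed_model(plots: pd.DataFrame, model: AdjustmentModel,
                    workspace: _MMEWorkspace | None = None) -> MixedModelFit:
    """Fit one mixed model by EM-REML and return components and effects."""
    y = plots[model.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if workspace is None:
        if model.genotype_fixed:
            _check_connectivity(plots)
        X, fixed_names, Zs, levels = _build_design(plots, model)
        workspace = _MMEWorkspace(X, Zs)
        workspace._fixed_names = fixed_names
        workspace._levels = levels
    res = workspace.reml(y)
    fit = MixedModelFit(
        variance_components=res["vc"],
        fixed_effects=pd.Series(res["beta"], index=workspace._fixed_names),
        fixed_cov=res["Cinv_xx"],
        random_effects=res["u"],
        loglik=res["loglik"],
        n_iter=res["n_iter"],
        boundary_flags=res["flags"],
    )
    if model.genotype_fixed:
        fit.blues, fit.blue_se = _genotype_blues(fit, workspace)
    return fit


def _genotype_blues(fit: MixedModelFit, ws: _MMEWorkspace):
    """Marginal genotype means: intercept + genotype effect (+ mean env)."""
    names = ws._fixed_names
    g_levels = ws._levels["genotype"]
    env_levels = ws._levels.get("env") or []
    p = len(names)
    L = np.zeros((len(g_levels), p))
    L[:, names.index("intercept")] = 1.0
    for i, g in enumerate(g_levels[1:], start=1):
        L[i, names.index(f"g[{g}]")] = 1.0
    if env_levels:
        # average over environments (reference env contributes 0)
        for e in env_levels[1:]:
            L[:, names.index(f"E[{e}]")] = 1.0 / len(env_levels)
    est = L @ fit.fixed_effects.to_numpy()
    se = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", L, fit.fixed_cov, L), 0.0))
    return (pd.Series(est, index=g_levels, name="BLUE"),
            pd.Series(se, index=g_levels, name="SE"))


def compute_blues(plots: pd.DataFrame, scope: str = "within_env",
                  dth_covariate: bool = True, trait: str = "GY") -> pd.DataFrame:
    """Genotype BLUEs (genotype fixed, blocking random), optionally per env.

    ``within_env`` fits each environment separately and returns one row per
    line x environment; ``across_env`` fits the multi-environment model
    (env fixed, genotype-by-environment random) and returns one row per
    line. DTH enters as a centered fixed covariate when requested.
    """
    if scope not in ("within_env", "across_env"):
        raise ValueError("scope must be 'within_env' or 'across_env'")
    frames = []
    if scope == "within_env":
        for env, sub in plots.groupby("env", sort=True):
            model = AdjustmentModel(response=trait, dth_covariate=dth_covariate)
            fit = fit_mixed_model(sub.reset_index(drop=True), model)
            frames.append(pd.DataFrame({
                "line": fit.blues.index, "env": env, "trait": trait,
                "estimate": fit.blues.to_numpy(), "se": fit.blue_se.to_numpy()}))
        return pd.concat(frames, ignore_index=True)
    model = AdjustmentModel(response=trait, dth_covariate=dth_covariate,
                            include_env=True)
    fit = fit_mixed_model(plots.reset_index(drop=True), model)
    return pd.DataFrame({"line": fit.blues.index, "trait": trait,
                         "estimate": fit.blues.to_numpy(),
                         "se": fit.blue_se.to_numpy()})


def h2_from_components(sigma_g2: float, sigma_e2: float, r: int) -> float:
    """Broad-sense heritability (%) on a line-mean basis with r replicates."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be nonnegative")
    denom = sigma_g2 + sigma_e2 / r
    if denom == 0.0:
        raise ValueError("H2 undefined: zero total variance")
    return 100.0 * sigma_g2 / denom


def heritability(plots: pd.DataFrame, trait: str = "GY", r: int | None = None
                 ) -> pd.Series:
    """Broad-sense heritability (%) per environment on a line-mean basis.

    All model terms random except the mean; H2 = sG2/(sG2 + se2/r) * 100
    with r the replicate count (the design count by default).
    """
    out = {}
    for env, sub in plots.groupby("env", sort=True):
        sub = sub.reset_index(drop=True)
        reps = r if r is not None else int(sub["rep"].nunique())
        model = AdjustmentModel(response=trait, genotype_fixed=False)
        fit = fit_mixed_model(sub, model)
        sg = fit.variance_components["genotype"]
        se2 = fit.variance_components["residual"]
        denom = sg + se2 / reps
        if denom == 0.0:
            raise ValueError(f"H2 undefined for env {env!r}: zero variance")
        out[env] = 100.0 * sg / denom
    return pd.Series(out, name=f"H2({trait})")


def band_columns(plots: pd.DataFrame) -> list:
    return [c for c in plots.columns if c.startswith("b") and c[1:].isdigit()]


def band_blues_and_h2(plots: pd.DataFrame, bands: list | None = None,
                      r: int | None = None):
    """Per-band BLUEs and heritability curves, per environment.

    Loops the BLUE and H2 machinery over every waveband column, reusing the
    design cross-products within each environment. Constant bands yield
    H2 = 0 with a flag rather than an error.

    Returns
    -------
    blues : DataFrame with columns line, env and one column per band.
    h2 : DataFrame env x band (percent), attribute-free plain table.
    """
    if bands is None:
        bands = band_columns(plots)
    if not bands:
        raise ValueError("no band columns found")
    blue_frames, h2_rows = [], {}
    for env, sub in plots.groupby("env", sort=True):
        sub = sub.reset_index(drop=True)
        reps = r if r is not None else int(sub["rep"].nunique())
        blue_model = AdjustmentModel(response=bands[0], genotype_fixed=True)
        Xb, fnb, Zb, levb = _build_design(sub, blue_model)
        ws_blue = _MMEWorkspace(Xb, Zb)
        ws_blue._fixed_names, ws_blue._levels = fnb, levb
        h2_model = AdjustmentModel(response=bands[0], genotype_fixed=False)
        Xh, fnh, Zh, levh = _build_design(sub, h2_model)
        ws_h2 = _MMEWorkspace(Xh, Zh)
        ws_h2._fixed_names, ws_h2._levels = fnh, levh

        blues = {}
        h2s = {}
        for b in bands:
            yb = sub[b].to_numpy(float)
            if yb.var() == 0.0:
                warnings.warn(f"band {b} constant in env {env!r}; H2 set to 0")
                g_levels = levb["genotype"]
                blues[b] = pd.Series(yb[0], index=g_levels)
                h2s[b] = 0.0
                continue
            m = AdjustmentModel(response=b, genotype_fixed=True)
            fit_b = fit_mixed_model(sub, m, workspace=ws_blue)
            blues[b] = fit_b.blues
            fit_h = fit_mixed_model(
                sub, AdjustmentModel(response=b, genotype_fixed=False),
                workspace=ws_h2)
            sg = fit_h.variance_components["genotype"]
            se2 = fit_h.variance_components["residual"]
            denom = sg + se2 / reps
            h2s[b] = 0.0 if denom == 0.0 else 100.0 * sg / denom
        bdf = pd.DataFrame(blues)
        bdf.insert(0, "env", env)
        bdf.insert(0, "line", bdf.index)
        blue_frames.append(bdf.reset_index(drop=True))
        h2_rows[env] = h2s
    blues_out = pd.concat(blue_frames, ignore_index=True)
    h2_out = pd.DataFrame.from_dict(h2_rows, orient="index")
    h2_out.index.name = "env"
    return blues_out, h2_out
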