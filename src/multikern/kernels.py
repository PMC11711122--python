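"""Relationship kernels and the nine nested model term lists.

Three base kernels drive every model:

* ``G = XX'/p`` — genomic relationship matrix from the column-standardized
  marker dosage matrix ``X`` (lines x p SNPs).
* ``P = SS'/m`` — hyperspectral relationship matrix from the standardized
  per-band BLUE matrix ``S`` (rows x m wavebands).
* ``K = WW'/q`` — environmental relationship matrix from standardized
  environmental-covariate features ``W`` (environments x q features).

Across-environment reaction-norm models place these on line-by-environment
observations via 0/1 incidence expansion ``Z K Z'`` and model interactions
(gE, HE, gw, Hw) as Hadamard products of the expanded matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelMatrix",
    "ModelSpec",
    "MODEL_SPECS",
    "standardize_columns",
    "linear_kernel",
    "expand_kernel",
    "interaction_kernel",
    "environment_kernel",
    "build_model_kernels",
]

_SYM_TOL = 1e-10
_PSD_TOL = -1e-8


@dataclass
class KernelMatrix:
    """A labeled symmetric PSD relationship matrix.

    Parameters
    ----------
    labels
        Unique row/column identifiers (lines, environments, or
        line-by-environment observation ids).
    values
        Symmetric matrix, PSD up to ``-1e-8`` on the smallest eigenvalue.
    kind
        One of ``{"G", "P", "K", "E", "expanded", "interaction", "generic"}``.
    """

    labels: list
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("kernel labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("kernel matrix is not symmetric")
        # enforce exact symmetry so downstream eigh sees a clean input
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.labels)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def ensure_psd(self, jitter: float = 1e-8) -> "KernelMatrix":
        """Return self, adding diagonal jitter at most once if needed."""
        lo = self.min_eigenvalue()
        if lo < _PSD_TOL:
            raise ValueError(f"kernel is not PSD (min eigenvalue {lo:.3e})")
        if lo < jitter:
            self.values = self.values + jitter * np.eye(self.n)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "generic") -> "KernelMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("kernel CSV must have identical row and column labels")
        return cls(labels=list(df.index), values=df.to_numpy(float), kind=kind)

    @classmethod
    def load_csv(cls, path, kind: str = "generic") -> "KernelMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0), kind=kind)


def standardize_columns(matrix, ddof: int = 0):
    """Center and scale every column to mean 0, sd 1 (population sd).

    Zero-variance columns are dropped with a warning. Accepts and returns
    either a DataFrame or an ndarray.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop == X.shape[1]:
        raise ValueError("all columns have zero variance")
    if n_drop:
        warnings.warn(f"dropping {n_drop} zero-variance column(s)", stacklevel=2)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    if is_df:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns[keep])
    return Z


def linear_kernel(matrix, labels=None, standardize: bool = True,
                  kind: str = "generic") -> KernelMatrix:
    """Cross-product kernel ``MM'/p`` after (optional) column standardization.

    This is the single recipe behind G (markers), P (band BLUEs) and
    K (EC features); the divisor is the retained column count, which puts
    the mean diagonal near 1 for standardized input.
    """
    if labels is None:
        if not isinstance(matrix, pd.DataFrame):
            raise ValueError("labels required when matrix is not a DataFrame")
        labels = list(matrix.index)
    M = standardize_columns(matrix) if standardize else matrix
    M = M.to_numpy(float) if isinstance(M, pd.DataFrame) else np.asarray(M, float)
    p = M.shape[1]
    if p == 0:
        raise ValueError("no columns left to build a kernel from")
    K = M @ M.T / p
    return KernelMatrix(labels=labels, values=K, kind=kind)


def incidence_matrix(obs_groups, group_labels) -> np.ndarray:
    """0/1 matrix Z with one 1 per row linking observations to group levels."""
    index = {g: i for i, g in enumerate(group_labels)}
    Z = np.zeros((len(obs_groups), len(group_labels)))
    for r, g in enumerate(obs_groups):
        if g not in index:
            raise KeyError(f"observation group {g!r} absent from kernel labels")
        Z[r, index[g]] = 1.0
    return Z


def expand_kernel(K: KernelMatrix, obs_groups, obs_labels=None) -> KernelMatrix:
    """Expand a group-level kernel to observation level: ``Z K Z'``.

    ``obs_groups`` maps each observation (in order) to a label of ``K``;
    entry (i, j) of the result is ``K[group(i), group(j)]``.
    """
    obs_groups = list(obs_groups)
    if obs_labels is None:
        obs_labels = list(range(len(obs_groups)))
    idx = {g: i for i, g in enumerate(K.labels)}
    try:
        rows = np.array([idx[g] for g in obs_groups])
    except KeyError as err:
        raise KeyError(f"observation group {err.args[0]!r} absent from kernel labels")
    V = K.values[np.ix_(rows, rows)]
    return KernelMatrix(labels=obs_labels, values=V, kind="expanded")


def interaction_kernel(A: KernelMatrix, B: KernelMatrix) -> KernelMatrix:
    """Hadamard (element-wise) product of two observation-level kernels.

    This is the reaction-norm interaction covariance: the product of
    conformable expanded matrices, PSD by the Schur product theorem.
    """
    if A.labels != B.labels:
        raise ValueError("interaction kernels must share observation labels and order")
    return KernelMatrix(labels=A.labels, values=A.values * B.values,
                        kind="interaction")


def environment_kernel(obs_envs, obs_labels=None) -> KernelMatrix:
    """Block kernel ZE ZE' — 1 where two observations share an environment."""
    obs_envs = list(obs_envs)
    if obs_labels is None:
        obs_labels = list(range(len(obs_envs)))
    e = np.asarray(obs_envs, dtype=object)
    V = (e[:, None] == e[None, :]).astype(float)
    return KernelMatrix(labels=obs_labels, values=V, kind="E")


@dataclass
class ModelSpec:
    """Declarative term list for one of the nine nested models."""

    name: str
    terms: tuple
    scope: str  # "within_env" | "across_env"
    description: str = ""


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", ("g",), "within_env", "genomic main effect"),
    "M2": ModelSpec("M2", ("H",), "within_env", "hyperspectral main effect"),
    "M3": ModelSpec("M3", ("g", "H"), "within_env", "genomic + hyperspectral"),
    "M4": ModelSpec("M4", ("E", "g", "gE"), "across_env", "G + GxE reaction norm"),
    "M5": ModelSpec("M5", ("E", "H", "HE"), "across_env", "H + HxE reaction norm"),
    "M6": ModelSpec("M6", ("E", "g", "H", "HE", "gE"), "across_env",
                    "G + H + GxE + HxE"),
    "M7": ModelSpec("M7", ("E", "g", "w", "gw", "gE"), "across_env",
                    "G + ECs + GxE + Gxw"),
    "M8": ModelSpec("M8", ("E", "H", "w", "HE", "Hw"), "across_env",
                    "H + ECs + HxE + Hxw"),
    "M9": ModelSpec("M9", ("E", "g", "w", "H", "HE", "Hw", "gE", "gw"),
                    "across_env", "comprehensive model"),
}


def build_model_kernels(spec, obs: pd.DataFrame, G: KernelMatrix | None = None,
                        P: KernelMatrix | None = None,
                        K: KernelMatrix | None = None,
                        literal_gw_uses_H: bool = False):
    """Assemble the ordered kernel list for one model.

    Parameters
    ----------
    spec
        A :class:`ModelSpec` or a model name ``"M1"``..``"M9"``.
    obs
        Observation table indexed by observation id with columns ``line``
        and (for across-environment scopes) ``env``.
    G, P, K
        Line-level genomic kernel, observation-level (or line-level, for
        within-environment scopes) hyperspectral kernel, and
        environment-level EC kernel. Only the kernels a model's terms need
        must be provided.
    literal_gw_uses_H
        Build the marker-by-EC interaction from the hyperspectral kernel
        instead of the genomic one (the literal printed covariance); off by
        default because the term is defined as a marker-by-covariate
        interaction.

    Returns
    -------
    list of (term_name, KernelMatrix) in the model's declared term order.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    obs_labels = list(obs.index)
    need = set(spec.terms)

    def _require(kern, symbol):
        if kern is None:
            raise ValueError(f"model {spec.name} needs the {symbol} kernel "
                             "but it was not provided")
        return kern

    out = []
    g_exp = None
    E_kern = None
    w_exp = None
    P_obs = None

    if {"g", "gE", "gw"} & need:
        Gk = _require(G, "G")
        g_exp = expand_kernel(Gk, obs["line"], obs_labels)
    if {"E", "gE", "HE"} & need:
        E_kern = environment_kernel(obs["env"], obs_labels)
    if {"w", "gw", "Hw"} & need:
        Kk = _require(K, "K (ECs)")
        w_exp = expand_kernel(Kk, obs["env"], obs_labels)
    if {"H", "HE", "Hw", "gw" if literal_gw_uses_H else ""} & need:
        Pk = _require(P, "P (hyperspectral)")
        if Pk.labels == obs_labels:
            P_obs = Pk
        else:
            P_obs = expand_kernel(Pk, obs["line"], obs_labels)

    for term in spec.terms:
        if term == "g":
            out.append(("g", g_exp))
        elif term == "E":
            out.append(("E", E_kern))
        elif term == "w":
            out.append(("w", w_exp))
        elif term == "H":
            out.append(("H", P_obs))
        elif term == "gE":
            out.append(("gE", interaction_kernel(g_exp, E_kern)))
        elif term == "HE":
            out.append(("HE", interaction_kernel(P_obs, E_kern)))
        elif term == "gw":
            base = P_obs if literal_gw_uses_H else g_exp
            out.append(("gw", interaction_kernel(base, w_exp)))
        elif term == "Hw":
            out.append(("Hw", interaction_kernel(P_obs, w_exp)))
        else:  # pragma: no cover - guarded by ModelSpec construction
            raise ValueError(f"unknown term {term!r}")
    return out
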