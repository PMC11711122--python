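"""Machine-learning comparison arm: RFR, GBR, RBF-SVM and a dense network.

Each regressor is trained on a column-wise concatenation of feature blocks
— imputed marker dosages (G), per-band BLUEs (H), and environment-level EC
features broadcast to observations (w) — and tuned by exhaustive grid
search with inner k-fold cross-validation. Per-block standardization is
part of the estimator pipeline, so scalers are fitted on training rows
only and no test information leaks into model selection.

Default hyperparameter grids:

* SVMR (RBF): C in [0.1, 1, 10, 100], gamma in [0.001, 0.01, 0.1, 1]
* RFR: n_estimators in [100, 500, 1000]; max_features in [all, sqrt, log2]
* GBR: learning_rate in [0.01, 0.1, 0.2]; max_depth in [3, 5, 7];
  n_estimators in [50, 100, 200]
* ANN: 1-3 hidden layers of 32/64/128 ReLU (or sigmoid) units, linear
  output, Adam or SGD on mean squared error, learning rate in
  [0.001, 0.01, 0.1], early stopping on a 10% validation split
  (patience 20 epochs, max 500).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics import make_scorer
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = ["FeatureBlockSpec", "GridSpec", "DEFAULT_GRIDS",
           "assemble_features", "tune_and_fit", "ann_build_and_train"]


@dataclass
class FeatureBlockSpec:
    """Which feature blocks feed the regressor, and whether to scale them."""

    blocks: tuple = ("G",)
    scaling: bool = True

    def __post_init__(self) -> None:
        bad = set(self.blocks) - {"G", "H", "w"}
        if bad:
            raise ValueError(f"unknown blocks: {sorted(bad)}")
        if not self.blocks:
            raise ValueError("at least one feature block required")


def _ann_architectures():
    sizes = (32, 64, 128)
    archs = []
    for depth in (1, 2, 3):
        archs += list(itertools.product(sizes, repeat=depth))
    return archs


DEFAULT_GRIDS: dict[str, dict] = {
    "SVMR": {"model__C": [0.1, 1, 10, 100],
             "model__gamma": [0.001, 0.01, 0.1, 1]},
    "RFR": {"model__n_estimators": [100, 500, 1000],
            # 1.0 = all features, the historical regressor meaning of "auto"
            "model__max_features": [1.0, "sqrt", "log2"]},
    "GBR": {"model__learning_rate": [0.01, 0.1, 0.2],
            "model__max_depth": [3, 5, 7],
            "model__n_estimators": [50, 100, 200]},
    "ANN": {"model__hidden_layer_sizes": _ann_architectures(),
            "model__activation": ["relu", "logistic"],
            "model__solver": ["adam", "sgd"],
            "model__learning_rate_init": [0.001, 0.01, 0.1]},
}


@dataclass
class GridSpec:
    """One ML model plus its hyperparameter grid and inner-CV settings."""

    model: str
    grid: dict | None = None
    inner_cv_folds: int = 5
    feature_blocks: FeatureBlockSpec = field(
        default_factory=lambda: FeatureBlockSpec(("G", "H")))
    scoring: str = "pearson"   # "pearson" | "neg_mse"

    def __post_init__(self) -> None:
        if self.model not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {sorted(DEFAULT_GRIDS)}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model].items()}
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("empty hyperparameter list in grid")


def assemble_features(spec: FeatureBlockSpec, targets: pd.DataFrame,
                      markers: pd.DataFrame | None = None,
                      band_blues: pd.DataFrame | None = None,
                      ecs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Concatenate the requested feature blocks for each target observation.

    ``targets`` is indexed by observation id with columns ``line`` (and
    ``env`` when the w block or per-environment band BLUEs are used).
    Marker rows are looked up by line, band BLUEs by (line, env) or line,
    and EC features are broadcast to every observation of an environment.
    Columns are prefixed with their block name; scaling happens inside the
    tuned pipeline, never here.
    """
    parts = []
    if "G" in spec.blocks:
        if markers is None:
            raise ValueError("G block requested but no marker table given")
        miss = set(targets["line"]) - set(markers.index)
        if miss:
            raise ValueError(f"lines missing from marker table: {sorted(miss)[:5]}")
        part = markers.loc[targets["line"]].to_numpy(float)
        parts.append(pd.DataFrame(part, index=targets.index,
                                  columns=[f"G:{c}" for c in markers.columns]))
    if "H" in spec.blocks:
        if band_blues is None:
            raise ValueError("H block requested but no band BLUE table given")
        if isinstance(band_blues.index, pd.MultiIndex):
            keys = list(zip(targets["line"], targets["env"]))
        else:
            keys = list(targets["line"])
        miss = [k for k in keys if k not in band_blues.index]
        if miss:
            raise ValueError(f"targets missing from band BLUEs: {miss[:5]}")
        part = band_blues.loc[keys].to_numpy(float)
        parts.append(pd.DataFrame(part, index=targets.index,
                                  columns=[f"H:{c}" for c in band_blues.columns]))
    if "w" in spec.blocks:
        if ecs is None:
            raise ValueError("w block requested but no EC table given")
        miss = set(targets["env"]) - set(ecs.index)
        if miss:
            raise ValueError(f"environments missing from EC table: {sorted(miss)}")
        part = ecs.loc[targets["env"]].to_numpy(float)
        parts.append(pd.DataFrame(part, index=targets.index,
                                  columns=[f"w:{c}" for c in ecs.columns]))
    return pd.concat(parts, axis=1)


def _pearson_score(y_true, y_pred):
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def _base_estimator(name: str, seed: int | None):
    if name == "SVMR":
        return SVR(kernel="rbf")
    if name == "RFR":
        return RandomForestRegressor(random_state=seed)
    if name == "GBR":
        return GradientBoostingRegressor(random_state=seed)
    if name == "ANN":
        return MLPRegressor(random_state=seed, max_iter=500,
                            early_stopping=True, validation_fraction=0.1,
                            n_iter_no_change=20)
    raise ValueError(name)


def _block_scaler(features: pd.DataFrame) -> ColumnTransformer:
    blocks = {}
    for i, c in enumerate(features.columns):
        blocks.setdefault(str(c).split(":", 1)[0], []).append(i)
    return ColumnTransformer(
        [(f"scale_{b}", StandardScaler(), cols) for b, cols in blocks.items()],
        remainder="drop")


def tune_and_fit(spec: GridSpec, features: pd.DataFrame, y_train: pd.Series,
                 seed: int | None = 0):
    """Exhaustive grid search with inner k-fold CV, then refit on all rows.

    Selection maximizes the mean inner-CV Pearson correlation between
    held-out predictions and responses (negative MSE available via the
    spec). Returns the fitted pipeline and a run report with the chosen
    point and the full inner-CV table.
    """
    y = np.asarray(y_train, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training responses")
    if np.std(y) == 0:
        raise ValueError("constant training response")
    pipe = Pipeline([
        ("scale", _block_scaler(features)),
        ("model", _base_estimator(spec.model, seed)),
    ])
    scorer = (make_scorer(_pearson_score) if spec.scoring == "pearson"
              else "neg_mean_squared_error")
    cv = KFold(n_splits=spec.inner_cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, spec.grid, scoring=scorer, cv=cv, refit=True,
                          n_jobs=None)
    search.fit(features.to_numpy(float), y)
    report = {
        "model": spec.model,
        "seed": seed,
        "blocks": list(spec.feature_blocks.blocks),
        "chosen": {k.replace("model__", ""): v
                   for k, v in search.best_params_.items()},
        "inner_cv_mean_score": float(search.best_score_),
        "n_candidates": len(search.cv_results_["params"]),
        "inner_cv_table": pd.DataFrame({
            "params": [str(p) for p in search.cv_results_["params"]],
            "mean_score": search.cv_results_["mean_test_score"],
        }),
    }
    return search.best_estimator_, report


def ann_build_and_train(architecture: tuple, features: pd.DataFrame,
                        y: pd.Series, activation: str = "relu",
                        solver: str = "adam", learning_rate_init: float = 0.001,
                        seed: int | None = 0, max_epochs: int = 500,
                        patience: int = 20):
    """Train one dense network at a fixed architecture point.

    Hidden layers use ReLU (or sigmoid), the output is linear, training
    minimizes mean squared error by backpropagation with early stopping on
    a 10% validation split. Aborts on non-finite loss.
    """
    net = Pipeline([
        ("scale", _block_scaler(features)),
        ("model", MLPRegressor(
            hidden_layer_sizes=tuple(architecture), activation=activation,
            solver=solver, learning_rate_init=learning_rate_init,
            random_state=seed, max_iter=max_epochs, early_stopping=True,
            validation_fraction=0.1, n_iter_no_change=patience)),
    ])
    yv = np.asarray(y, float)
    if np.std(yv) == 0:
        # degenerate target: constant predictor
        class _Const:
            def __init__(self, c):
                self.c = c

            def predict(self, X):
                return np.full(len(X), self.c)

        return _Const(float(yv[0]))
    net.fit(features.to_numpy(float), yv)
    loss = net.named_steps["model"].loss_
    if not np.isfinite(loss):
        raise RuntimeError(f"ANN training diverged (loss={loss})")
    return net
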