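"""Machine-learning arm: grid-tuned random forest on marker + band features.

Concatenates imputed marker dosages (G block) and per-band BLUEs (H block)
for one year, tunes a random-forest regressor by exhaustive grid search
with 5-fold inner CV (selection metric: Pearson correlation), and scores
it on a held-out 20% of lines. The same feature plumbing drives the SVM,
gradient-boosting and neural-network regressors via their printed default
grids (ml.DEFAULT_GRIDS).
"""

import numpy as np

import multikern as mk
from multikern import experiments, ml

cfg = experiments.within_year_study_config(seed=5)
markers, plots, weather, _ = mk.simulate_dataset(cfg)
data = mk.prepare_dataset(markers, plots, weather)

obs = data.obs.copy()
obs.index = list(obs["line"])
rng = np.random.default_rng(0)
lines = rng.permutation(obs.index.to_numpy())
train, test = lines[: int(0.8 * len(lines))], lines[int(0.8 * len(lines)):]

spec = ml.GridSpec("RFR", grid={"model__n_estimators": [100, 300],
                                "model__max_features": [1.0, "sqrt"]},
                   feature_blocks=ml.FeatureBlockSpec(("G", "H")))
feats = ml.assemble_features(spec.feature_blocks, obs,
                             markers=data.markers_imputed,
                             band_blues=data.band_blues)
est, report = ml.tune_and_fit(spec, feats.loc[train], obs.loc[train, "y"],
                              seed=0)
pred = est.predict(feats.loc[test].to_numpy(float))
rho = mk.pearson_rho(pred, obs.loc[test, "y"])
print(f"chosen hyperparameters: {report['chosen']}")
print(f"inner-CV mean Pearson score: {report['inner_cv_mean_score']:.3f} "
      f"over {report['n_candidates']} grid points")
print(f"held-out accuracy (rho, n={len(test)} lines): {rho:.3f}")
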