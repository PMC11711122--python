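"""Forward prediction: train on 2021+2022, predict grain yield in 2023.

Masks the 2023 yields (the year's hyperspectral and weather data remain
available — both are measured on the validation-year trial itself) and
compares three kernel models: genomic-only M1, phenomic reaction-norm M5,
and the comprehensive M9. The report shows the Pearson accuracy in the
held-out year and the coincide index — the percentage of the true top-25%
yielding lines that the model also ranks in its top 25% (25% would be
chance level).
"""

import multikern as mk
from multikern import experiments

cfg = experiments.forward_study_config(seed=8)
markers, plots, weather, _ = mk.simulate_dataset(cfg)
data = mk.prepare_dataset(markers, plots, weather)

plan = mk.make_forward_plan(data.obs, ["2021", "2022"], "2023")
report = mk.run_benchmark(["M1", "M5", "M9"], plan, data,
                          mcmc=mk.MCMCConfig(n_iter=3000, burn_in=600, seed=1))
cols = ["model", "rho[2023]", "rho_weighted", "coincide_index"]
print(report[cols].round(3).to_string(index=False))
print("\nrho[2023]: correlation of predicted vs observed 2023 yield BLUEs;")
print("coincide_index: % overlap of predicted and observed top-25% lines.")
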