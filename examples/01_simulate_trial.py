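"""Generate a synthetic multi-year wheat trial and check its heritability.

Builds a reduced three-year panel (partial line overlap, two replicates in
incomplete blocks, family-structured SNPs, hyperspectral bands, daily
weather), then estimates within-year broad-sense heritability from the
plot table. The printed H2 values vary with year because each year
re-draws its line set, its share of genotype-by-environment deviations,
and its field effects.
"""

import multikern as mk

cfg = mk.SimConfig(
    n_lines_per_year={"2021": 120, "2022": 100, "2023": 80},
    n_overlap={("2021", "2022"): 24, ("2022", "2023"): 20,
               ("2021", "2023"): 8, ("2021", "2022", "2023"): 5},
    n_markers=500, n_bands=20, blocks_per_rep=5, seed=42)

markers, plots, weather, truth = mk.simulate_dataset(cfg)

print(f"lines x markers: {markers.n_lines} x {markers.n_markers}")
print(f"plots: {len(plots)} rows "
      f"({plots.groupby('env').size().to_dict()} per year, 2 reps each)")
print(f"daily weather rows: {len(weather)}")
print()
print(plots[["plot_id", "line", "env", "rep", "block", "DTH", "GY"]].head())
print()
h2 = mk.heritability(plots)          # all terms random except the mean
print("within-year broad-sense heritability of grain yield (%):")
print(h2.round(1).to_string())
print("(H2 = sG2/(sG2 + se2/r) x 100 with r = 2 replicates; the "
      f"{cfg.h2_yield * 100:.0f}% dial sets the genetic main effect — "
      "realized within-year H2 also counts the year-specific GxE and "
      "heritable-maturity channels, so it sits above the dial)")
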