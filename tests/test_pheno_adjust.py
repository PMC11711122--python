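import numpy as np
import pandas as pd
import pytest

import multikern as mk
from multikern import pheno_adjust, simdata
from multikern.pheno_adjust import (AdjustmentModel, compute_blues,
                                    fit_mixed_model, h2_from_components,
                                    heritability)

from conftest import single_year_config


def balanced_plots(n_geno=20, n_reps=2, var_g=2.0, var_e=2.0, seed=0,
                   mu=10.0):
    """Complete balanced design: every genotype once per replicate, one
    block per replicate (so genotype means need no block adjustment)."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(var_g), n_geno)
    rows = []
    for k in range(1, n_reps + 1):
        for i in range(n_geno):
            rows.append((f"P{k}{i}", f"G{i:03d}", "2021", k, "B1", 100.0,
                         mu + g[i] + rng.normal(0, np.sqrt(var_e))))
    return pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                       "block", "DTH", "GY"]), g


class TestFitMixedModel:
    def test_balanced_blues_equal_raw_means(self):
        plots, _ = balanced_plots(seed=1)
        fit = fit_mixed_model(plots, AdjustmentModel())
        raw = plots.groupby("line")["GY"].mean()
        assert np.max(np.abs(fit.blues - raw.loc[fit.blues.index])) < 1e-8

    def test_constant_response_degenerates(self):
        plots, _ = balanced_plots(seed=2)
        plots["GY"] = 7.5
        fit = fit_mixed_model(plots, AdjustmentModel())
        assert all(v == 0.0 for v in fit.variance_components.values())
        assert np.allclose(fit.blues, 7.5)

    def test_reml_matches_anova_on_balanced_design(self):
        # one-way random model: EMS closed form sigma_e = MSE,
        # sigma_g = (MSB - MSE)/r
        plots, _ = balanced_plots(n_geno=40, n_reps=3, seed=3)
        model = AdjustmentModel(genotype_fixed=False, random_terms=())
        fit = fit_mixed_model(plots, model)
        wide = plots.pivot_table(index="line", values="GY", aggfunc="mean")
        grand = plots["GY"].mean()
        r = 3
        msb = r * ((wide["GY"] - grand) ** 2).sum() / (len(wide) - 1)
        within = plots.groupby("line")["GY"].transform("mean")
        mse = ((plots["GY"] - within) ** 2).sum() / (len(plots) - len(wide))
        sg_anova = (msb - mse) / r
        assert fit.variance_components["residual"] == pytest.approx(mse, rel=1e-6)
        assert fit.variance_components["genotype"] == pytest.approx(sg_anova,
                                                                    rel=1e-6)

    def test_recovery_of_planted_components(self):
        # (sigma_G2, sigma_block2, sigma_e2) = (2, 1, 2) on incomplete blocks
        rng = np.random.default_rng(42)
        ests = {"genotype": [], "block": [], "residual": []}
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n_geno, n_blocks = 200, 10
            g = rng.normal(0, np.sqrt(2.0), n_geno)
            rows = []
            for k in (1, 2):
                order = rng.permutation(n_geno)
                beff = rng.normal(0, 1.0, n_blocks)
                for pos, i in enumerate(order):
                    b = pos * n_blocks // n_geno
                    rows.append((f"p{k}{pos}", f"G{i}", "e", k, f"R{k}B{b}",
                                 0.0, g[i] + beff[b] + rng.normal(0, np.sqrt(2.0))))
            plots = pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                                "block", "DTH", "GY"])
            fit = fit_mixed_model(
                plots, AdjustmentModel(genotype_fixed=False,
                                       random_terms=("block",)))
            for term, tv in (("genotype", 2.0), ("block", 1.0),
                             ("residual", 2.0)):
                ests[term].append(fit.variance_components[term])
        for term, tv in (("genotype", 2.0), ("block", 1.0), ("residual", 2.0)):
            assert np.mean(ests[term]) == pytest.approx(tv, rel=0.15)

    def test_disconnected_design_rejected(self):
        rows = []
        for i, (g, b) in enumerate([("A", "B1"), ("A", "B1"), ("B", "B2"),
                                    ("B", "B2")]):
            rows.append((f"p{i}", g, "e", 1, b, 0.0, float(i)))
        plots = pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                            "block", "DTH", "GY"])
        with pytest.raises(ValueError, match="disconnected"):
            fit_mixed_model(plots, AdjustmentModel())


class TestComputeBlues:
    def test_single_genotype_mean(self):
        rng = np.random.default_rng(0)
        rows = [(f"p{i}", "G1", "2021", 1 + i % 2, f"B{i % 2}", 0.0,
                 5.0 + rng.normal()) for i in range(10)]
        plots = pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                            "block", "DTH", "GY"])
        out = compute_blues(plots, dth_covariate=False)
        assert out["estimate"].iloc[0] == pytest.approx(plots["GY"].mean(),
                                                        abs=0.5)

    def test_balanced_toy_hand_arithmetic(self):
        # 3 genotypes x 2 reps, one block each: BLUE = genotype mean
        vals = [10.0, 12.0, 8.0, 9.0, 14.0, 15.0]
        rows = []
        for i, v in enumerate(vals):
            rows.append((f"p{i}", f"G{i % 3}", "2021", 1 + i // 3, "B1", 0.0, v))
        plots = pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                            "block", "DTH", "GY"])
        out = compute_blues(plots, dth_covariate=False).set_index("line")
        assert out.loc["G0", "estimate"] == pytest.approx((10 + 9) / 2, abs=1e-6)
        assert out.loc["G1", "estimate"] == pytest.approx((12 + 14) / 2, abs=1e-6)
        assert out.loc["G2", "estimate"] == pytest.approx((8 + 15) / 2, abs=1e-6)

    def test_dth_covariate_improves_genetic_correlation(self):
        diffs = []
        for seed in range(4):
            cfg = single_year_config(n_lines=120, seed=seed, dth_effect=-60.0)
            m = simdata.simulate_markers(cfg)
            plots, truth = simdata.simulate_trial(m, cfg)
            g = truth.genetic_values
            with_cov = compute_blues(plots, dth_covariate=True).set_index("line")
            without = compute_blues(plots, dth_covariate=False).set_index("line")
            r_with = np.corrcoef(with_cov["estimate"], g.loc[with_cov.index])[0, 1]
            r_without = np.corrcoef(without["estimate"], g.loc[without.index])[0, 1]
            diffs.append(r_with - r_without)
        assert np.mean(diffs) > 0

    def test_across_env_scope_returns_line_rows(self, small_dataset):
        _, _, plots, _, _ = small_dataset
        out = compute_blues(plots, scope="across_env", dth_covariate=True)
        assert set(out.columns) >= {"line", "estimate", "se"}
        assert out["line"].is_unique


class TestHeritability:
    def test_closed_form(self):
        assert h2_from_components(2.0, 2.0, 2) == pytest.approx(66.666667,
                                                                abs=1e-4)
        assert h2_from_components(0.0, 2.0, 2) == 0.0
        with pytest.raises(ValueError):
            h2_from_components(0.0, 0.0, 2)

    def test_recovery_of_planted_h2(self):
        vals = []
        for seed in range(6):
            cfg = single_year_config(n_lines=250, seed=seed, h2_yield=0.55)
            m = simdata.simulate_markers(cfg)
            plots, _ = simdata.simulate_trial(m, cfg)
            vals.append(heritability(plots).iloc[0])
        assert abs(np.mean(vals) - 55.0) <= 5.0

    def test_band_copy_of_heritable_trait_matches(self):
        plots, _ = balanced_plots(n_geno=60, n_reps=2, seed=5)
        plots["b500"] = plots["GY"]
        _, h2 = mk.band_blues_and_h2(plots, bands=["b500"])
        direct = heritability(plots)
        assert h2.iloc[0, 0] == pytest.approx(direct.iloc[0], abs=1e-6)

    def test_pure_noise_band_near_zero(self):
        plots, _ = balanced_plots(n_geno=60, n_reps=2, seed=6)
        rng = np.random.default_rng(0)
        plots["b600"] = rng.normal(size=len(plots))
        _, h2 = mk.band_blues_and_h2(plots, bands=["b600"])
        assert h2.iloc[0, 0] < 15.0

    def test_constant_band_flagged_zero(self):
        plots, _ = balanced_plots(n_geno=30, n_reps=2, seed=7)
        plots["b700"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            _, h2 = mk.band_blues_and_h2(plots, bands=["b700"])
        assert h2.iloc[0, 0] == 0.0


class TestEquivariance:
    def test_shift_moves_blues_leaves_h2(self):
        plots, _ = balanced_plots(n_geno=40, n_reps=2, seed=8)
        shifted = plots.copy()
        shifted["GY"] = shifted["GY"] + 100.0
        b1 = compute_blues(plots, dth_covariate=False).set_index("line")
        b2 = compute_blues(shifted, dth_covariate=False).set_index("line")
        assert np.allclose(b2["estimate"], b1["estimate"] + 100.0, atol=1e-6)
        h1, h2_ = heritability(plots), heritability(shifted)
        assert h1.iloc[0] == pytest.approx(h2_.iloc[0], abs=1e-6)

    def test_scale_multiplies_components_leaves_h2(self):
        plots, _ = balanced_plots(n_geno=40, n_reps=2, seed=9)
        scaled = plots.copy()
        scaled["GY"] = scaled["GY"] * 3.0
        m = AdjustmentModel(genotype_fixed=False, random_terms=())
        f1 = fit_mixed_model(plots, m)
        f2 = fit_mixed_model(scaled, m)
        for term in ("genotype", "residual"):
            assert f2.variance_components[term] == pytest.approx(
                9.0 * f1.variance_components[term], rel=1e-4)
        assert heritability(plots).iloc[0] == pytest.approx(
            heritability(scaled).iloc[0], abs=1e-4)
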