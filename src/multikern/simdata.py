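"""Synthetic multi-year wheat trial generator with known ground truth.

The generator emulates an unbalanced three-year winter-wheat panel: partial
line overlap between years, an alpha-lattice-like layout with two replicates
per line, biallelic SNP dosages, per-plot hyperspectral reflectance (two
flights averaged, ~300 bands over 380-1020 nm with a heritability peak near
the red edge at 700 nm), and daily weather for a November 11 - May 11
growing window. Every latent quantity (breeding values, marker effects,
variance components, band loadings) is recorded so parameter-recovery tests
can compare estimates against truth.

Default sizes follow the study conditions this package targets: 330/262/139
lines across three years with 48/50/12 pairwise and 6 three-way shared
lines, two replicates, 300 bands. Marker count defaults to 2000, a
reduced-scale stand-in for a ~23k-SNP GBS panel. Yield is in kg/ha with a
grand mean of 2500, plot residual SD ~500, and variance components set so
within-year broad-sense heritability lands near 0.55-0.6.

Effect model for grain yield of line i in environment (year) j, replicate
k, block l:

    GY = mu + E_j + g_i + gE_ij + R_k(j) + B_l(k,j)
         + beta_DTH * (DTH_i - mean(DTH)) + e

with g = Xc beta (Xc centered dosages) scaled to the requested heritability
and gE built by re-drawing a fraction of marker effects per year (a
correlated-effects model, so the genomic reaction-norm kernel has genuine
signal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ioqc import MarkerMatrix, EC_VARIABLES

__all__ = ["SimConfig", "SimTruth", "simulate_markers", "simulate_trial",
           "simulate_bands", "simulate_ecs", "simulate_dataset",
           "write_exchange_files", "default_band_h2_profile"]


def default_band_h2_profile(wavelength_nm):
    """Target per-band heritability: baseline 0.15 with a peak ~0.6 at 700 nm."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return 0.15 + 0.45 * np.exp(-0.5 * ((lam - 700.0) / 60.0) ** 2)


def _default_ec_profiles() -> dict:
    """Per-year (mean, sd) for the six daily weather variables.

    Magnitudes follow a humid-subtropical winter-wheat season: daily mean
    temperature around 15 C with +/- year shifts, high relative humidity,
    episodic rainfall, and solar radiation rising toward spring.
    """
    base = {
        "t_avg_C": (15.0, 4.5), "t_min_C": (9.0, 4.5), "t_max_C": (22.0, 4.5),
        "rel_hum": (79.0, 6.0), "rain_cm": (0.25, 0.5), "solrad": (150.0, 35.0),
    }
    shifts = {"2021": 2.5, "2022": -0.8, "2023": -1.7}
    profiles = {}
    for year, dt in shifts.items():
        profiles[year] = {
            "t_avg_C": (base["t_avg_C"][0] + dt, base["t_avg_C"][1]),
            "t_min_C": (base["t_min_C"][0] + dt, base["t_min_C"][1]),
            "t_max_C": (base["t_max_C"][0] + dt, base["t_max_C"][1]),
            "rel_hum": (base["rel_hum"][0] - 2.0 * dt, base["rel_hum"][1]),
            "rain_cm": (max(base["rain_cm"][0] * (1 + 0.4 * dt), 0.02),
                        base["rain_cm"][1]),
            "solrad": (base["solrad"][0] + 8.0 * dt, base["solrad"][1]),
        }
    return profiles


@dataclass
class SimConfig:
    """All dials of the synthetic trial generator.

    Variances are on the kg^2/ha^2 scale of plot grain yield. ``h2_yield``
    is the target within-year broad-sense heritability on a line-mean basis
    with ``n_reps`` replicates; the genotypic variance is derived from it
    and ``var_resid``.
    """

    n_lines_per_year: dict = field(
        default_factory=lambda: {"2021": 330, "2022": 262, "2023": 139})
    n_overlap: dict = field(
        default_factory=lambda: {("2021", "2022"): 48, ("2022", "2023"): 50,
                                 ("2021", "2023"): 12, ("2021", "2022", "2023"): 6})
    n_markers: int = 2000
    maf_range: tuple = (0.05, 0.5)
    mu: float = 2500.0
    h2_yield: float = 0.55
    var_year: float = 70000.0
    var_gxe: float = 50000.0
    var_block: float = 20000.0
    var_rep: float = 10000.0
    var_resid: float = 250000.0
    n_reps: int = 2
    blocks_per_rep: int = 10
    gxe_redraw_fraction: float = 0.5
    gxe_ec_corr_length: float = 2.0  # deg C length-scale tying gE to EC similarity
    residual_het: float = 0.02
    n_families: int = 40
    family_relatedness: float = 0.7
    n_bands: int = 300
    band_range_nm: tuple = (380.0, 1020.0)
    band_h2_profile: object = None  # callable wavelength -> target H2; default peak at 700
    band_genetic_corr: float = 0.6
    band_flight_noise_sd: float = 0.02
    ec_profiles: dict = field(default_factory=_default_ec_profiles)
    dth_mean: float = 95.0
    dth_genetic_sd: float = 4.0
    dth_line_noise_sd: float = 2.0
    dth_plot_noise_sd: float = 1.0
    dth_effect: float = -20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_year", "var_gxe", "var_block", "var_rep", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.h2_yield < 1.0:
            raise ValueError("h2_yield must be in [0, 1)")
        if abs(self.band_genetic_corr) > 1.0:
            raise ValueError("band_genetic_corr must be in [-1, 1]")
        if self.band_h2_profile is None:
            self.band_h2_profile = default_band_h2_profile
        self._line_design()  # validates overlap feasibility

    # ------------------------------------------------------------------
    def _line_design(self) -> dict:
        """Assign line IDs to years honouring the pairwise/triple overlaps.

        Pairwise counts are read as inclusive of the all-years lines.
        """
        years = sorted(self.n_lines_per_year)
        if len(years) == 1:
            y = years[0]
            n = self.n_lines_per_year[y]
            return {y: [f"L{i + 1:04d}" for i in range(n)]}
        if len(years) != 3:
            raise ValueError("the overlap design expects 1 or 3 years")
        y1, y2, y3 = years
        ov = {tuple(sorted(k)): v for k, v in self.n_overlap.items()}
        n_all = ov.get((y1, y2, y3), 0)
        n12 = ov.get((y1, y2), 0) - n_all
        n23 = ov.get((y2, y3), 0) - n_all
        n13 = ov.get((y1, y3), 0) - n_all
        if min(n12, n23, n13) < 0:
            raise ValueError("pairwise overlaps smaller than the all-years count")
        u1 = self.n_lines_per_year[y1] - n12 - n13 - n_all
        u2 = self.n_lines_per_year[y2] - n12 - n23 - n_all
        u3 = self.n_lines_per_year[y3] - n23 - n13 - n_all
        if min(u1, u2, u3) < 0:
            raise ValueError("overlap design infeasible: per-year counts "
                             "smaller than implied overlaps")
        counter = [0]

        def take(n):
            ids = [f"L{counter[0] + i + 1:04d}" for i in range(n)]
            counter[0] += n
            return ids

        all3 = take(n_all)
        s12, s23, s13 = take(n12), take(n23), take(n13)
        q1, q2, q3 = take(u1), take(u2), take(u3)
        return {y1: all3 + s12 + s13 + q1,
                y2: all3 + s12 + s23 + q2,
                y3: all3 + s23 + s13 + q3}

    @property
    def lines_by_year(self) -> dict:
        return self._line_design()

    @property
    def all_lines(self) -> list:
        seen = {}
        for year in sorted(self.n_lines_per_year):
            for l in self._line_design()[year]:
                seen[l] = None
        return sorted(seen)

    @property
    def var_genetic(self) -> float:
        """Genotypic variance implied by h2_yield, var_resid and n_reps."""
        if self.h2_yield == 0.0:
            return 0.0
        return self.h2_yield / (1.0 - self.h2_yield) * self.var_resid / self.n_reps


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    true_breeding_values: pd.DataFrame  # line x year (g_i + gE_ij)
    true_variance_components: dict
    true_marker_effects: np.ndarray
    true_band_loadings: np.ndarray | None = None
    genetic_values: pd.Series | None = None  # main-effect g_i per line
    dth_values: pd.Series | None = None
    band_wavelengths: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "true_breeding_values": self.true_breeding_values.to_dict(),
            "true_variance_components": self.true_variance_components,
            "true_marker_effects": list(map(float, self.true_marker_effects)),
            "true_band_loadings": (None if self.true_band_loadings is None
                                   else list(map(float, self.true_band_loadings))),
            "genetic_values": (None if self.genetic_values is None
                               else self.genetic_values.to_dict()),
            "dth_values": (None if self.dth_values is None
                           else self.dth_values.to_dict()),
            "band_wavelengths": (None if self.band_wavelengths is None
                                 else list(map(float, self.band_wavelengths))),
        }
        s = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_markers(config: SimConfig, planted_missing: float = 0.0,
                     planted_low_maf: float = 0.0,
                     planted_high_het: float = 0.0) -> MarkerMatrix:
    """Draw biallelic dosages for an inbred panel: maf ~ U(maf_range) per marker.

    Lines are nearly fully homozygous (selfed wheat), with a small residual
    heterozygosity rate ``config.residual_het``; genotype probabilities are
    chosen so the expected dosage is exactly 2*maf, hence the realized
    allele frequencies follow the sampled maf distribution.

    The panel is structured into ``n_families`` founder families: each line
    copies its family founder's genotype at a fraction
    ``family_relatedness`` of markers (drawing the rest fresh from the
    population frequencies). This mimics a breeding panel of related lines
    and gives the genomic relationship matrix genuine off-diagonal
    structure — without it, across-year genomic prediction has no
    information to transfer. Set ``family_relatedness=0`` for an unrelated
    panel.

    The ``planted_*`` fractions replace that share of markers with QC
    violations (>80% missing, maf < 0.05, or >10% heterozygosity) for
    filter tests; they default to 0.
    """
    if config.n_markers < 2:
        raise ValueError("need at least 2 markers")
    lines = config.all_lines
    n = len(lines)
    if n < 2:
        raise ValueError("need at least 2 lines")
    rng = _rng(config, 1)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_markers)
    h = np.minimum(config.residual_het, 2 * maf)  # keep P(hom-alt) >= 0
    p0 = 1.0 - maf - h / 2.0
    p1 = h

    def draw_inbred(n_rows):
        u = rng.random(size=(n_rows, config.n_markers))
        return np.where(u < p0[None, :], 0.0,
                        np.where(u < (p0 + p1)[None, :], 1.0, 2.0))

    dosages = draw_inbred(n)
    if config.family_relatedness > 0 and config.n_families < n:
        founders = draw_inbred(config.n_families)
        fam = rng.integers(config.n_families, size=n)
        copy = rng.random(size=(n, config.n_markers)) < config.family_relatedness
        dosages = np.where(copy, founders[fam], dosages)

    n_bad = [int(round(f * config.n_markers))
             for f in (planted_missing, planted_low_maf, planted_high_het)]
    if sum(n_bad) > config.n_markers:
        raise ValueError("planted fractions exceed the marker count")
    if sum(n_bad):
        order = rng.permutation(config.n_markers)
        i = 0
        for j in range(n_bad[0]):  # >80% missing
            col = order[i]; i += 1
            mask = rng.random(n) < 0.9
            mask[rng.integers(n)] = True
            dosages[mask, col] = np.nan
        for j in range(n_bad[1]):  # maf below 0.05
            col = order[i]; i += 1
            p = rng.uniform(0.001, 0.04)
            dosages[:, col] = rng.binomial(2, p, size=n)
            if np.nanmean(dosages[:, col]) / 2 >= 0.05:  # resample until rare
                dosages[:, col] = 0.0
                dosages[rng.integers(n), col] = 1.0
        for j in range(n_bad[2]):  # heterozygosity above 10%
            col = order[i]; i += 1
            dosages[:, col] = rng.choice([0.0, 1.0, 2.0], size=n,
                                         p=[0.35, 0.3, 0.35])
    return MarkerMatrix(lines, [f"M{k + 1:05d}" for k in range(config.n_markers)],
                        dosages)


def _scale_to_var(x: np.ndarray, target: float) -> np.ndarray:
    """Center and rescale a vector so its population variance equals target."""
    x = x - x.mean()
    v = x.var()
    if target == 0.0 or v == 0.0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def simulate_trial(markers: MarkerMatrix, config: SimConfig
                   ) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the plot-level phenotype table and its ground truth.

    Returns a table with one row per plot (line, env, rep, block, DTH, GY)
    and a :class:`SimTruth` carrying breeding values, marker effects and the
    requested variance components.
    """
    design = config.lines_by_year
    missing = [l for yl in design.values() for l in yl
               if l not in set(markers.line_ids)]
    if missing:
        raise ValueError(f"markers do not cover design lines: {missing[:5]}")
    rng = _rng(config, 2)
    lines = markers.line_ids
    X = markers.dosages
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)
    Xc = X - X.mean(axis=0)

    var_g = config.var_genetic
    beta = rng.normal(size=markers.n_markers)
    g = _scale_to_var(Xc @ beta, var_g)
    g_ser = pd.Series(g, index=lines)

    years = sorted(design)
    year_eff = {y: e for y, e in zip(
        years, _scale_to_var(rng.normal(size=len(years)), config.var_year)
        if len(years) > 1 else np.zeros(len(years)))}

    # year-specific deviations of a fraction of marker effects (gE). The
    # deviation effects are correlated across years according to EC-profile
    # similarity (squared-exponential on the mean temperature shift), so
    # years with similar growing conditions share G-by-E patterns — the
    # structure the enviromic reaction-norm kernel is built to exploit.
    bv = {}
    if config.var_gxe > 0:
        C = np.eye(len(years))
        if config.gxe_ec_corr_length > 0:
            t_means = []
            for y in years:
                prof = config.ec_profiles.get(y)
                t_means.append(prof["t_avg_C"][0] if prof else np.nan)
            t_means = np.asarray(t_means, float)
            if np.all(np.isfinite(t_means)):
                d = t_means[:, None] - t_means[None, :]
                C = np.exp(-0.5 * (d / config.gxe_ec_corr_length) ** 2)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(len(years)))
        redraw = rng.random(markers.n_markers) < config.gxe_redraw_fraction
        gamma = L @ rng.normal(size=(len(years), markers.n_markers))
        for j, y in enumerate(years):
            dev = _scale_to_var(Xc @ (redraw * gamma[j]), config.var_gxe)
            bv[y] = g + dev
    else:
        for y in years:
            bv[y] = g + np.zeros(len(lines))
    bv_df = pd.DataFrame(bv, index=lines)

    # heritable line-level days-to-heading
    beta_d = rng.normal(size=markers.n_markers)
    dth_g = _scale_to_var(Xc @ beta_d, config.dth_genetic_sd ** 2)
    dth = (config.dth_mean + dth_g
           + rng.normal(0, config.dth_line_noise_sd, size=len(lines)))
    dth_ser = pd.Series(dth, index=lines)
    dth_center = float(dth_ser.mean())

    rows = []
    line_pos = {l: i for i, l in enumerate(lines)}
    for y in years:
        ylines = design[y]
        for k in range(1, config.n_reps + 1):
            rep_eff = rng.normal(0, np.sqrt(config.var_rep))
            order = rng.permutation(len(ylines))
            n_blocks = min(config.blocks_per_rep, len(ylines))
            block_eff = rng.normal(0, np.sqrt(config.var_block), size=n_blocks)
            for pos, li in enumerate(order):
                line = ylines[li]
                b = pos * n_blocks // len(ylines)
                i = line_pos[line]
                e = rng.normal(0, np.sqrt(config.var_resid))
                # yield responds to the plot's realized maturity, so the
                # DTH covariate slope is estimable within genotype
                dth_plot = dth_ser[line] + rng.normal(0, config.dth_plot_noise_sd)
                gy = (config.mu + year_eff[y] + bv[y][i] + rep_eff + block_eff[b]
                      + config.dth_effect * (dth_plot - dth_center) + e)
                rows.append((f"{y}_R{k}_P{pos + 1:03d}", line, y, k,
                             f"R{k}B{b + 1:02d}", dth_plot, gy))
    plots = pd.DataFrame(rows, columns=["plot_id", "line", "env", "rep",
                                        "block", "DTH", "GY"])
    truth = SimTruth(
        true_breeding_values=bv_df,
        true_variance_components={
            "genotype": var_g, "year": config.var_year, "gxe": config.var_gxe,
            "rep": config.var_rep, "block": config.var_block,
            "residual": config.var_resid,
            "dth_slope": config.dth_effect,
        },
        true_marker_effects=beta,
        genetic_values=g_ser,
        dth_values=dth_ser,
    )
    return plots, truth


def band_names(config: SimConfig) -> list:
    lam = np.linspace(*config.band_range_nm, config.n_bands)
    return [f"b{int(round(l))}" for l in lam]


def simulate_bands(trial: pd.DataFrame, truth: SimTruth, config: SimConfig
                   ) -> pd.DataFrame:
    """Append per-plot reflectance columns (two flights averaged) to the trial.

    Per band b with wavelength lambda_b the plot value is

        baseline(lambda_b) + l_b * z_ij + noise,
        z_ij = rho * bv_std_ij + sqrt(1-rho^2) * q_bi

    where bv_std is the line's standardized year-specific genetic value
    (main effect plus that year's G-by-E deviation — canopy reflectance
    tracks realized performance in the season it is imaged, which is why
    validation-year imagery is informative), q_b an independent heritable
    line effect, and the loading l_b is set so the realized broad-sense
    heritability of the delivered (flight-averaged) values matches the
    configured profile. Reflectances are clipped to [0, 1].
    """
    rho = config.band_genetic_corr
    if abs(rho) > 1.0:
        raise ValueError("band_genetic_corr must be in [-1, 1]")
    rng = _rng(config, 3)
    lam = np.linspace(*config.band_range_nm, config.n_bands)
    names = band_names(config)

    lines = list(truth.genetic_values.index)
    # standardized year-specific genetic values (per environment)
    bv = truth.true_breeding_values
    bv_std = {}
    for env in bv.columns:
        col = bv[env].to_numpy()
        sd = col.std()
        bv_std[env] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    # smooth vegetation-like baseline: green bump + red-edge step
    baseline = (0.05 + 0.04 * np.exp(-0.5 * ((lam - 550) / 30.0) ** 2)
                + 0.40 / (1.0 + np.exp(-(lam - 715) / 12.0)))

    h2_target = np.clip(np.asarray(config.band_h2_profile(lam), float), 0.0, 0.999)
    sig_f = config.band_flight_noise_sd
    resid_var = sig_f ** 2 / 2.0  # two flights averaged
    load = np.sqrt(h2_target / (1.0 - h2_target) * resid_var / config.n_reps)

    q = rng.normal(size=(len(lines), config.n_bands))
    line_pos = {l: i for i, l in enumerate(lines)}
    rows = np.array([line_pos[l] for l in trial["line"]])
    g_plot = np.array([bv_std[e][i] for e, i in zip(trial["env"], rows)])
    z = (rho * g_plot[:, None]
         + np.sqrt(max(0.0, 1.0 - rho ** 2)) * q[rows, :])

    genetic = load[None, :] * z
    f1 = baseline[None, :] + genetic + rng.normal(0, sig_f, size=genetic.shape)
    f2 = baseline[None, :] + genetic + rng.normal(0, sig_f, size=genetic.shape)
    refl = np.clip(0.5 * (f1 + f2), 0.0, 1.0)

    out = trial.copy()
    out[names] = refl
    truth.true_band_loadings = load
    truth.band_wavelengths = lam
    return out


def simulate_ecs(config: SimConfig) -> pd.DataFrame:
    """Daily weather for each year's Nov 11 - May 11 growing window.

    Guarantees t_min <= t_avg <= t_max on every row and nonnegative
    rainfall; per-year mean shifts follow ``ec_profiles`` so environments
    are distinguishable.
    """
    import zlib

    frames = []
    for year in sorted(config.ec_profiles):
        prof = config.ec_profiles[year]
        # stream keyed by the profile content: years with identical profiles
        # (and the same seed) get identical daily series
        sig = zlib.crc32(repr(sorted(prof.items())).encode())
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4, sig]))
        end = pd.Timestamp(int(year), 5, 11)
        start = pd.Timestamp(int(year) - 1, 11, 11)
        dates = pd.date_range(start, end, freq="D")
        n = len(dates)
        doy = np.arange(n)
        # coldest near mid-window, warming toward May
        season = -np.cos(2 * np.pi * (doy - n / 2) / 365.0)
        mean_t, sd_t = prof["t_avg_C"]
        t_avg = mean_t + 6.0 * season + rng.normal(0, sd_t * 0.5, n)
        lo_gap = max(prof["t_avg_C"][0] - prof["t_min_C"][0], 0.5)
        hi_gap = max(prof["t_max_C"][0] - prof["t_avg_C"][0], 0.5)
        t_min = t_avg - np.abs(rng.normal(lo_gap, 1.5, n))
        t_max = t_avg + np.abs(rng.normal(hi_gap, 1.5, n))
        mean_h, sd_h = prof["rel_hum"]
        rel_hum = np.clip(rng.normal(mean_h, sd_h, n), 20.0, 100.0)
        mean_r, _ = prof["rain_cm"]
        wet = rng.random(n) < 0.35
        rain = np.where(wet, rng.exponential(mean_r / 0.35, n), 0.0)
        mean_s, sd_s = prof["solrad"]
        solrad = np.clip(mean_s + 60.0 * season + rng.normal(0, sd_s, n), 5.0, None)
        frames.append(pd.DataFrame({
            "env": year, "date": dates, "t_avg_C": t_avg, "t_min_C": t_min,
            "t_max_C": t_max, "rel_hum": rel_hum, "rain_cm": rain,
            "solrad": solrad,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: markers, plot table with bands, weather, truth."""
    markers = simulate_markers(config)
    plots, truth = simulate_trial(markers, config)
    plots = simulate_bands(plots, truth, config)
    weather = simulate_ecs(config)
    return markers, plots, weather, truth


def write_exchange_files(outdir, markers: MarkerMatrix, plots: pd.DataFrame,
                         weather: pd.DataFrame, truth: SimTruth,
                         config: SimConfig) -> dict:
    """Write the standard exchange files (TSV/CSV/JSON) consumed downstream."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "plots": os.path.join(outdir, "plots.csv"),
        "bands": os.path.join(outdir, "bands.csv"),
        "weather": os.path.join(outdir, "weather.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    markers.to_dataframe().to_csv(paths["genotypes"], sep="\t")
    names = [c for c in plots.columns if c.startswith("b") and c[1:].isdigit()]
    plots.drop(columns=names).to_csv(paths["plots"], index=False)
    plots[["plot_id"] + names].to_csv(paths["bands"], index=False)
    weather.to_csv(paths["weather"], index=False)
    truth.to_json(paths["truth"])
    return paths
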