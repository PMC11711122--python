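# Methods

## Two-stage analysis

The pipeline follows the two-stage convention of multi-environment trial
analysis. Stage 1 fits, per environment (year), the plot model

    Y_ijkl = mu + g_i + R_k + B_l(k) + beta_DTH * (DTH - mean) + e_ijkl

with genotype fixed and replicate/block random to produce best linear
unbiased estimates (BLUEs) of each line's yield, and the all-random
version of the same model to estimate variance components for broad-sense
heritability, H2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r) * 100 with r
the replicate count (design value 2; configurable). Days to heading
enters as a centered fixed covariate so maturity differences do not
masquerade as yield potential. An across-environment variant adds a fixed
year effect and a random genotype-by-year term. Stage 2 treats the BLUEs
(line-by-environment observations for the multi-year models) as the
response of a multi-kernel random-effect regression.

Two-stage analysis loses a little information relative to a single joint
fit but keeps each stage cheap, lets the hyperspectral bands be adjusted
once and reused across models, and makes the model comparison orthogonal
to the plot-level adjustment.

## EM-REML

Variance components are estimated by EM on Henderson's mixed-model
equations. Each iteration solves the MME at the current components,
updates sigma_k^2 <- (u_k'u_k + sigma_e^2 tr(C^kk)) / q_k and sigma_e^2
from the residual sum of squares, and evaluates the REML criterion from
the same Cholesky factor. Plain EM is monotone but linearly (sometimes
sublinearly) convergent, so three safeguards are layered on top, each
triggered only by the trajectory itself:

* **Guarded Aitken acceleration** every fourth sweep: per-component
  geometric extrapolation, accepted only if it increases the REML
  criterion (one extra Cholesky to check).
* **Boundary pinning**: a component that has shrunk monotonically for 30
  sweeps below 5% of the response variance is tested explicitly against
  the boundary — it is pinned at the floor (1e-8 x var(y)) iff the REML
  criterion does not drop. Pinned components are reported as 0 with a
  boundary flag.
* **Plateau stops**: convergence is declared on relative parameter change
  < 1e-8, or on a sustained likelihood plateau (10 consecutive sweeps
  below 1e-9 relative change, or < 2e-7 relative gain over 40 sweeps).
  The windowed form matters for designs with collinear random terms
  (e.g., one block per replicate makes replicate and block variance
  jointly unidentifiable: the likelihood is flat along their sum) and for
  near-zero components where the criterion surface is extremely flat.

On balanced complete designs the estimates agree with closed-form
expected-mean-squares ANOVA to < 1e-6 relative error (tested), and BLUEs
equal raw genotype means. The per-band loop reuses the design
cross-products (X'X, X'Z, Z'Z) across all bands within an environment,
which is what makes ~300-band heritability scans affordable.

## Kernels

All three relationship matrices use one recipe: column-standardize
(population SD; zero-variance columns dropped with a warning), then
MM'/p. The population-SD convention puts the mean diagonal of G at 1 in
expectation; a sample-SD convention would rescale the kernel by a
constant that the variance component absorbs, so nothing downstream
depends on the choice. The hyperspectral kernel P is built from
standardized per-band BLUEs at line-by-environment resolution (within-year
models use that year's line-level BLUEs); the enviromic kernel K from
standardized 10-day-interval weather features per environment.

Interactions follow the reaction-norm construction: expand group-level
kernels to observations with 0/1 incidence matrices (Z K Z') and take the
element-wise (Hadamard) product of conformable expanded matrices — gE =
ZGZ' o ZEZE', and analogously HE, gw (genomic-by-enviromic), Hw. The
Schur product theorem keeps every interaction PSD; a single 1e-8 diagonal
jitter is added when needed (the EC kernel over 3 environments is
necessarily low-rank). The marker-by-covariate interaction gw is built
from the genomic kernel; a `literal_gw_uses_H` switch builds it from the
hyperspectral kernel instead for users who want that variant.

Model term lists: M1={g}, M2={H}, M3={g,H}, M4={E,g,gE}, M5={E,H,HE},
M6={E,g,H,HE,gE}, M7={E,g,w,gw,gE}, M8={E,H,w,HE,Hw},
M9={E,g,w,H,HE,Hw,gE,gw}. The environment main effect is a random effect
with block kernel ZE ZE', which keeps the sampler uniform across terms.

## Gibbs sampler

Each kernel is eigendecomposed once (eigenvalues > 1e-8 kept); writing
u_k = V_k delta_k with delta_kj ~ N(0, sigma_k^2 lambda_kj) makes the
full-conditional of each term's coefficients independent Gaussians, so a
sweep costs two matrix-vector products per term. Variance components get
scaled-inverse-chi-square priors, df0 = 5, with scales set so each term's
prior mode is prior_R2/n_terms of the phenotypic variance (on the
kernel's mean-diagonal scale) and the residual mode is (1-prior_R2) x
var(y); prior_R2 defaults to 0.5. Missing responses are imputed from the
posterior predictive each sweep (data augmentation), which is how masked
cross-validation folds and forward-prediction years are handled — the
masked input values are never read, a property the leakage tests assert
byte-for-byte. Defaults: 12,000 sweeps, 2,000 burn-in, thinning 5; the
validation experiments use shorter chains and check effective sample
sizes instead of fixed lengths. A closed-form BLUP solver
(`gblup_oracle`) provides the exact solution at fixed variance
components; the sampler's posterior-mean effects match it with
correlation > 0.999 (tested on random instances).

With n = 0 observed responses the prior scales are undefined (they are
set from the observed phenotypic variance), so the sampler requires at
least 10 observed values rather than supporting prior-only runs.

## Synthetic trial generator

The generator emulates a three-year unbalanced winter-wheat panel:
330/262/139 lines by default with 48/50/12 pairwise and 6 three-way
shared lines, two replicates in incomplete blocks (default 10 per
replicate, random allocation — exact alpha-design construction is out of
scope), ~2,000 SNPs (a reduced-scale stand-in for a ~23k GBS panel), 300
bands over 380–1020 nm, and daily weather from November 11 to May 11.

Yield-scale defaults were set once from the kind of descriptive
statistics such trials report: grand mean 2500 kg/ha, plot residual SD
500, year variance 70,000, G-by-E variance 50,000, block 20,000,
replicate 10,000 (kg^2/ha^2), and an `h2_yield` dial (default 0.55) from
which the genetic main-effect variance is derived. Realized within-year
H2 sits somewhat above the dial because the year-specific G-by-E and
heritable-maturity channels also contribute line-level variance.

Design choices that matter:

* **Genotypes are inbred-line dosages**, nearly homozygous with a 2%
  residual heterozygosity rate, with genotype probabilities chosen so the
  expected dosage is exactly 2 x MAF. A Hardy–Weinberg draw would carry
  up to 50% heterozygosity and be annihilated by the het > 10% QC rule.
* **Founder families** (default 40 families, 70% founder-copy rate) give
  the genomic kernel genuine off-diagonal structure. Without relatedness,
  across-year genomic prediction has no channel: a panel of unrelated
  lines transfers nothing to a new year beyond the few repeated entries.
* **Marker effects are i.i.d. normal** (infinitesimal model), matching
  the GBLUP equivalence the kernel regression assumes. G-by-E deviations
  re-draw a fraction (default 50%) of marker effects per year, with the
  year-specific deviation effects **correlated across years according to
  EC-profile similarity** (squared-exponential kernel on the mean
  temperature shift, length-scale 2 degrees C). Years with similar growing
  conditions therefore share G-by-E patterns — precisely the structure
  the enviromic reaction-norm terms (gw, Hw) exist to exploit; without
  it those terms have nothing real to detect.
* **Band reflectance** is baseline(lambda) + loading x genetic signal +
  flight noise, two flights averaged, clipped to [0,1]. The per-band
  loading is solved from a target heritability profile (default: 0.15
  baseline with a 0.6 peak at 700 nm, the red edge). The genetic signal
  tracks the line's **year-specific** genetic value (main effect plus
  that year's G-by-E deviation) with correlation `band_genetic_corr`
  (default 0.6), plus an independent heritable component: canopy
  reflectance images realized in-season performance, which is why
  validation-year imagery is informative for forward prediction.
* **DTH** is a heritable line trait whose plot-level measurement enters
  yield linearly (default -20 kg/ha per day), so the covariate adjustment
  has a real confounder to remove and its slope is estimable within
  genotype.
* **Weather** is generated per year from mean/SD profiles with a seasonal
  cycle, ordered so t_min <= t_avg <= t_max holds row-wise and rainfall
  is nonnegative; the stream is keyed to the profile content, so two
  years with identical profiles receive identical daily series.

What the generator does not emulate: spatial field trend, radiometric
artifacts, linkage disequilibrium decay, pedigree depth beyond one
founder generation, EC-yield mechanisms beyond the correlation structure
above. Passing tests therefore show the *machinery* is correct and that
the models detect the planted structure; they do not certify accuracy
levels on real field data.

## Quality control and aggregation conventions

Markers are removed if missingness > 80%, minor-allele frequency < 0.05
(computed after folding to the minor allele), or heterozygosity > 10%
(fraction of dosage-1 calls among observed); boundary values survive, and
the three criteria apply jointly so filtering is order-independent.
Missing dosages are filled with the per-marker mean of observed calls —
continuous values, preserving allele frequency, which is the only
property the cross-product kernel uses. The 182-day EC window yields 18
complete 10-day intervals plus a 2-day remainder kept as its own short
interval by default (configurable to drop); rainfall is averaged like
every other variable (a per-interval sum is available via option).

## Evaluation

CV2 is 10-fold cross-validation over lines within a year (each fold
tested once); the cluster-aware variant builds folds as unions of whole
genomic clusters (PCA of dosages, top 10 components, k-means) so related
lines never straddle train and test. Forward prediction masks only the
target year's yields; its hyperspectral and EC features remain available.
Accuracy is Pearson's rho per environment on line-level BLUEs; across
environments the inverse-variance weighted mean uses V(r) =
(1-r^2)/(n-2), with |r| = 1 returned directly (infinite weight).
Fold-score variability uses the corrected SE sqrt(s^2 (1/k +
n_test/n_train)), which accounts for overlapping training sets. The
coincide index takes the top ceil(0.25 n) by predicted and by observed
value (ties broken by value then label) and reports the overlap as a
percentage of the observed-set size; under independence it calibrates to
~25%.

## Machine-learning arm

Feature blocks (imputed dosages, band BLUEs, environment-broadcast EC
features) are concatenated and standardized per block *inside* the
estimator pipeline, so scalers only ever see training rows. Grid search
is exhaustive with 5-fold inner CV selecting the maximum mean Pearson
correlation (negative MSE available). Default grids: SVM-RBF C in
{0.1,1,10,100}, gamma in {0.001,0.01,0.1,1}; random forest 100/500/1000
trees with max_features in {all, sqrt, log2}; gradient boosting learning
rate {0.01,0.1,0.2} x depth {3,5,7} x {50,100,200} estimators; the dense
network explores 1–3 hidden layers of 32/64/128 ReLU (or sigmoid) units,
Adam or SGD, learning rate {0.001,0.01,0.1}, early stopping on a 10%
validation split (patience 20 epochs, max 500), linear output, MSE loss.

## Problem sizes in the validation experiments

The standard experiments run three years of 150/130/110 lines (overlaps
30/28/10/6), 600–800 markers in 20–25 families, and 12 bands; the
heritability-recovery study uses 300 lines x 1000 markers; chains of
1,500–6,000 sweeps are paired with effective-sample-size diagnostics.
These sizes preserve the unbalanced structure and the signal-to-noise
regime of the full defaults while keeping each experiment to minutes on
one CPU. Heritability recovery uses the family-structured panel because
variance-ratio identification needs eigenvalue spread in G: with
thousands of independent markers and no relatedness, G approaches the
identity and the genomic share of variance is barely identifiable for
any method.

## Known limitations

* EM-REML handles the few-component models used here; it is not a
  general-purpose REML engine (no correlated random effects, no AR1/spatial
  structures, single response).
* The EC kernel over three environments is rank-2 after centering, and
  centered features force at least one negative cross-year similarity;
  with so few environments the enviromic terms carry limited, sometimes
  sign-ambiguous information. This is a small-sample property of the
  construction, not an implementation artifact.
* Forward prediction reports single-split results by design; the
  experiments replicate over simulation seeds instead of split
  randomness.
* The sampler's equal prior split across terms shrinks variance ratios
  toward the prior when identification is weak (visible as a mild bias
  toward 0.5 in the recovery study at planted ratios 0.2 and 0.8).
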