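# multikern

Multi-kernel genomic, hyperspectral and enviromic prediction of grain
yield in unbalanced multi-year wheat trials.

Breeding programs routinely phenotype heat-stressed winter wheat with
UAV-mounted hyperspectral cameras alongside genotyping-by-sequencing and
public weather records. The statistical question is whether stacking those
data layers — SNP markers (G), canopy reflectance over ~300 wavebands (H),
and environmental covariates summarized over the growing season (w) —
improves yield prediction within a season and, more importantly, *forward*
into an untested year. `multikern` implements that entire analysis as a
tested Python library, together with a synthetic multi-year trial
generator with known ground truth so every stage can be validated by
parameter recovery.

## The model

Stage 1 adjusts plot yields with the mixed model

    Y_ijkl = mu + g_i + E_j + gE_ij + R_k + B_l(k,j) + beta*DTH + e_ijkl

(genotype fixed for BLUEs, blocking random, days-to-heading as a centered
covariate; all terms random for heritability, H2 = sG2/(sG2+se2/r)).
Stage 2 regresses the BLUEs on variance-component terms whose covariances
are relationship kernels:

    y = 1*mu + sum_k u_k + eps,      u_k ~ N(0, sigma_k^2 * K_k)

with `G = XX'/p` from standardized SNP dosages, `P = SS'/m` from
standardized band BLUEs, `K = WW'/q` from 10-day-interval weather
features, incidence expansion `ZKZ'` onto line-by-environment
observations, and reaction-norm interactions (gE, HE, gw, Hw) as Hadamard
products of expanded kernels. Nine nested models M1–M9 (from genomic-only
`y = mu + g + eps` up to the comprehensive
`y = mu + E + g + w + H + HE + Hw + gE + gw + eps`) are fitted by a Gibbs
sampler in the eigenspace of each kernel, with scaled-inverse-chi-square
priors and data augmentation for masked responses — so cross-validation
and forward prediction are a matter of masking the target yields.

A machine-learning arm (random forest, gradient boosting, RBF-SVM, dense
neural network; exhaustive grid search with inner CV) runs on the
concatenated feature blocks, and the evaluation module provides 10-fold
CV2, cluster-aware splitting, forward prediction plans, the
inverse-variance weighted correlation r_phi with V(r) = (1-r^2)/(n-2),
the Bouckaert–Frank corrected SE, and the coincide index (overlap of
predicted and observed top-25% lines).

## Worked example

`examples/` contains one narrative script per capability. Forward
prediction (`python examples/05_forward_prediction.py`) trains on two
simulated years and predicts the third:

```
model  rho[2023]  rho_weighted  coincide_index
   M1       0.51          0.51          53.571
   M5       0.35          0.35          50.000
   M9       0.50          0.50          53.571

rho[2023]: correlation of predicted vs observed 2023 yield BLUEs;
coincide_index: % overlap of predicted and observed top-25% lines.
```

`rho[2023]` is the Pearson correlation between predicted and observed
yield BLUEs in the masked year; a coincide index of ~54% means the model
recovers about half of the truly top-yielding quartile (chance level is
25%). Averaged over many simulated trials the comprehensive M9 is the
most accurate forward predictor, with the phenomic-only M5 and
genomic-only M1 trailing — single trials, as above, are noisier.

## Layout

```
src/multikern/
  simdata.py      synthetic trial generator (markers, plots, bands, weather)
  ioqc.py         VCF/TSV genotype I/O, marker QC, imputation, EC aggregation
  pheno_adjust.py EM-REML mixed models: BLUEs, heritability, per-band curves
  kernels.py      G/P/K kernels, incidence expansion, interactions, M1-M9
  bayes.py        multi-kernel RKHS Gibbs sampler + closed-form BLUP oracle
  ml.py           grid-tuned RFR/GBR/SVM/ANN on concatenated feature blocks
  evaluation.py   CV2/forward plans, rho, r_phi, corrected SE, coincide index
  pipeline.py     raw tables -> BLUEs, kernels, feature blocks
  experiments.py  standard validation experiments (used by the tests)
```
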