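# mtgp — Bayesian multi-trait, multi-environment genomic prediction

`mtgp` implements the Bayesian multi-trait (BME) and multi-trait
multi-environment (BMTME) genomic-prediction models used in plant breeding,
together with Bayesian multi-output regressor stacking (BMORS), the
cross-validation designs breeders use to evaluate them, and the
Pearson/MAAPE accuracy summaries. It is aimed at quantitative geneticists
who want to estimate genetic (co)variances between traits and environments
and predict unphenotyped line-by-environment cells from genome-wide markers.

## The models

For J lines phenotyped for L traits in I environments (n = records), the
core model is

```
Y = X β + Z1 b1 + Z2 b2 + E
```

* `Y` (n×L) trait records; `X` (n×I) environment incidence; `β` (I×L)
  environment-by-trait means.
* `b1 ~ MN(0, G, Σt)` — line effects with the genomic relationship matrix
  `G = W W' / p` as row covariance and an unstructured trait genetic
  covariance `Σt` (L×L) as column covariance.
* `b2 ~ MN(0, ΣE ⊗ G, Σt)` — line-by-environment effects, with an
  unstructured environment covariance `ΣE` (I×I).
* `E ~ MN(0, Iₙ, Re)` — residuals with unstructured trait covariance `Re`.

The random effects are whitened through the Cholesky factor of `G`
(`Z1 = ZG·L`, `Z2 = ZEG·chol(I⊗G)`), so the sampler works with
identity-row-covariance effects. Fitting is blocked Gibbs sampling:
matrix-normal full conditionals for `β`, `b1`, `b2` (effects sampled in row
blocks, decoupled through the eigenbasis of each block's cross-product) and
inverse-Wishart full conditionals for `Σt`, `ΣE`, `Re`. Cells named in a
testing set are masked before fitting and predicted by data augmentation.
BME is the same model without the `Z2 b2` term (single or pooled
environment); BMORS is a cheap two-stage alternative that fits univariate
GBLUP per trait (stage 1) and then regresses each trait on the standardized
stage-1 predictions of all traits (stage 2),

```
y_l = β1 Ẑ1 + β2 Ẑ2 + … + βL ẐL + e,   Ẑ_l = (ŷ_l − μ_l) / σ_l .
```

Prediction accuracy is summarized per (environment, trait) as the mean over
cross-validation partitions of Pearson's correlation and the mean arctangent
absolute percentage error, MAAPE = mean arctan|(y − ŷ)/y| ∈ [0, π/2].

## Worked example

Simulate a maize-style toy dataset (30 lines × 3 traits × 3 environments,
family-structured markers) and evaluate the BMTME model under five-fold
cross-validation:

```bash
mtgp simulate --preset maize_like --seed 7 --out data
mtgp fit-bmtme --pheno data/pheno.csv --grm data/grm.csv \
     --niter 1250 --burnin 500 --thin 2 --bs 50 \
     --cv kfold:5 --seed 123 --out fit
```

`fit/summary.csv` then contains one row per environment-trait combination
(these exact numbers reproduce with the seeds above):

```
Environment Trait  Pearson  SE_Pearson  MAAPE  SE_MAAPE
        EBU   ASI   0.8308      0.0762 0.5175    0.1136
        EBU    PH   0.7323      0.0741 0.0064    0.0006
        EBU Yield   0.6351      0.1259 0.1792    0.0183
        KAK   ASI   0.6020      0.1302 0.4957    0.0400
        KAK    PH   0.7705      0.0822 0.0043    0.0006
        KAK Yield   0.4682      0.1475 0.1918    0.0380
        KTI   ASI   0.6535      0.1432 0.5209    0.0762
        KTI    PH   0.8090      0.0742 0.0052    0.0006
        KTI Yield   0.7661      0.1317 0.1932    0.0410
```

`Pearson` is the correlation between observed and predicted values on the
masked testing cells, averaged over the five folds (higher is better);
`MAAPE` is the bounded relative error (lower is better — PH looks tiny
because plant-height values are large, so relative errors are small);
the `SE_*` columns are standard errors across folds and become `NaN` when a
single testing set is used. `fit/metrics_complete.csv` holds the
per-partition values, and a parameter-estimation run (no `--cv`) writes
`yHat.csv`, `varTrait.csv`, `varEnv.csv` and `vare.csv` — the posterior
means of the fitted values and of `Σt`, `ΣE`, `Re`. Convert a covariance to
correlations with `mtgp.cov_to_correlation`.

The same workflow is available from Python (`mtgp.fit_bmtme`,
`mtgp.cross_validate_bmtme`, `mtgp.fit_bmors`, ...); see the docstrings and
`docs/methods.md`.

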