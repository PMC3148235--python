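# pbsig — dose-specific blood gene-expression signatures of lead exposure

`pbsig` re-implements, as a reusable and fully testable pipeline, the
analysis behind blood-based transcriptomic biomarkers of lead (Pb)
exposure in the mouse: two weeks of lead acetate in drinking water at a
low or high dose, a peripheral-blood bleed at the end of exposure and a
second after two weeks of recovery, and a supervised-classification
analysis that asks four questions:

1. **Can blood expression classify exposure?** For each dose, the 250
   probes most correlated with exposure form a *signature*; a metagene
   probit model turns them into a per-animal probability of exposure,
   validated by leave-one-out cross-validation (LOOCV) and summarized by
   ROC curves (AUC, sensitivity, specificity).
2. **Is the signature dose-specific?** A model frozen at one dose is used
   to score the other dose's cohort (cross-prediction).
3. **Does the signature persist after exposure ends?** Control-subtracted
   signature expression is compared between the exposure and recovery
   bleeds.
4. **What biology do the signatures carry?** Signatures are split into
   up/down components, overlapped between doses (including the
   discordant probes: up at the low dose, down at the high dose), scored
   against in-vitro pathway-perturbation signatures projected across
   platforms, and annotated by hypergeometric gene-set overlap against
   GMT collections.

Because the original arrays are an external download, the package ships a
synthetic-data generator that emulates the study design — 3 groups
(control n = 14, low n = 15, high n = 15), bleeds of 7 + 15 + 15 animals
at exposure and 7 + 15 + 13 at recovery (72 samples), dose-specific
planted probe blocks with a controlled 28-probe overlap, and full
reversion of effects at recovery — so every stage runs and is tested
without any network access.

## The model

For a probes-by-samples log2 expression matrix (RMA-style values) with a
binary label *y* (0 = control, 1 = exposed):

1. **Selection.** Rank probes by |Pearson r| between expression and *y*;
   keep the top *k* (default 250). Sign of *r* defines up/down.
2. **Metagenes.** Center each selected probe by its training mean and
   take the thin SVD of the k × n submatrix, X = U D Vᵀ. The top *m*
   right singular vectors (default m = 2) give each sample a score
   vector v ("metagenes").
3. **Probit regression.** P(y = 1 | v) = Φ(β₀ + βᵀv), fitted either by
   deterministic Newton maximization of the ridge-penalized
   log-likelihood (λ‖β‖², λ = 0.5, intercept unpenalized — finite even
   under perfect separation) or by Albert–Chib Gibbs sampling with
   N(0, 100) priors (2000 draws after 500 burn-in).
4. **Prediction.** A new sample x* is centered with the stored training
   means, projected v* = x*ᵀU_m D_m⁻¹, and scored Φ(β₀ + βᵀv*).

LOOCV repeats *all* of steps 1–3 inside every fold (honest
cross-validation; a `fixed_signature` flag reproduces the optimistic
variant that selects probes once). AUC is the Mann–Whitney concordance
with Hanley–McNeil standard error; group comparisons of pathway scores
use one-way ANOVA with Bonferroni-adjusted pairwise t tests on the pooled
within-group variance; gene-set overlap uses the upper-tail
hypergeometric test P(X ≥ o).

## Worked example

```bash
for step in analysis/0*.py; do python "$step"; done
```

runs the whole story on the simulated study and prints, among others:

```
low: 22 samples, LOOCV AUC 1.000, sensitivity 1.00, specificity 1.00
high: 22 samples, LOOCV AUC 1.000, sensitivity 1.00, specificity 1.00
high_model_on_independent_low_cohorts_mean: AUC 0.422
low: mean |d| exposure 3.042 log2 units, recovery 0.360 (ratio 0.118)
high signature: 91 up, 159 down
shared: 28 total (10 up in both, 7 down in both, 11 discordant)
one-way ANOVA: F = 936.779, p = 1.849e-30
```

Reading: with the planted effect of 3 noise-SD the 22-animal LOOCV
separates perfectly (AUC 1.0); a frozen high-dose model scores
independent low-dose cohorts at chance (dose specificity); recovery-bleed
signature expression collapses to ~12% of its exposure-bleed displacement
(no persistence); the rebuilt signatures recover the planted composition
— 91 up/159 down at the high dose and a 28-probe overlap splitting
10 up / 7 down / 11 discordant; and a pathway planted only in high-dose
animals raises their mean predicted activation (0.63 vs 0.41 in controls)
with a Bonferroni-significant high-vs-control contrast.

The same stages are available as subcommands of the `pbsig` CLI
(`simulate`, `build`, `loocv`, `crosspredict`, `recovery`, `compare`,
`pathways`, `enrich`, `all`) operating on GCT/CLS/GMT/TSV files.

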