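# Methods notes

This note documents the models, defaults and numerical choices behind
`metabomwas`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## 1. Preprocessing

Stage order is fixed: missingness filter → PQN → log2 → kNN imputation →
LOF sample removal → extreme-value masking → second kNN round.

- **Missingness filter.** Metabolites with *strictly more than*
  `max_missing_frac` (default 0.25) missing values are dropped; a
  metabolite at exactly 25% is retained. Samples are never dropped here.
- **PQN.** The reference spectrum is the metabolite-wise median across all
  samples (the reference choice is a free parameter of PQN; the median
  reference is standard and robust to the case/control imbalance of a
  disease cohort). Each sample's quotient is the median over metabolites of
  sample/reference, ignoring missing cells; with ≥ 500 metabolites the
  quotient tracks a planted dilution factor at Spearman ρ > 0.95.
- **kNN imputation** (scikit-learn `KNNImputer`): Euclidean distance over
  mutually observed metabolites rescaled by the number of shared features,
  unweighted mean of the k = 10 nearest samples. k = 10 is a common
  metabolomics default; the result is insensitive to k in the 5–20 range on
  smooth data. Observed cells are never altered.
- **LOF.** Default 20 neighbours, flag threshold 1.5 on the reachability-
  density ratio. Both values are conventional; the number of samples
  flagged is data-specific. LOF runs on the imputed (complete) matrix —
  running it on partially observed data would make the distance metric
  depend on the missingness pattern.
- **Extreme values.** Per metabolite, values are centred/scaled
  (mean 0, SD 1 — per metabolite, not per matrix) and cells with
  `|z| > |Φ⁻¹(α/n)|` are masked (α = 0.0125, n = number of samples; for
  n = 547 the cutoff is ≈ 4.08 SD). This is a two-tailed 2α band with a
  Bonferroni-style division by n, so on genuinely normal data each cell is
  flagged with probability 2α/n and each metabolite contributes ≈ 0.025
  expected flags regardless of n. Zero-variance metabolites are skipped
  with a warning instead of erroring (they arise in degenerate synthetic
  configurations). The new holes are re-imputed by a second kNN round.

## 2. Site correction

Parametric empirical-Bayes location/scale adjustment (ComBat) with a
protected covariate design (sex, age at death, PMI, APOE4 count,
ethnoracial group; categoricals dummy-coded against the lexicographically
first level for determinism). Implementation choices:

- Pooled variances use 1/n, and the per-batch scale estimates use ddof = 0,
  keeping the two consistent: a single-batch "correction" is then exactly
  the identity, and no-shrink correction removes per-batch residual means
  exactly (both asserted at 1e-6 in the tests).
- EB priors: normal on batch locations, inverse-gamma on squared scales,
  hyperparameters moment-matched across metabolites; posterior updates
  iterated to relative tolerance 1e-4 (cap 100 iterations). If the prior
  moments degenerate (zero spread across metabolites) the unshrunk
  estimates are used.
- A **no-shrink mode** performs plain per-batch standardization of the
  covariate-adjusted residual. It is the brute-force oracle for the EB
  path and is exposed on the CLI (`correct --no-shrink`).
- **Idempotence** is exact (1e-6 RMS) without protected covariates. With
  covariates it cannot be exact for any location/scale method: rescaling
  residuals per batch breaks their orthogonality to the covariate columns,
  so a second pass re-estimates small batch terms (observed ≈ 0.01 RMS on
  cohort-scale data). EB shrinkage additionally leaves a fraction
  ≈ δ²/(n_b τ² + δ²) of each batch location behind by design; at the
  default cohort scale this is why the mean site variance fraction drops to
  ~0.3–0.4% rather than to zero.
- Confounding guard: the stacked [site indicators | covariates] design must
  be full rank; a covariate constant within batches (or a singleton batch)
  raises instead of silently absorbing the batch effect. Groups that are
  *absent* from some sites (the cohort's structural zeros) keep the design
  full rank and are handled.

**Variance partition.** Per metabolite an ordinary fixed-effects linear
model over sex, age at death, APOE4 count, PMI, site, group and Braak stage
is fitted and variance is attributed by sequential sums of squares in that
order (categoricals as grouped dummy blocks, via blockwise Gram–Schmidt
with re-orthogonalization). Sequential attribution makes the fractions plus
residual sum to exactly 1 and is deterministic; its order dependence means
shared variance between correlated predictors (e.g. site and group) is
credited to the earlier term — acceptable here because the diagnostic
compares the *same* ordering before and after correction. Mixed-model
variance partitioning is out of scope.

## 3. Interaction screen

- **Ordinal outcomes** (Braak 1–6 ascending severity; CERAD and Reagan in
  their native 1 = most-severe coding — direction only flips coefficient
  signs, never LRT values) use a cumulative-logit proportional-odds model,
  maximized by a damped Newton ascent with analytic gradient and Hessian,
  started at the empirical cumulative logits with zero slopes. Steps are
  halved until the likelihood increases and the thresholds stay ordered;
  convergence is max |grad| < 1e-8 (cap 100 iterations). Slope norms
  above 30 are treated as quasi-separation and flagged non-converged.
  K = 2 reduces exactly to logistic regression and is reused for the AD
  diagnosis screen (case/control only; "other" samples excluded).
- **LRT.** `Λ = −2(ℒ₀ − ℒ₁)` clamped at 0, df = parameter difference. With
  three ethnoracial groups the interaction adds two parameters, so df = 2;
  df = 1 would apply only to a two-group contrast. Under the null generator
  the empirical type-I error at nominal 0.05 is ≈ 0.052 (1,000 replicates,
  n = 500), computed by the acceptance suite.
- Metabolite abundance is standardized per screen (the LRT is invariant to
  affine rescaling, asserted at 1e-6; standardization only aids Newton
  conditioning). Group contrasts are treatment-coded against the largest
  group. Non-converged fits get missing p-values and are excluded from the
  BH family, with a count logged.
- **BH** is the step-up `q_(j) = min_{l≥j} m p_(l)/l`, applied within each
  outcome separately (outcomes are reported separately, so each forms its
  own family). Hits are q < 0.1.
- **Within-group follow-up** drops the group covariate and refits per
  group; p-values are Wald (an LRT variant would behave equivalently at
  these sample sizes); star tiers at 0.005 / 0.01 / 0.05.

## 4. Enrichment

One-sided Fisher's exact (hypergeometric upper tail) per annotation class,
2×2 table of hit × class membership, BH across classes. The universe is the
post-filter metabolite set that entered the screen, not the full platform
panel. Two-sided testing is available by flag; over-representation is the
default because depletion of a hit class is not the scientific question
here. The same routine applies to any grouping column, e.g. sphingolipid
chain-length/saturation strata.

## 5. Synthetic cohorts

The generator's defaults state the emulated world: 220/148/177 donors in
three ethnoracial groups over four sites with the published imbalance
(including one site with zero HA and one with zero NHW donors), group-
specific APOE4/sex/age distributions (the NHW group skews ~8 years older),
900 metabolites with the published super-pathway composition, per-site
additive log2 shifts (SD 0.25, tuned to ≈ 4% pre-correction site variance),
per-site multiplicative noise scales (log-SD 0.15), per-sample dilution
(log2-SD 0.2), 10% missing cells (uniform by default; an intensity-
dependent mechanism is available — the true mechanism in such data is
unknown), and sporadic 8-log2-unit extreme cells (rate 5e-4).

**Outcome model.** Braak stage is drawn from a proportional-odds model:
covariate effects (APOE4 0.5 log-odds/allele, sex 0.2, age 0.03/yr) plus a
latent "pathology factor" carried by the 20 interaction metabolites, which
form a co-regulated module (pairwise correlation 0.8, as co-regulated lipid
species show on this kind of platform). The factor slope is calibrated in
closed form so that each module member's *marginal* slope equals the
configured value (0.8 / 0.3 / 0.0 log-odds per SD for HA / NHW / NHAA) —
the configured unit is the quantity the per-metabolite screen estimates.
Conditioning the outcome jointly on 20 *independent* metabolites instead
was implemented and rejected: it attenuates every marginal slope by ≈ 0.46
and badly misspecifies the single-metabolite model, inflating false
positives. Thresholds are equally spaced over ±1.4 total latent SD around
the mean linear predictor so all six Braak levels are populated at default
n. CERAD is drawn as a noisy decreasing transform of Braak, Reagan by a
rule on both, and the diagnosis by the published case/control rule; because
synthetic CERAD inherits much of Braak's variation, the CERAD/Reagan/
diagnosis screens can pick up echoes of the planted Braak interaction —
unlike the real study, where only Braak interacted.

**What a green test establishes.** The generator has independent Gaussian
noise, linear covariate effects, exactly proportional odds, and missingness
unrelated to site. Real cohorts violate all of these (heavy tails,
platform-batch drift within site, informative missingness), so recovery
tests validate the machinery, not the biology; the published headline
quantities (60/907 hits, 4.2%→0.2% site variance) are data-specific and are
mirrored only qualitatively.

**Determinism.** One global seed fans out through `SeedSequence.spawn` into
per-stage child generators, so each stage is individually reproducible and
two runs with the same seed are byte-identical.

## 6. Known limitations

- Proportional-odds assumption is not itself tested (out of scope).
- Fixed-effects variance partition under strong site–group confounding
  credits shared variance to site; interpret the group fraction as a lower
  bound pre-correction.
- EB shrinkage trades a small residual site effect for variance control;
  use no-shrink mode if exact per-site centering matters more than
  stability at small batch sizes.
- The acceptance-scale recovery rates are properties of the stated
  synthetic world; they are not estimates of power in any real cohort.
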