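# metabomwas

Metabolome-wide association screens for multi-site postmortem brain cohorts:
does the relationship between a brain metabolite and Alzheimer's-disease
neuropathology differ by ethnoracial group?

The package is written for biostatisticians and computational biologists
working with untargeted brain metabolomics (e.g. Metabolon-style panels of
~900 metabolites) collected across several brain banks, where study-site
artifacts are confounded with the biological contrasts of interest. It
provides the full analysis chain as a tested library plus a thin CLI:

1. **QC preprocessing** — remove metabolites with >25% missing values,
   probabilistic quotient normalization (PQN), log2 transform, kNN
   imputation, local-outlier-factor (LOF) sample removal, per-metabolite
   extreme-value masking at `q = |Φ⁻¹(α/n)|` (α = 0.0125), and re-imputation.
2. **Site correction** — covariate-preserving parametric empirical-Bayes
   batch correction (ComBat). The observed log2 abundance is modeled as

   `Y_im = X_i β_m + γ_{b(i),m} + δ_{b(i),m} ε_im`

   where `b(i)` is the study site of sample *i* and `X_i` carries the
   protected covariates (sex, age at death, PMI, APOE4 count, ethnoracial
   group). Per-site locations γ and scales δ are shrunk across metabolites
   (normal / inverse-gamma priors, moment-matched, iterated posterior
   updates) and removed; the covariate contribution is restored. A
   per-metabolite variance-partition diagnostic (sequential sums of squares
   over sex, age, APOE4, PMI, site, group, Braak) quantifies the removal.
3. **Interaction screen** — per metabolite and outcome (Braak stage, CERAD
   score, Reagan score as cumulative-logit ordinal regressions; binary AD
   diagnosis as logistic regression):

   - base:        `outcome ~ metabolite + group + sex + age + PMI + APOE4`
   - interaction: `base + metabolite : group`

   compared by the likelihood-ratio statistic `Λ = −2(ℒ₀ − ℒ₁) ~ χ²_df`
   with df equal to the number of group contrasts, Benjamini–Hochberg
   adjusted within each outcome (hits at q < 0.1). Within-group follow-up
   refits `outcome ~ metabolite + covariates` inside each group to locate
   the source of heterogeneity (stars: \*\*\* p<0.005, \*\* p<0.01, \* p<0.05).
4. **Class enrichment** — one-sided Fisher's exact over-representation of
   hit metabolites per annotation class against the screened universe.
5. **Synthetic cohorts** — a generator that emulates the joint structure of
   a multiethnic, four-site study (group×site imbalance with structural
   zeros, per-site location/scale artifacts, dilution, missingness, extreme
   values, and a co-regulated metabolite module whose Braak slopes differ by
   group) together with a ground-truth record for recovery testing. The
   diagnosis rule is the published one: case if Braak ≥ 4 and CERAD ≤ 2,
   control if Braak ≤ 3 and CERAD ≥ 3, otherwise excluded from the
   diagnosis screen.

## Worked example

```sh
metabomwas run --seed 1 --out demo_run
```

simulates the default 545-donor cohort (220 NHAA / 148 HA / 177 NHW over
four sites, 900 metabolites, 20 interaction metabolites with marginal Braak
slopes 0.8 / 0.3 / 0.0 log-odds per SD), preprocesses, corrects, screens all
four outcomes and writes per-stage artifacts. The printed summary (seed 1):

```json
{
  "n_samples": 545,
  "n_metabolites": 900,
  "site_variance_pre": 0.0447,
  "site_variance_post": 0.0040,
  "hits": {"braak": 19, "cerad": 2, "reagan": 10, "diagnosis": 13}
}
```

Reading: before correction 4.5% of per-metabolite variance is attributable
to study site, 0.4% after, while planted group effects survive; 19 of the
900 metabolites show a Braak-by-group interaction at FDR < 0.1, and the
enrichment table for those hits puts sphingomyelins (5 hits in a class of
52, Fisher p = 0.0033) and dipeptides (3/19, p = 0.0063) at the top — the
generator plants its interaction metabolites preferentially in those
classes. The same screen can be driven from Python:

```python
from metabomwas import SynthConfig, generate_cohort, mwas_interaction_screen
from metabomwas.preprocess import pqn_normalize, log2_transform

matrix, metadata, annotation, truth = generate_cohort(SynthConfig(seed=1))
normalized, _ = pqn_normalize(matrix)
table = mwas_interaction_screen(log2_transform(normalized), metadata, "braak")
print(table.sort_values("p").head())
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete default-world pipeline from scratch with the given
seed — simulation, preprocessing, site correction with variance partition,
the four-outcome interaction screen and enrichment — prints the run summary
and writes the result JSON to `--out`.

## Layout

- `src/metabomwas/synth.py` — cohort generator + ground truth
- `src/metabomwas/preprocess.py` — QC chain and cohort harmonization
- `src/metabomwas/batchcorrect.py` — ComBat + variance partition
- `src/metabomwas/assoc.py` — ordinal/logistic fits, LRT, BH, screens
- `src/metabomwas/enrich.py` — Fisher class over-representation
- `src/metabomwas/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O
- `docs/methods.md` — modeling assumptions, defaults, numerical choices
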