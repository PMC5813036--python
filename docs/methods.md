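# Methods

This note documents the statistical model the package implements, the
synthetic-data conditions it is exercised under, and the design choices made
where more than one reasonable convention exists. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Scores

### Observed genetic scores

A panel is a list of SNPs with per-allele log odds ratios β̂ₖ and risk-allele
frequencies fₖ (both taken as given; the panel file is authoritative for
risk-allele orientation — no strand-flipping logic). The observed score is
the weighted dosage sum Σₖ β̂ₖ gᵢₖ over complete genotypes; a subject with
any missing dosage is routed to conditional simulation instead (missingness
is chip-level in the generator, so partial genotype rows do not arise there).

Under Hardy–Weinberg equilibrium and linkage equilibrium the score's
population variance is σ² = Σₖ 2β̂ₖ²fₖ(1−fₖ) and its mean is μ₀ = Σₖ 2β̂ₖfₖ.
σ² is additive over disjoint sub-panels; both are exact identities of the
Binomial(2, f) dosage distribution and are tested against enumeration.

### LD policy

Designated surrogate pairs (keep, drop) are resolved by dropping the
surrogate — rs10483813 is removed from the 24-SNP panel so the rs999737
locus is not double-weighted, leaving 23 SNPs. Any other same-chromosome
pair with R² above the threshold (default 0.3) is *retained but reported*;
the bundled LD table contains one such pair (rs6678914/rs4245739, R² 0.35).
The R² table is consumed as an input; the generator draws SNPs
independently, so LD enters only through this policy.

### Conditional simulation of unobserved scores

Where genotypes do not exist the score is drawn once per subject from

    GRS | d, h ~ N(μ₀ + d·σ² + ½·h·σ², σ²)

with d case status and h first-degree family history. The d·σ² shift is the
rare-disease conditional mean of a score with logistic effect 1 per unit;
the ½·h·σ² term transmits half the proband's expected deviation to a
first-degree relative. Two conventions around this formula are ours:

* **Mean anchor μ₀.** For a score simulated for *every* subject (GRS68) the
  anchor is irrelevant — all downstream metrics are invariant to a common
  shift — and we use μ₀ = 0. For GRS24, where ~35 % of subjects are
  simulated and the rest carry observed sums centred at μ₀ ≈ 1, the
  simulated draws are anchored at the panel's μ₀ so both provenances share a
  scale; without this the two clusters inflate the score variance roughly
  tenfold and destroy continuous-mode discrimination.
* **σ² for GRS24** is computed from the retained 23-SNP panel (the panel the
  observed sums actually use), not the pre-exclusion 24-SNP panel.
* One draw per subject per seed; no averaging over draws.

Mixed provenance within GRS92 (observed GRS24 + simulated GRS68) is allowed
and tracked per subject. With h ≡ 0 the simulated score discriminates at
AUROC = Φ(σ/√2) exactly; this closed form is used both as a test oracle and
to calibrate the generator (below).

### Risk-factor scores

MRFS and NMRFS are each fitted as one multivariate logistic regression of
status on the dummy-coded factors of their own set (reference = first
category; intercept estimated but excluded from the score), then applied as
per-subject sums of fitted betas. The two sets are fitted *separately* by
default — each beta adjusted only within its own set, mirroring the parallel
construction of the two scores — with `combined=True` available to adjust
every factor for all others. Weights are in-sample (fitted and applied on
the same cohort), as in the validation design the package reproduces; the
null-calibration test applies weights out of sample precisely because
in-sample fitting of k noise parameters inflates the apparent AUROC by
≈ Φ(√(k/(nW))/√2) − ½ (W = mean Bernoulli variance), which at k ≈ 12,
n = 3,642 is ~0.03 — fitting noise, not signal.

Missing factor values are handled complete-case with counts logged.
Menopausal status and age at menopause are encoded as one combined
categorical (premenopausal / menopause-age bands) to avoid structural
missingness. Fits use Newton–Raphson with tolerance 1e-10; non-convergence
and complete separation raise errors naming the factor set.

FM = GRS92 + MRFS + NMRFS on the complete-case intersection.

## 2. Evaluation conventions

* **Deciles:** pooled case+control sample; cutpoints are the 10 %–90 %
  linear-interpolation quantiles; a value tied with a cutpoint falls in the
  lower decile (sizes may then be unequal; this is reported, not corrected).
  Decile odds ratios come from logistic fits on decile indicators — the
  model is saturated, so estimates equal cross-product ratios (tested to
  1e-6) — with Wald 95 % CIs. A zero cell yields the raw cross-product with
  an undefined CI and a flag; no continuity correction.
* **AUROC:** Mann–Whitney with ties counting ½. Default mode collapses
  subjects to their decile-model fitted probability (the observed case
  fraction of their decile — the saturated MLE); `continuous` mode ranks
  the raw score. Constant predictors return 0.5 with a warning.
* **NRI/IDI:** computed on fitted probabilities from *univariate* logistic
  models of status on each composite score; enhanced composites are sums of
  component scores, not refit bivariate models (a `refit` flag provides the
  alternative). Nesting is asserted by the caller, not verified. Ties in
  NRI count toward neither direction.
* **AUROC-difference p-value:** DeLong's paired test on the same predictors
  as the reported AUROCs (midrank placement values; identical predictors
  short-circuit to Δ=0, p=1; zero placement variance is an error). A
  bootstrap cross-check appears in the tests.
* **Descriptives:** case/control means with equal-variance Student-t tests,
  pairwise Pearson correlations, Gaussian-KDE density grids per arm.

## 3. Incidence projection

A univariate logistic slope β (log-OR per score unit) scales a baseline
age-specific incidence table: rateᵢ = baseline · exp[β(sᵢ − s̄)]. The
log-OR is used directly as a log rate ratio — faithful to the procedure
being reproduced; for a rare disease the OR→rate-ratio gap is second-order,
and we document rather than correct it. s̄ is the pooled case+control mean
(`mean_score` parameter covers alternatives); percentiles are empirical
linear-interpolation quantiles, consistent with the decile convention, and
clamp to the observed min/max below 100 subjects (with a warning).
Identities: the mean-score subject reproduces the baseline bit-exactly;
curve(p)/curve(q) is age-constant and equals exp(β(s_p − s_q)).

The bundled baseline table is a synthetic 5-year-group approximation of a
southern-European female breast-cancer incidence schedule (per 100,000
woman-years), shipped so the projection stage runs offline; it is not
measured data.

## 4. The synthetic cohort generator

The generator produces the conditions the analysis assumes, not a portrait
of any real population:

* **Design:** 1,732 cases / 1,910 controls, ages 20–85; controls
  frequency-matched to cases on 5-year bins by largest-remainder
  apportionment (per-bin proportions match within 1/n_controls); exact
  requested counts or an error naming the infeasible bin.
* **Covariates:** HWE genotypes, independent across SNPs; factors sampled
  independently from their category probabilities; ages uniform. Family
  history is a root binary covariate with its own effect, used both inside
  NMRFS and as h in the conditional simulation (its double role in the
  analysis). Genotype missingness is subject-level (whole chip): by default
  1,138/1,732 cases and 1,239/1,910 controls keep genotypes (594 and 671
  masked).
* **Disease model:** logistic in all dosages and factor dummies, sampled
  from a source population 20× the target size. `intercept` is interpreted
  as the baseline log-odds at the *average* covariate profile — the analytic
  mean of the linear predictor (Σ2βf per panel + Σpβ per factor) is
  subtracted — so prevalence ≈ expit(intercept) ≈ 4.7 % at the default −3,
  keeping the rare-disease premise of the conditional simulation.
* **Latent panel:** the 68-SNP panel's genotypes are generated and fed into
  the disease model but never emitted, reproducing the situation the
  conditional simulation exists for.
* **RNG:** one master seed spawns named child streams (genotypes,
  latent_genotypes, factors, status, masking, grs24_sim, grs68_sim), so any
  stage can be re-run in isolation with identical draws; fixed seed ⇒
  bit-identical cohorts.

### Calibration of the default conditions

Effect sizes were fixed once, before testing, by inverting AUROC = Φ(σ/√2):
the 23-SNP retained panel's σ² is (√2·Φ⁻¹(0.5676))² ≈ 0.0580 and the
68-SNP panel's is (√2·Φ⁻¹(0.5936))² ≈ 0.1121, the discrimination levels the
two genetic scores are meant to carry; SNP betas were drawn once and scaled
to those totals. Default factor betas give dummy-score variances ≈ 0.073
(non-modifiable, dominated by family history at OR 2 and prevalence 8 %)
and ≈ 0.005 (modifiable), so the intended hierarchy genetic >
non-modifiable > modifiable holds by construction. Exact factor category
definitions are not hard-coded anywhere downstream — the generator is fully
parameterised by `RiskFactorSpec`s.

### What the generator does **not** emulate

Real LD between SNPs (draws are independent), population stratification,
genotype–family-history correlation (so the ½hσ² term is a deliberate
misspecification relative to the generator, as it is relative to any single
study), missing-at-random factor data, recall bias, age–factor dependence,
and calendar effects. Passing tests therefore demonstrate correctness of
the *procedures* and their behaviour under the stated model — not
transportability of any fitted weight to real data.

## 5. Problem sizes and determinism

The test suite uses study-size cohorts (n = 3,642) throughout: 20
replicates for weight recovery (bias per parameter averaged over replicates,
coverage pooled over 320 parameter draws), 50 replicates for the score
hierarchy, 100,000 draws per stratum for simulation moments, 20,000 per arm
for the binormal AUROC limit, and 200 random instances (n ≤ 100) for the
metric-enumeration oracles. All randomness flows from fixed seeds;
`scripts/acceptance.py` derives everything from `--seed` and is
byte-deterministic given it.

## 6. Known limitations

* Decile-model AUROC on heavily tied scores inherits the decile tie rule;
  alternative quantile definitions would move third-decimal digits.
* The DeLong test is asymptotic; at very small n the bootstrap fallback in
  the tests is the more honest reference.
* NRI/IDI standard errors are not reported by the library (the tests use
  the standard closed forms where needed).
* Logistic fits use plain Newton–Raphson; quasi-separated configurations
  fail loudly rather than being penalised (no Firth correction).
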