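# Methods

## The epimutation model

`semscan` detects *stochastic epigenetic mutations* (SEMs): per-CpG,
per-subject methylation states that lie far outside the population
distribution at that locus. For each probe with beta values
β₁ … β_n across samples, the quartiles Q1 and Q3 and the interquartile
range IQR = Q3 − Q1 define the extreme Tukey fences

    lower = Q1 − k·IQR,    upper = Q3 + k·IQR,    k = 3,

and a sample is epimutated at that probe when its beta value *strictly*
exceeds a fence (hyper above, hypo below; a value equal to a fence is
not a call, since the rule is "exceeding"). k = 3 marks the classical
*extreme* outlier fence — for Gaussian data it sits at ±4.72 SD, a
per-value tail probability of about 2.4 × 10⁻⁶ — and is exposed for
sensitivity analysis (calls are monotone decreasing in k).

The per-subject *epimutation burden* is the total call count; it is
heavily right-skewed, so downstream models use log_sem = ln(n + 1). The
+1 keeps zero-burden subjects (typically children) in the regressions;
how zero counts should enter the log transform is otherwise
underdetermined.

Quartile conventions differ across boxplot routines. The default is
linear interpolation of order statistics at position p·(n − 1); the
Tukey hinge convention (depth (⌊(n+1)/2⌋ + 1)/2) is available via
`quantile_method="tukey"`. For n ≳ 30 the two differ negligibly; the
calling rule itself is convention-agnostic.

Assumptions worth keeping in mind: the population at each probe is
treated as homogeneous (no covariate-adjusted or cell-type-aware
fences), all samples share one denominator (incomplete matrices are
refused rather than silently per-probe dropped), and fences are
estimated from the same samples being called, so they are sample
statistics, not fixed thresholds — with few samples (< 30) the
false-positive rate is somewhat above the asymptotic tail value.

## Preprocessing

Standard array QC precedes calling: samples with bisulfite-conversion
control intensity < 4000 (strict) are dropped, then samples whose PC1 or
PC2 score on the probe-standardised matrix lies > 4 SD from the mean
(globally aberrant profiles). Probes are removed, in fixed order, for
any missing beta, for detection p ≥ 0.05 in more than 5% of samples,
and for residing on chromosome X or Y (X-linked methylation reflects
X-inactivation, not somatic epimutation, and would confound the female
samples). Quantile normalisation then forces every sample onto the mean
order-statistic distribution; ties receive the mean reference value
over their rank span so tied inputs stay tied. Mixed 27K/450K cohorts
are pooled on the probe intersection after per-platform QC.

Two caveats are documented rather than hidden. Background and
Infinium-I/II peak correction operate on fluorescence intensities,
which a beta matrix no longer carries; `background_correct` is an
identity placeholder. And quantile normalisation equalises per-sample
value multisets *exactly*, hence per-sample means: global
methylation-level trends (average beta vs age or BMI) must be measured
before normalisation, or on a probe subset of a larger normalised
array. Per-probe outlier calls survive normalisation essentially
unchanged because an epimutated value sits among similar-magnitude
values of other probes and keeps its rank neighbourhood.

## Gene-level enrichment

For a single subject, over-representation of epimutated probes in a
gene is tested with the inclusive hypergeometric upper tail
P(X ≥ S_I), where N_G is the probe universe, N_S the subject's
epimutated probes, G_I the gene's probes and S_I the epimutated ones
among them. Raw p-values are Bonferroni-corrected by the number of
genes tested (genes with ≥ 1 probe in the universe). The default
universe is the post-QC probe set actually scanned; the full manifest
can be supplied instead. A probe mapping to several genes counts once
per gene but once in the universe totals. The survival function is
evaluated in log space, keeping relative precision for tails down to
10⁻³⁰⁰; tests verify < 10⁻¹⁰ relative error against exact rational
arithmetic.

## XCI skewing (HUMARA)

Methylation-sensitive digestion (HpaII/HhaI) destroys the unmethylated,
active-X allele before PCR of the AR CAG repeat, so digested peak
heights reflect the inactive X. With digested heights (h₁, h₂) and
undigested heights (u₁, u₂) correcting allele-specific amplification
bias, the corrected ratio r = (h₁/h₂)/(u₁/u₂) gives the fraction
f = r/(1+r) of cells with allele 1 inactive, and the degree of skewing

    DS = |(1 − f) − 0.5| × 100 ∈ [0, 50],

0 meaning random 50:50 inactivation and 50 complete skew. A single zero
digested peak is the limit r ∈ {0, ∞} (DS = 50); both zero is an error.
DS is invariant under allele relabelling and common rescaling of all
four peaks, and monotone in |log r|. Heterozygosity (two resolvable CAG
alleles) is the caller's responsibility.

## Association layer

All model variables are Z-scored (n−1 denominator), so coefficients are
standardized β. Regressions are OLS with normal-approximation 95% CIs;
designs with condition number > 10⁸ are rejected as collinear, naming
the worst pair. The correlation ratio η = √(SS_between/SS_total)
summarises a continuous variable across categorical groups (the five
age strata 0–19, 20–39, 40–59, 60–79, 80–106), with groups weighted by
size.

The path model is a recursive system of standardized regressions: each
endogenous variable is regressed on its parent set, and the edge
coefficients are the standardized partial coefficients. For a
recursive, just-identified diagram this coincides with the
structural-equation estimates, so no general SEM fitter is needed. The
default diagram is age → log_sem, age → avg_beta, log_sem → avg_beta,
age → ds_xci, log_sem → ds_xci, avg_beta → ds_xci; the edge set is
configuration, not code. The scientific question it encodes: does age
retain a direct effect on XCI skewing once the epimutation burden is
adjusted for, or is the well-known age–skewing association mediated by
burden?

Missing covariates (BMI; DS outside the informative-female subset) are
handled by complete-case analysis per model, or by chained-equation
multiple imputation with posterior-noise draws (m = 5 by default,
deterministic per seed), pooled by Rubin's rules: q̄ = mean of the m
estimates, W = mean within-imputation variance, B = between-imputation
variance, T = W + (1 + 1/m)·B.

## The synthetic cohort generator

No deposited cohort exists, so the generator emulates the study design
end to end and carries its ground truth. Defaults: 178 subjects aged
3–106 years with at least 10 per age stratum; ~53% measured on a
"450K"-like platform, the rest on "27K"; 2000 shared probes (standing
in for the 25,014-probe pooled matrix) plus 500 private probes per
platform, a slice of the private ones on chrX to exercise the sex-
chromosome filter; genes of 10 consecutive probes.

Component choices, each with its rationale:

- **Baselines** μ_j are bimodal (Beta(2,8)/Beta(8,2) mixture, clipped to
  [0.03, 0.97]) — real methylation landscapes are bimodal, and baseline
  diversity is what lets per-probe outliers survive quantile
  normalisation.
- **Noise** is logit-normal (SD 0.15 on the logit scale, values clipped
  to [0.001, 0.999]): heteroscedastic, shrinking near 0 and 1, as on
  arrays. Its heavier-than-Gaussian beta-scale tails at extreme
  baselines produce a realistic trickle of baseline false-positive
  calls (~10⁻⁴ per value), far above the Gaussian tail bound but
  negligible against planted burdens.
- **Global drift**: −3 × 10⁻⁴ beta/year, plus −2 × 10⁻³ per BMI unit —
  mild global hypomethylation with age and BMI.
- **Burden**: counts ~ Poisson(λ₀·e^{b·age + u}) with λ₀ = 2, b =
  0.04/year and a subject-level frailty u ~ N(0, 1) clipped to ±2. The
  frailty keeps the individual-level age–burden correlation near the
  observed regime (r ≈ 0.6–0.7) instead of near-deterministic; Poisson
  regression still recovers b because the frailty is age-independent.
- **Planted epimutations** are displaced towards the far unit-interval
  boundary by max(effect size, 7·σ_j + 0.05) — beyond any achievable
  fence — with the direction (hyper/hypo) recorded in the truth set.
  Displacements that would leave [0.005, 0.995] raise an error.
- **Duplicates**: replicates re-measure a subject with fresh noise,
  inherit each planted call with probability `duplicate_share` (0.99)
  and gain independent calls for the complement. Subjects with < 10
  planted epimutations are not duplicated: indicator-vector correlation
  is degenerate for near-empty call sets, and the study's duplicated
  samples were high-burden adults.
- **XCI skewing**, informative females only (~70% of females):
  DS = 25 + 7·(log_sem_true − 2.8) + N(0, 6), clipped to [0, 50]. The
  map is linear by design — a saturating (sigmoid) map, or frequent
  boundary clipping, makes E[DS | burden] nonlinear and leaks a
  spurious direct age→DS effect through the burden–age correlation,
  breaking the generator's full-mediation contract. With these values
  clipping affects ~3% of subjects and the conditional age→DS test
  rejects at its nominal 5% rate (measured 5.5% over 200 seeds).

What the generator does *not* emulate: probe–probe co-methylation,
cell-composition mixtures, batch effects beyond the platform split, and
intensity-level artifacts. Passing tests therefore demonstrate the
statistical machinery — fence calling, enrichment, concordance,
mediation recovery — under the assumed generative structure, not
robustness to every failure mode of real arrays.

## Numerical and scale choices

Problem sizes are desk-scale by design: 1,000 random matrices for the
fence-oracle agreement check, 10⁷ Gaussian draws (2000 probes × 5000
samples — large per-probe n keeps the finite-sample fence bias well
inside the binomial tolerance) for the null false-positive rate, 20
cohort replicates for rate recovery, 50 seeds for mediation recovery,
30 pairs for duplicate concordance. The whole validation runs in well
under a minute of compute per block on one CPU.

Other numerics: fences compare strictly; quantile normalisation
resolves ties by rank-span means; the collinearity guard is a condition
number of 10⁸; imputation seeds derive from a `SeedSequence` so runs
are reproducible; hypergeometric tails use the survival function, never
1 − CDF.

## Known limitations

- Fences are unadjusted for covariates and assume an outlier-free
  majority per probe; contamination above ~25% per probe breaks the
  quartile robustness.
- With only beta values available, background/peak correction cannot be
  reproduced; pipelines starting from IDATs should pre-correct upstream.
- The path analysis is linear-Gaussian on Z-scores; saturating
  relations (e.g. DS near its 0/50 bounds) attenuate and can bias edge
  tests, as the generator work above demonstrates.
- `impute_missing` assumes missingness at random given the observed
  covariates.
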