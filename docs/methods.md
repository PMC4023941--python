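# Methods

## Score model

The genetic risk score is a strictly unweighted allele count. A panel declares,
per variant, which allele increases dopamine neurotransmission; a subject's
score is the number of such alleles carried across the panel. For SNPs this is
the 0/1/2 risk-allele count; for the DAT 3′-UTR VNTR each allele contributes 1
point when its repeat count is ≤ 9 and 0 otherwise. The cutoff is implemented
as a predicate rather than an enumerated allele list so that repeat counts
never observed in the source data (e.g. 5 or 12) are still coded consistently
with the stated rule; such out-of-range repeats trigger a log warning because
the rule is an extrapolation there. Panels are versioned YAML data, not code:
the 3-variant and 4-variant sub-panels used by the replication-style analyses
are configuration files (`stard3`, `gsp4`) rather than separate code paths.

When genotypes are unavailable, imputed dosages (expected risk-allele counts
in [0, 2]) substitute one-for-one and the score becomes a real-valued sum.
Orientation is resolved at read time — a dosage column whose metadata names the
non-risk allele is flipped d → 2 − d before anything downstream sees it — so
all scoring code can assume risk-allele dosages. This removes the classic
sign-error failure mode of score pipelines. Mixed panels (some variants
genotyped, one imputed) are supported; each variant contributes whichever
representation it has, which is why observed score maxima can be fractional.

Scores of different panel sizes are never rescaled to a common range, so
regression coefficients are comparable only within a panel.

## Quality control

Hardy-Weinberg equilibrium is tested per SNP with the uncorrected 1-df Pearson
chi-square against expected counts (np², 2npq, nq²) at the allele frequency
estimated from the same sample. No continuity correction is applied — the
uncorrected statistic is the one that reproduces the reference values the test
suite pins. A monomorphic variant is reported as untestable rather than
yielding NaN. The multi-allelic VNTR has no standard biallelic test; the QC
report optionally collapses its alleles into the two scoring classes
(≤ 9 vs ≥ 10 repeats) and tests the collapsed system, labelling the row as a
collapsed test.

Missing data handling is strict complete-case: subjects with any missing value
among the required fields are excluded, in two audited stages (genotype/dosage
completeness first, then phenotype/covariates), and the report carries input /
excluded / retained counts, the exclusion percentage to two decimals, and
per-field missingness. No imputation of any kind is performed by this package.

## Association analysis

The primary model is OLS of the symptom scale on the score plus covariates.
Continuous covariates enter untransformed; categorical covariates are
dummy-coded with k−1 indicators against the most frequent level (a stable
choice under resampling; the reference can be pinned explicitly). Standard
errors come from σ̂²(XᵀX)⁻¹; p-values are two-sided from the t distribution at
the residual degrees of freedom, never the normal approximation, and the 95%
CI is β ± t₀.₉₇₅,df·SE. Rank-deficient designs are rejected with the collinear
columns named. The fitting itself is delegated to statsmodels OLS; the test
suite cross-checks estimates, SEs, p-values and CIs against an independent
normal-equations oracle to 1e-8.

Phenotypes are screened, not transformed: moment-based skewness and kurtosis
(bias-adjusted G1 and excess G2 by default; a flag yields the Pearson
non-excess convention, since reported screening values do not identify which
convention produced them) are computed and reported, mirroring an analysis
policy of fitting the raw scale when shape statistics are within reasonable
limits.

Sensitivity analyses: leave-one-out re-fits the model on every size-(V−1)
sub-panel (the full score equals any sub-panel score plus the omitted
variant's points, an identity the tests enforce exactly); the single-variant
scan fits each variant's 0/1/2 points separately and controls the family-wise
error rate by Bonferroni with m = number of variants scanned. Bonferroni is
the only multiplicity method offered.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Genotypes** are drawn in Hardy-Weinberg equilibrium — two independent
  Bernoulli alleles per SNP, two draws from a repeat-count frequency table for
  the VNTR. Default frequencies are the sample frequencies implied by the
  discovery cohort's reported genotype counts (rs4680 Met 0.3755, rs4532 G
  0.2619, rs1800497 Glu 0.7051, rs6280 Gly 0.3425; DAT repeats over 544
  counted alleles: 10 → 0.8346, 9 → 0.1507, 11 → 0.0037, 6 → 0.0074,
  7 → 0.0018, 8 → 0.0018). Variants are simulated in linkage equilibrium even
  though DRD1 and DAT share a chromosome; no LD information is available for
  the source sample, and this is a documented limitation.
- **Dosages** are hard calls plus truncated Gaussian noise, clipped to [0, 2].
  `calibrate_dosage_noise` inverts corr²(count, count+e) = 2pq/(2pq+σ²) to hit
  a target imputation-quality r² (e.g. 0.8); the default noise SD of 0.3
  corresponds to r² ≈ 0.84 at the rs4680 frequency.
- **Covariates**: age uniform over the eligible 18–35 range, sex Bernoulli
  (P(female) = 0.568), ethnicity categorical (Asian 0.49 / White 0.30 / Other
  0.21), optional standard-normal ancestry-PC columns.
- **Phenotype**: y = intercept + slope·GRS + covariate offsets + N(0, σ).
  Defaults: slope −0.80 symptom points per score point, intercept 11.7 and
  σ = 6.3, chosen so the Gaussian-mode phenotype mean/SD land near the
  observed 8.7 ± 6.5 at the default score distribution. Default covariate
  offsets are modest (sex +0.5; ethnicity White +0.8, Other +1.5 vs Asian) —
  enough to make covariate adjustment non-trivial without dominating the
  signal. The `cesd_like` mode rounds to integers and clamps to [0, 60],
  which reproduces the mild positive skew of real symptom scales.

Every stage draws from an independent seeded sub-stream of the spec's seed, so
outputs are bit-reproducible and adding one stage never perturbs another's
draws.

### What the simulation does and does not show

Passing parameter-recovery tests shows the estimator is unbiased and
calibrated *under the generative model*: independent variants in exact HWE, a
truly linear dose-response, covariates independent of genotype, Gaussian
noise. Real cohorts violate several of these (inter-locus correlation — the
reported score SD of 1.6 exceeds the ≈ 1.42 implied by independent variants at
the reported marginals, suggesting such correlation in the real sample;
population stratification; measurement artefacts), so green tests certify the
pipeline's arithmetic and calibration, not the biology. Subject-level results
of any real cohort are not reproducible from printed summaries; the published
effect sizes serve as generating values for recovery experiments, not as
targets for exact reproduction.

Note also that the `cesd_like` floor/ceiling attenuates the fitted slope by
roughly 9% at the default settings (measured: mean fitted β ≈ −0.73 for a
generating −0.80 over 100 replicates) — a real censoring effect, which is why
calibration checks run in `gaussian` mode while `cesd_like` exists to exercise
the descriptive screening path.

## Numerical and design choices

- Genotype dialect: `a/b` with no phasing semantics, order-insensitive,
  missing sentinel `./.`; amino-acid labels (Met/Val, Glu/Lys, Ser/Gly) are
  accepted as aliases and resolved through the panel's label map.
- Exclusion percentages are reported rounded to two decimals; rendered tables
  are full precision by default with an optional display precision, so
  rounding is a presentation choice, never compounded into computation.
- The recovery experiment's problem sizes (n = 273 per cohort, 500 replicates
  for calibration checks) match the discovery-cohort scale while keeping a
  full run in seconds.
- Pipeline runs are deterministic: identical config and seed produce
  byte-identical TSV outputs, and the run log records the package version and
  seed. Audit tables (exclusion report, demographics) are always emitted even
  when analysis toggles are off, because exclusion accounting is the least
  reproducible part of published score analyses.

## Known limitations

- No LD, ascertainment or gene–environment structure in the simulator.
- No weighted or genome-wide polygenic scores; no exact (Fisher-type) HWE
  test; no multi-allelic HWE beyond the collapsed VNTR option.
- VCF input covers biallelic SNPs only; VNTR genotypes must arrive via TSV.
- Dosage-based scoring assumes the upstream imputation is trustworthy; the
  package consumes dosages and never re-imputes.
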