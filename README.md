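# dopagrs

Unweighted dopamine genetic risk scores for candidate-gene association
analysis: declarative score panels, hard-call and imputed-dosage scoring,
Hardy-Weinberg QC, audited complete-case filtering, covariate-adjusted linear
association with leave-one-out and single-variant sensitivity analyses, and a
synthetic-cohort generator so the entire pipeline is testable without access
to any real genotype data.

## The scientific problem

Individual common variants in dopamine-pathway genes have small effects on
behavioural phenotypes, so single-SNP association tests in modest cohorts are
underpowered. A *genetic risk score* (GRS) addresses this by summing, across a
panel of functional polymorphisms, the number of alleles that push the same
biological direction — here, alleles that increase dopamine neurotransmission.
The shipped 5-variant panel covers synaptic dopamine availability (*COMT*
rs4680, the *DAT* 3′-UTR 40-bp VNTR rs28363170) and receptor binding (*DRD1*
rs4532, *DRD2/ANKK1* rs1800497, *DRD3* rs6280).

Each variant contributes 0, 1 or 2 points:

| points | rs4532 | rs1800497 | rs6280 | rs4680 | rs28363170 |
|--------|--------|-----------|--------|--------|------------|
| 0 | A/A | Lys/Lys | Ser/Ser | Val/Val | 10/10 |
| 1 | A/G | Glu/Lys | Ser/Gly | Val/Met | 9/10 |
| 2 | G/G | Glu/Glu | Gly/Gly | Met/Met | 9/9 |

For the VNTR the rule is a repeat-count predicate: each allele with ≤ 9
repeats scores 1, alleles with ≥ 10 repeats score 0 (so the rare 6/7/8-repeat
alleles count like 9, and 11 counts like 10). The per-subject score is the
plain unweighted sum

&nbsp;&nbsp;&nbsp;&nbsp;GRS = Σ<sub>v</sub> (risk-allele count at *v*) ∈ {0, …, 2V},

or the sum of imputed risk-allele dosages (each in [0, 2]) when hard calls are
unavailable. The association model is ordinary least squares,

&nbsp;&nbsp;&nbsp;&nbsp;y = α + β·GRS + γᵀ·covariates + ε,

where y is a continuous depressive-symptom scale (CES-D, HAM-D or a POMS
t-score) and covariates are age, sex, race/ethnicity or ancestry principal
components, and marital status. Inference is t-based (two-sided p, 95% CI);
the single-variant scan applies a Bonferroni threshold α/m over the m variants
scanned.

## Worked example

Simulate a discovery-style cohort (n = 273, allele frequencies from the
published genotype counts, true slope −0.80 CES-D points per score point,
bounded integer phenotype) and run the full analysis:

```python
import dopagrs as d

panel = d.builtin_panel("hs5")
spec = d.SimulationSpec(seed=5, phenotype_mode="cesd_like")
cohort = d.simulate_cohort(spec, panel)

scores = d.compute_grs_hardcall(cohort, panel)
qc = d.qc_report(cohort, panel)
fit = d.grs_association(cohort, panel, covariate_spec=["ethnicity"])
print(fit.term("grs"))
```

Output for this seed:

```
n = 273
mean score 3.79 sd 1.34 range 0-7
phenotype mean 9.8 sd 6.4 skew 0.37

variant_id  risk_allele_freq  chi_square  p_value
    rs4680             0.390       0.019    0.889
rs28363170             0.189       0.013    0.910
    rs4532             0.236       0.006    0.936
 rs1800497             0.731       0.139    0.709
    rs6280             0.350       2.907    0.088

grs: beta -0.88  se 0.29  p 0.0024  CI (-1.44, -0.31)   r2 0.038  n 273
```

Every variant is consistent with Hardy-Weinberg equilibrium (all chi-square
p > 0.05, as expected for genotypes drawn under HWE), the mean score sits near
the 3.7 implied by the generating allele frequencies, and the fitted slope
−0.88 ± 0.29 recovers the generating −0.80 within one standard error.
`d.predicted_difference(fit, "grs", 10)` translates the slope into the expected
symptom difference between the lowest (0) and highest (10) possible scores —
8.8 CES-D points for this fit.

The same analysis runs from the shell against TSV/VCF inputs:

```bash
grs simulate --spec spec.yaml --panel hs5 --out cohort/
grs run --config run.yaml      # QC + scoring + association + sensitivity tables
```

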