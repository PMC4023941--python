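"""Synthetic cohorts with the statistical structure the score analysis assumes.

The generator draws genotypes in Hardy-Weinberg equilibrium at configurable
risk-allele frequencies (SNPs: two independent Bernoulli alleles; the DAT VNTR:
two draws from a repeat-count frequency table), perturbs hard calls into
imputation-style fractional dosages, samples demographic covariates, and builds
a phenotype that is linear in the genetic risk score with additive covariate
effects and Gaussian noise. An optional CES-D-like mode floors the phenotype at
0, caps it at 60 and rounds to integers, which reproduces the mild positive
skew of real symptom-scale data.

Default frequencies are the sample frequencies implied by the discovery
cohort's printed genotype counts (n = 273 subjects; 272 called for the VNTR),
and the default slope of -0.80 symptom points per score point matches that
cohort's adjusted estimate. Variants are simulated in linkage equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .association import GRS_TERM, grs_association
from .cohort import CohortTable
from .panel import ScorePanel
from .scoring import SCORE_COLUMN, compute_grs_hardcall

#: Reported genotype counts of the discovery sample (n = 273; the VNTR has 272
#: called subjects). Genotype keys are canonical (alleles sorted). These are
#: the source of every default frequency below.
HS_GENOTYPE_COUNTS: dict[str, dict[str, int]] = {
    "rs4680": {"A/A": 38, "A/G": 129, "G/G": 106},          # Met/Met, Val/Met, Val/Val
    "rs4532": {"G/G": 21, "A/G": 101, "A/A": 151},
    "rs1800497": {"A/A": 23, "A/G": 115, "G/G": 135},       # Lys/Lys, Lys/Glu, Glu/Glu
    "rs6280": {"C/C": 32, "C/T": 123, "T/T": 118},          # Gly/Gly, Gly/Ser, Ser/Ser
    "rs28363170": {"10/10": 190, "9/10": 66, "9/9": 8, "10/11": 2,
                   "6/10": 4, "7/10": 1, "8/10": 1},
}


def _snp_risk_freq(counts: dict[str, int], risk: str) -> float:
    copies = sum(n * g.split("/").count(risk) for g, n in counts.items())
    return copies / (2 * sum(counts.values()))


def _repeat_freq(counts: dict[str, int]) -> dict[int, float]:
    tally: dict[int, int] = {}
    for g, n in counts.items():
        for tok in g.split("/"):
            tally[int(tok)] = tally.get(int(tok), 0) + n
    total = sum(tally.values())
    return {rep: c / total for rep, c in sorted(tally.items())}


#: Risk-allele frequencies implied by the printed genotype counts
#: (e.g. rs4680 Met: (2*38 + 129) / 546 ~ 0.3755).
HS_SNP_RISK_FREQ: dict[str, float] = {
    "rs4680": _snp_risk_freq(HS_GENOTYPE_COUNTS["rs4680"], "A"),
    "rs4532": _snp_risk_freq(HS_GENOTYPE_COUNTS["rs4532"], "G"),
    "rs1800497": _snp_risk_freq(HS_GENOTYPE_COUNTS["rs1800497"], "G"),
    "rs6280": _snp_risk_freq(HS_GENOTYPE_COUNTS["rs6280"], "C"),
}

#: DAT 3'-UTR repeat-count allele frequencies over the 544 counted alleles.
HS_DAT_REPEAT_FREQ: dict[int, float] = _repeat_freq(HS_GENOTYPE_COUNTS["rs28363170"])

# independent sub-streams per stage, so adding a stage never shifts another's draws
_STREAM = {"genotypes": 0, "dosages": 1, "covariates": 2, "phenotype": 3}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Generative parameters for one synthetic cohort.

    ``snp_risk_freq`` maps SNP ids to risk-allele frequencies and
    ``vntr_repeat_freq`` maps VNTR ids to repeat-count frequency tables; the
    defaults reproduce the discovery sample's marginal genotype distribution.
    ``true_slope`` is the phenotype change per score point, ``noise_sd`` the
    residual standard deviation (both in symptom-scale points). The default
    intercept/noise (11.7, 6.3) put the gaussian-mode phenotype near the
    discovery sample's observed mean and SD (8.7 +/- 6.5) at the default score
    distribution. ``covariate_effects`` adds phenotype offsets: a number for a
    continuous/binary covariate, a level -> offset mapping for a categorical.
    """

    n: int = 273
    seed: int = 0
    snp_risk_freq: dict[str, float] = field(default_factory=lambda: dict(HS_SNP_RISK_FREQ))
    vntr_repeat_freq: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"rs28363170": dict(HS_DAT_REPEAT_FREQ)}
    )
    true_slope: float = -0.80
    intercept: float = 11.7
    noise_sd: float = 6.3
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.5, "ethnicity": {"White": 0.8, "Other": 1.5}}
    )
    phenotype_mode: str = "gaussian"  # or "cesd_like"
    dosage_noise: float = 0.3
    age_range: tuple[float, float] = (18.0, 35.0)
    p_female: float = 0.568
    ethnicity_proportions: dict[str, float] = field(
        default_factory=lambda: {"Asian": 0.49, "White": 0.30, "Other": 0.21}
    )
    n_pcs: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError("cohort size must be >= 1")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.dosage_noise < 0:
            raise SimulationError("dosage_noise must be >= 0")
        if self.phenotype_mode not in ("gaussian", "cesd_like"):
            raise SimulationError(f"unknown phenotype mode {self.phenotype_mode!r}")
        for vid, f in self.snp_risk_freq.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"{vid}: allele frequency {f} outside [0, 1]")
        for vid, table in self.vntr_repeat_freq.items():
            if not math.isclose(sum(table.values()), 1.0, abs_tol=1e-9):
                raise SimulationError(f"{vid}: repeat frequencies must sum to 1")
        if not math.isclose(sum(self.ethnicity_proportions.values()), 1.0, abs_tol=1e-9):
            raise SimulationError("ethnicity proportions must sum to 1")


def spec_from_yaml(path) -> SimulationSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "vntr_repeat_freq" in doc:
        doc["vntr_repeat_freq"] = {
            vid: {int(k): float(v) for k, v in table.items()}
            for vid, table in doc["vntr_repeat_freq"].items()
        }
    if "age_range" in doc:
        doc["age_range"] = tuple(doc["age_range"])
    return SimulationSpec(**doc)


def _rng(spec: SimulationSpec, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed), _STREAM[stage]])


def _subject_index(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"S{i:0{width}d}" for i in range(1, n + 1)], name="subject_id")


def simulate_genotypes(spec: SimulationSpec, panel: ScorePanel) -> CohortTable:
    """Draw HWE genotypes for every panel variant; deterministic given the seed."""
    rng = _rng(spec, "genotypes")
    idx = _subject_index(spec.n)
    cols: dict[str, list[str]] = {}
    for rule in panel:
        if rule.is_vntr:
            table = spec.vntr_repeat_freq.get(rule.variant_id)
            if table is None:
                raise SimulationError(f"no repeat-frequency table for VNTR {rule.variant_id}")
            reps = sorted(table)
            probs = np.array([table[r] for r in reps])
            draws = rng.choice(reps, size=(spec.n, 2), p=probs)
            cols[rule.variant_id] = [f"{min(a, b)}/{max(a, b)}" for a, b in draws]
        else:
            if rule.variant_id not in spec.snp_risk_freq:
                raise SimulationError(f"no allele frequency for SNP {rule.variant_id}")
            f = spec.snp_risk_freq[rule.variant_id]
            risk, nonrisk = rule.risk_allele, rule.nonrisk_allele
            draws = rng.random((spec.n, 2)) < f
            cols[rule.variant_id] = [
                "/".join(sorted(risk if hit else nonrisk for hit in pair)) for pair in draws
            ]
    return CohortTable(genotypes=pd.DataFrame(cols, index=idx))


def simulate_dosages(cohort: CohortTable, spec: SimulationSpec, panel: ScorePanel) -> CohortTable:
    """Perturb hard calls into imputation-style dosages, clipped to [0, 2].

    Dosage = true risk-allele count + Normal(0, dosage_noise), clipped; the
    squared correlation with the true counts rises towards 1 as the noise
    shrinks (see :func:`calibrate_dosage_noise` for choosing the noise level to
    hit a target imputation-quality r^2).
    """
    rng = _rng(spec, "dosages")
    points = compute_grs_hardcall(cohort, panel)
    snp_ids = [r.variant_id for r in panel if not r.is_vntr]
    dose = {}
    for vid in snp_ids:
        true = points[vid].to_numpy(dtype=float)
        noisy = true + rng.normal(0.0, spec.dosage_noise, size=len(true))
        dose[vid] = np.clip(noisy, 0.0, 2.0)
    dosages = pd.DataFrame(dose, index=cohort.subjects)
    alleles = {vid: panel[vid].risk_allele for vid in snp_ids}
    return replace(cohort, dosages=dosages, dosage_alleles=alleles)


def calibrate_dosage_noise(risk_freq: float, target_r2: float = 0.8) -> float:
    """Noise SD giving (approximately) a target squared correlation with truth.

    Ignoring clipping, corr^2(count, count + e) = var_count / (var_count +
    sigma_e^2) with var_count = 2pq under HWE, so sigma_e = sqrt(2pq (1 - r2) / r2).
    """
    if not 0.0 < target_r2 <= 1.0:
        raise SimulationError("target r^2 must be in (0, 1]")
    var_count = 2.0 * risk_freq * (1.0 - risk_freq)
    return math.sqrt(var_count * (1.0 - target_r2) / target_r2)


def simulate_covariates(spec: SimulationSpec) -> CohortTable:
    """Age (uniform over the eligible range), sex (0/1), ethnicity, optional PCs."""
    rng = _rng(spec, "covariates")
    idx = _subject_index(spec.n)
    lo, hi = spec.age_range
    cols: dict[str, np.ndarray | list] = {
        "age": rng.uniform(lo, hi, size=spec.n),
        "sex": (rng.random(spec.n) < spec.p_female).astype(int),  # 1 = female
    }
    levels = list(spec.ethnicity_proportions)
    probs = np.array([spec.ethnicity_proportions[lv] for lv in levels])
    cols["ethnicity"] = rng.choice(levels, size=spec.n, p=probs)
    for k in range(1, spec.n_pcs + 1):
        cols[f"PC{k}"] = rng.normal(0.0, 1.0, size=spec.n)
    return CohortTable(covariates=pd.DataFrame(cols, index=idx))


def _covariate_offset(spec: SimulationSpec, covariates: pd.DataFrame) -> np.ndarray:
    offset = np.zeros(len(covariates))
    for name, effect in spec.covariate_effects.items():
        if name not in covariates.columns:
            raise SimulationError(f"covariate effect for absent column {name!r}")
        col = covariates[name]
        if isinstance(effect, Mapping):
            offset += col.map(lambda lv: effect.get(lv, 0.0)).to_numpy(dtype=float)
        else:
            offset += float(effect) * col.to_numpy(dtype=float)
    return offset


def simulate_phenotype(cohort: CohortTable, panel: ScorePanel, spec: SimulationSpec) -> CohortTable:
    """y = intercept + slope * GRS + covariate offsets + Normal(0, noise_sd).

    In ``cesd_like`` mode the result is floored at 0, capped at 60 and rounded
    to integers, mimicking a bounded symptom questionnaire.
    """
    rng = _rng(spec, "phenotype")
    scores = compute_grs_hardcall(cohort, panel)[SCORE_COLUMN].to_numpy(dtype=float)
    y = spec.intercept + spec.true_slope * scores
    if spec.covariate_effects:
        if cohort.covariates is None:
            raise SimulationError("covariate effects specified but cohort has no covariates")
        y = y + _covariate_offset(spec, cohort.covariates)
    y = y + rng.normal(0.0, spec.noise_sd, size=len(scores))
    scale = None
    if spec.phenotype_mode == "cesd_like":
        y = np.clip(np.round(y), 0.0, 60.0)
        scale = "cesd"
    pheno = pd.Series(y, index=cohort.subjects, name="phenotype")
    return replace(cohort, phenotype=pheno, phenotype_scale=scale)


def simulate_cohort(
    spec: SimulationSpec, panel: ScorePanel, with_dosages: bool = False
) -> CohortTable:
    """Full pipeline input: genotypes (+dosages), covariates and phenotype."""
    cohort = simulate_genotypes(spec, panel)
    if with_dosages:
        cohort = simulate_dosages(cohort, spec, panel)
    cov = simulate_covariates(spec)
    cohort = replace(cohort, covariates=cov.covariates)
    return simulate_phenotype(cohort, panel, spec)


def parameter_recovery_experiment(
    spec: SimulationSpec,
    panel: ScorePanel,
    replicates: int,
    covariate_spec=("ethnicity",),
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Repeatedly simulate and refit; summarize slope recovery and calibration.

    Each replicate gets an independent child seed derived from ``spec.seed``.
    Returns a summary (mean fitted slope, its Monte-Carlo SE, empirical SD,
    95% CI coverage of the true slope, rejection rate at ``alpha``) and the
    per-replicate fit table.
    """
    if replicates < 2:
        raise SimulationError("at least two replicates are required")
    child_seeds = np.random.SeedSequence(int(spec.seed)).generate_state(replicates)
    rows = []
    for rep, child in enumerate(child_seeds):
        rep_spec = replace(spec, seed=int(child))
        cohort = simulate_cohort(rep_spec, panel)
        fit = grs_association(cohort, panel, covariate_spec=covariate_spec)
        term = fit.term(GRS_TERM)
        rows.append({
            "replicate": rep,
            "beta": term["beta"],
            "se": term["se"],
            "p": term["p"],
            "ci_low": term["ci_low"],
            "ci_high": term["ci_high"],
        })
    table = pd.DataFrame(rows)
    covered = (table["ci_low"] <= spec.true_slope) & (spec.true_slope <= table["ci_high"])
    summary = {
        "true_slope": spec.true_slope,
        "replicates": replicates,
        "mean_beta": float(table["beta"].mean()),
        "sd_beta": float(table["beta"].std(ddof=1)),
        "mc_se": float(table["beta"].std(ddof=1) / math.sqrt(replicates)),
        "ci_coverage": float(covered.mean()),
        "rejection_rate": float((table["p"] < alpha).mean()),
    }
    return summary, table
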