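"""Per-variant genotype QC: counts, allele frequency, Hardy-Weinberg chi-square.

The Hardy-Weinberg test is the uncorrected 1-df Pearson chi-square against the
expected proportions (p^2, 2pq, q^2) at the allele frequency estimated from the
same counts. No continuity correction is applied. A monomorphic variant is
flagged untestable instead of producing a NaN statistic.

The multi-allelic DAT VNTR can optionally be collapsed into the two scoring
classes (repeats <= 9 vs >= 10) and tested as a biallelic system; the report
labels such rows as collapsed tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .panel import ScorePanel, VariantRule, code_genotype


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts keyed to risk-allele copy number (2 / 1 / 0)."""

    n_hom_risk: int
    n_het: int
    n_hom_nonrisk: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_nonrisk) < 0:
            raise QCError("genotype counts must be non-negative")
        if self.n_total < 1:
            raise QCError("genotype counts are empty")

    @property
    def n_total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_nonrisk


@dataclass(frozen=True)
class HWEResult:
    chi_square: float
    p_value: float
    risk_allele_freq: float
    expected: tuple[float, float, float]  # (hom risk, het, hom non-risk)
    testable: bool = True
    collapsed: bool = False
    df: int = 1


def tabulate_genotypes(
    cohort: CohortTable, rule: VariantRule, collapse_vntr: bool = False
) -> GenotypeCounts:
    """Count genotypes by risk-allele copy number for one variant.

    A VNTR is multi-allelic, so it must be collapsed into its two scoring
    classes (``collapse_vntr=True``) before a biallelic tabulation makes sense;
    each allele with repeats <= 9 counts as a risk allele.
    """
    if rule.is_vntr and not collapse_vntr:
        raise QCError(
            f"{rule.variant_id}: VNTR genotypes must be collapsed before tabulation"
        )
    if cohort.genotypes is None or rule.variant_id not in cohort.genotypes.columns:
        raise QCError(f"variant {rule.variant_id!r} absent from cohort genotypes")
    calls = cohort.genotypes[rule.variant_id].dropna()
    if calls.empty:
        raise QCError(f"{rule.variant_id}: no called genotypes")
    tallies = [0, 0, 0]  # index = risk-allele copies
    for g in calls:
        tallies[code_genotype(rule, g)] += 1
    return GenotypeCounts(n_hom_risk=tallies[2], n_het=tallies[1], n_hom_nonrisk=tallies[0])


def allele_frequency(counts: GenotypeCounts) -> float:
    """Sample risk-allele frequency (2*hom + het) / (2*n)."""
    return (2 * counts.n_hom_risk + counts.n_het) / (2 * counts.n_total)


def hwe_chi_square(counts: GenotypeCounts, collapsed: bool = False) -> HWEResult:
    """Uncorrected Pearson chi-square test for Hardy-Weinberg proportions.

    Expected counts are (np^2, 2npq, nq^2) at the estimated frequency; the
    statistic has 1 degree of freedom (one frequency estimated from the data).
    The statistic is invariant to which homozygote class is labelled "risk".
    """
    n = counts.n_total
    p = allele_frequency(counts)
    if p == 0.0 or p == 1.0:
        return HWEResult(
            chi_square=0.0, p_value=1.0, risk_allele_freq=p,
            expected=(n * p, 0.0, n * (1 - p)), testable=False, collapsed=collapsed,
        )
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_hom_risk, counts.n_het, counts.n_hom_nonrisk)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(
        chi_square=float(chi2), p_value=p_value, risk_allele_freq=p,
        expected=expected, collapsed=collapsed,
    )


def qc_report(cohort: CohortTable, panel: ScorePanel, collapse_vntr: bool = True) -> pd.DataFrame:
    """One row per panel variant: counts, frequency, chi-square, p, flags."""
    rows = []
    for rule in panel:
        counts = tabulate_genotypes(cohort, rule, collapse_vntr=rule.is_vntr)
        if rule.is_vntr and not collapse_vntr:
            continue
        res = hwe_chi_square(counts, collapsed=rule.is_vntr)
        rows.append({
            "variant_id": rule.variant_id,
            "gene": rule.gene,
            "n_hom_risk": counts.n_hom_risk,
            "n_het": counts.n_het,
            "n_hom_nonrisk": counts.n_hom_nonrisk,
            "risk_allele_freq": res.risk_allele_freq,
            "chi_square": res.chi_square,
            "p_value": res.p_value,
            "testable": res.testable,
            "collapsed": res.collapsed,
        })
    return pd.DataFrame(rows)
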