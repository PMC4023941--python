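"""Genetic risk score computation and panel derivations.

The score is strictly unweighted: each variant contributes its risk-allele
count (hard call, integer 0-2) or imputed risk-allele dosage (real in [0, 2]),
and the subject's score is the plain sum over the panel. Scores of panels of
different sizes live on different ranges and are never rescaled, so regression
coefficients are not comparable across panels.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortTable
from .panel import MissingGenotypeError, PanelError, ScorePanel, code_genotype

SCORE_COLUMN = "score"


class ScoringError(ValueError):
    pass


def _points_frame(per_variant: dict[str, pd.Series], panel: ScorePanel) -> pd.DataFrame:
    df = pd.DataFrame(per_variant)
    df[SCORE_COLUMN] = df[list(panel.variant_ids)].sum(axis=1)
    df.attrs["panel"] = panel.name
    return df


def compute_grs_hardcall(cohort: CohortTable, panel: ScorePanel) -> pd.DataFrame:
    """Integer scores from called genotypes; one row per subject.

    Returns a frame with one points column per panel variant plus ``score``.
    Missing genotypes are a contract violation here — run the complete-case
    filter first.
    """
    if cohort.genotypes is None:
        raise ScoringError("cohort has no genotype table")
    per_variant: dict[str, pd.Series] = {}
    for rule in panel:
        if rule.variant_id not in cohort.genotypes.columns:
            raise ScoringError(f"panel variant {rule.variant_id!r} absent from cohort")
        calls = cohort.genotypes[rule.variant_id]
        if calls.isna().any():
            missing = list(calls.index[calls.isna()][:5])
            raise MissingGenotypeError(
                f"{rule.variant_id}: missing genotypes reached scoring "
                f"(subjects {missing}); apply complete_case_filter first"
            )
        per_variant[rule.variant_id] = calls.map(lambda g, r=rule: code_genotype(r, g))
    return _points_frame(per_variant, panel)


def compute_grs_dosage(cohort: CohortTable, panel: ScorePanel) -> pd.DataFrame:
    """Real-valued scores from risk-allele-oriented imputed dosages."""
    if cohort.dosages is None:
        raise ScoringError("cohort has no dosage table")
    per_variant: dict[str, pd.Series] = {}
    for rule in panel:
        if rule.is_vntr:
            raise ScoringError(f"{rule.variant_id}: VNTRs have no dosage representation")
        if rule.variant_id not in cohort.dosages.columns:
            raise ScoringError(f"panel variant {rule.variant_id!r} absent from dosages")
        vals = cohort.dosages[rule.variant_id]
        if vals.isna().any():
            missing = list(vals.index[vals.isna()][:5])
            raise ScoringError(
                f"{rule.variant_id}: missing dosages reached scoring (subjects {missing})"
            )
        per_variant[rule.variant_id] = vals.astype(float)
    return _points_frame(per_variant, panel)


def compute_grs_mixed(cohort: CohortTable, panel: ScorePanel) -> pd.DataFrame:
    """Scores from whichever representation each variant has.

    A variant contributes integer points when the cohort carries its genotypes
    and dosage otherwise — the situation of a panel with one imputed SNP among
    genotyped ones, where observed score maxima can be fractional.
    """
    per_variant: dict[str, pd.Series] = {}
    for rule in panel:
        has_geno = (
            cohort.genotypes is not None
            and rule.variant_id in cohort.genotypes.columns
            and cohort.genotypes[rule.variant_id].notna().all()
        )
        if has_geno:
            calls = cohort.genotypes[rule.variant_id]
            per_variant[rule.variant_id] = calls.map(lambda g, r=rule: code_genotype(r, g))
        elif cohort.dosages is not None and rule.variant_id in cohort.dosages.columns:
            vals = cohort.dosages[rule.variant_id]
            if vals.isna().any():
                raise ScoringError(f"{rule.variant_id}: missing dosages reached scoring")
            per_variant[rule.variant_id] = vals.astype(float)
        else:
            raise ScoringError(
                f"panel variant {rule.variant_id!r} has neither complete genotypes nor dosages"
            )
    return _points_frame(per_variant, panel)


def compute_grs(cohort: CohortTable, panel: ScorePanel, mode: str = "hardcall") -> pd.DataFrame:
    """Dispatch on ``mode``: ``hardcall``, ``dosage`` or ``mixed``."""
    try:
        fn = {"hardcall": compute_grs_hardcall,
              "dosage": compute_grs_dosage,
              "mixed": compute_grs_mixed}[mode]
    except KeyError:
        raise ScoringError(f"unknown scoring mode {mode!r}") from None
    return fn(cohort, panel)


def subset_panel(panel: ScorePanel, variant_ids, name: str | None = None) -> ScorePanel:
    """Restrict a panel to the given variants, preserving panel order."""
    wanted = list(variant_ids)
    if not wanted:
        raise PanelError("subset must name at least one variant")
    unknown = [v for v in wanted if v not in panel]
    if unknown:
        raise PanelError(f"variants not in panel {panel.name!r}: {unknown}")
    rules = tuple(r for r in panel if r.variant_id in wanted)
    return ScorePanel(rules=rules, name=name or f"{panel.name}_subset{len(rules)}")


def leave_one_out_panels(panel: ScorePanel) -> list[tuple[str, ScorePanel]]:
    """All size V-1 sub-panels, one per omitted variant.

    Used as a sensitivity analysis: the full score equals any sub-panel score
    plus the omitted variant's points, so an association that survives every
    omission is not driven by a single variant.
    """
    if len(panel) < 2:
        raise PanelError("leave-one-out requires a panel of at least two variants")
    out = []
    for rule in panel:
        rest = tuple(r for r in panel if r.variant_id != rule.variant_id)
        out.append((rule.variant_id,
                    ScorePanel(rules=rest, name=f"{panel.name}_minus_{rule.variant_id}")))
    return out
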