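"""Cohort tables: genotype/dosage/phenotype I/O and complete-case filtering.

All tables are tab-separated UTF-8 text with a header row and a ``subject_id``
key column. Genotypes are unphased allele-pair strings (``A/G``; missing is
``./.``); dosages are imputed risk-allele expected counts in [0, 2] (missing is
an empty cell). No imputation is ever performed here — subjects with missing
required fields are dropped by an explicit, audited complete-case filter.

Dosage orientation is resolved at read time: a sidecar metadata table names the
allele each dosage column counts, and columns counting the non-risk allele are
flipped (d -> 2 - d) so every stored dosage counts the risk allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING_GENOTYPE, PanelError, ScorePanel, normalize_genotype

logger = logging.getLogger(__name__)

DOSAGE_TOLERANCE = 1e-6

#: Declared phenotype scales and their admissible ranges (None = unbounded).
PHENOTYPE_SCALES: dict[str, tuple[float, float] | None] = {
    "cesd": (0.0, 60.0),   # 20-item depression scale, past week
    "hamd": (0.0, 52.0),   # 17-item clinician-rated depression scale
    "poms": None,          # depression/dejection subscale t-score
}


class CohortError(ValueError):
    """Malformed cohort table or inconsistent metadata."""


@dataclass
class CohortTable:
    """Subjects x (genotypes, dosages, phenotype, covariates), any subset present.

    All component frames are indexed by ``subject_id``; components share the
    same index once joined. ``dosage_alleles`` records, per dosage column, the
    counted allele after orientation resolution (always the risk allele when
    read through :func:`read_dosage_table`).
    """

    genotypes: pd.DataFrame | None = None
    dosages: pd.DataFrame | None = None
    dosage_alleles: dict[str, str] = field(default_factory=dict)
    phenotype: pd.Series | None = None
    phenotype_scale: str | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.phenotype is not None and self.phenotype_scale is not None:
            bounds = PHENOTYPE_SCALES.get(self.phenotype_scale)
            if bounds is not None:
                lo, hi = bounds
                vals = self.phenotype.dropna()
                bad = vals[(vals < lo) | (vals > hi)]
                if len(bad):
                    raise CohortError(
                        f"phenotype values outside the {self.phenotype_scale} "
                        f"range [{lo}, {hi}]: subjects {list(bad.index[:5])}"
                    )

    @property
    def subjects(self) -> pd.Index:
        for part in (self.genotypes, self.dosages, self.covariates):
            if part is not None:
                return part.index
        if self.phenotype is not None:
            return self.phenotype.index
        raise CohortError("empty cohort: no component tables")

    @property
    def n(self) -> int:
        return len(self.subjects)

    def join(self, other: "CohortTable") -> "CohortTable":
        """Merge components of two cohorts on the intersection of subjects."""
        common = self.subjects.intersection(other.subjects)
        dropped = len(self.subjects.union(other.subjects)) - len(common)
        if dropped:
            logger.info("join: %d subjects absent from one side dropped", dropped)

        def pick(a, b):
            if a is None:
                return None if b is None else b.loc[common]
            if b is not None:
                raise CohortError("both cohorts define the same component")
            return a.loc[common]

        return CohortTable(
            genotypes=pick(self.genotypes, other.genotypes),
            dosages=pick(self.dosages, other.dosages),
            dosage_alleles={**self.dosage_alleles, **other.dosage_alleles},
            phenotype=pick(self.phenotype, other.phenotype),
            phenotype_scale=self.phenotype_scale or other.phenotype_scale,
            covariates=pick(self.covariates, other.covariates),
        )

    def subset(self, subjects: pd.Index) -> "CohortTable":
        def take(part):
            return None if part is None else part.loc[subjects]

        return replace(
            self,
            genotypes=take(self.genotypes),
            dosages=take(self.dosages),
            phenotype=take(self.phenotype),
            covariates=take(self.covariates),
        )


@dataclass
class ExclusionReport:
    """Audit record of a complete-case filter pass.

    ``stage_excluded`` gives, in filter order, how many subjects each stage
    removed (variants first, then phenotype/covariates); ``field_missing``
    counts missing values per required field over the input table.
    """

    n_input: int
    n_excluded: int
    n_retained: int
    stage_excluded: dict[str, int] = field(default_factory=dict)
    field_missing: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise CohortError("exclusion accounting does not balance")

    @property
    def percent_excluded(self) -> float:
        """Share of input subjects excluded, as a percentage rounded to 2 dp."""
        return round(100.0 * self.n_excluded / self.n_input, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_input", self.n_input),
            ("n_excluded", self.n_excluded),
            ("n_retained", self.n_retained),
            ("percent_excluded", self.percent_excluded),
        ]
        rows += [(f"excluded_at_{k}", v) for k, v in self.stage_excluded.items()]
        rows += [(f"missing_{k}", v) for k, v in self.field_missing.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if df.columns[0] != "subject_id":
        raise CohortError(f"{path}: first column must be 'subject_id', got {df.columns[0]!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"{path}: duplicate subject ids {dupes[:5]}")
    return df.set_index("subject_id")


def read_genotype_table(path, panel: ScorePanel | None = None) -> CohortTable:
    """Read a subject x variant table of allele-pair strings.

    Allele pairs are order-normalized (``G/A`` -> ``A/G``) and aliases resolved
    against the panel when one is supplied; ``./.`` is kept as missing. Columns
    for variants not in the panel are retained but ignored by scoring.
    """
    df = _read_tsv(path)
    if panel is not None:
        for col in df.columns:
            if col not in panel:
                logger.info("%s: column %r not in panel %r; ignored by scoring", path, col, panel.name)
                continue
            rule = panel[col]
            df[col] = [
                normalize_genotype(rule, g) if not pd.isna(g) else g for g in df[col]
            ]
    df = df.replace(MISSING_GENOTYPE, np.nan)
    return CohortTable(genotypes=df)


def write_genotype_table(cohort: CohortTable, path) -> None:
    df = cohort.genotypes.fillna(MISSING_GENOTYPE)
    df.to_csv(path, sep="\t", index_label="subject_id")


def read_dosage_table(path, panel: ScorePanel, metadata: Mapping[str, str] | str) -> CohortTable:
    """Read imputed allele dosages and orient every column to the risk allele.

    ``metadata`` names the counted allele per variant column — either a mapping
    or a path to a two-column TSV (``variant_id``, ``counted_allele``). A column
    counting the non-risk allele is flipped ``d -> 2 - d``. Values outside
    [0, 2] beyond a 1e-6 tolerance are rejected.
    """
    if not isinstance(metadata, Mapping):
        meta_df = pd.read_csv(metadata, sep="\t", dtype=str)
        metadata = dict(zip(meta_df["variant_id"], meta_df["counted_allele"]))
    raw = _read_tsv(path)
    df = raw.apply(pd.to_numeric)
    oriented: dict[str, str] = {}
    for col in df.columns:
        if col not in metadata:
            raise CohortError(f"{path}: no counted-allele metadata for {col!r}")
        vals = df[col]
        bad = vals[(vals < -DOSAGE_TOLERANCE) | (vals > 2 + DOSAGE_TOLERANCE)]
        if len(bad):
            raise CohortError(
                f"{path}: dosage outside [0, 2] for {col!r}, subjects {list(bad.index[:5])}"
            )
        df[col] = vals.clip(0.0, 2.0)
        rule = panel[col] if col in panel else None
        counted = metadata[col]
        if rule is None:
            oriented[col] = counted
            continue
        if rule.is_vntr:
            raise CohortError(f"{col}: dosages are not defined for VNTR variants")
        counted_nuc = rule.resolve_allele(counted)
        if counted_nuc == rule.risk_allele:
            oriented[col] = counted_nuc
        else:
            df[col] = 2.0 - df[col]
            oriented[col] = rule.risk_allele
            logger.info("%s: flipped %s dosages from %s to risk allele %s",
                        path, col, counted_nuc, rule.risk_allele)
    return CohortTable(dosages=df, dosage_alleles=oriented)


def write_dosage_table(cohort: CohortTable, path, metadata_path=None) -> None:
    cohort.dosages.to_csv(path, sep="\t", index_label="subject_id", na_rep="")
    if metadata_path is not None:
        pd.DataFrame(
            {"variant_id": list(cohort.dosage_alleles),
             "counted_allele": list(cohort.dosage_alleles.values())}
        ).to_csv(metadata_path, sep="\t", index=False)


def read_phenotype_table(path, phenotype: str, scale: str | None = None) -> CohortTable:
    """Read a phenotype/covariate table; every non-phenotype column is a covariate."""
    df = _read_tsv(path)
    if phenotype not in df.columns:
        raise CohortError(f"{path}: phenotype column {phenotype!r} not found")
    pheno = pd.to_numeric(df[phenotype])
    covs = df.drop(columns=[phenotype])
    for col in covs.columns:
        try:
            covs[col] = pd.to_numeric(covs[col])
        except (ValueError, TypeError):
            pass  # categorical covariate stays as strings
    return CohortTable(phenotype=pheno, phenotype_scale=scale,
                       covariates=covs if len(covs.columns) else None)


def write_phenotype_table(cohort: CohortTable, path) -> None:
    df = pd.DataFrame({cohort.phenotype.name or "phenotype": cohort.phenotype})
    if cohort.covariates is not None:
        df = pd.concat([df, cohort.covariates], axis=1)
    df.to_csv(path, sep="\t", index_label="subject_id", na_rep="")


def read_vcf_biallelic(path, panel: ScorePanel) -> CohortTable:
    """Read GT calls for the panel's SNPs from a VCF.

    Only biallelic SNP records whose ID matches a panel SNP are used; GT indices
    are translated to allele pairs against REF/ALT. VNTR variants are never read
    from VCF. Raises if a panel SNP is absent or a call is not diploid.
    """
    from cyvcf2 import VCF

    snp_ids = [r.variant_id for r in panel if not r.is_vntr]
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, list] = {}
    for rec in vcf:
        if rec.ID not in snp_ids:
            continue
        if len(rec.ALT) != 1:
            raise CohortError(f"{rec.ID}: multi-allelic records are not supported")
        alleles = [rec.REF, rec.ALT[0]]
        col = []
        for gt in rec.genotypes:  # [a0, a1, phased]
            if len(gt) != 3:
                raise CohortError(f"{rec.ID}: non-diploid genotype {gt}")
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col.append(np.nan)
            else:
                rule = panel[rec.ID]
                col.append(normalize_genotype(rule, f"{alleles[a0]}/{alleles[a1]}"))
        calls[rec.ID] = col
    absent = [v for v in snp_ids if v not in calls]
    if absent:
        raise CohortError(f"panel SNPs absent from VCF: {absent}")
    df = pd.DataFrame(calls, index=pd.Index(samples, name="subject_id"))
    return CohortTable(genotypes=df)


def _resolve_required(cohort: CohortTable, required_fields: Sequence[str]):
    """Split required field names into variant fields and phenotype/covariate fields."""
    variant_fields, other_fields = [], []
    for name in required_fields:
        if cohort.genotypes is not None and name in cohort.genotypes.columns:
            variant_fields.append(name)
        elif cohort.dosages is not None and name in cohort.dosages.columns:
            variant_fields.append(name)
        elif name == "phenotype" and cohort.phenotype is not None:
            other_fields.append(name)
        elif cohort.covariates is not None and name in cohort.covariates.columns:
            other_fields.append(name)
        else:
            raise CohortError(f"required field {name!r} not present in cohort")
    return variant_fields, other_fields


def _field_series(cohort: CohortTable, name: str) -> pd.Series:
    if cohort.genotypes is not None and name in cohort.genotypes.columns:
        return cohort.genotypes[name]
    if cohort.dosages is not None and name in cohort.dosages.columns:
        return cohort.dosages[name]
    if name == "phenotype":
        return cohort.phenotype
    return cohort.covariates[name]


def complete_case_filter(
    cohort: CohortTable, required_fields: Iterable[str]
) -> tuple[CohortTable, ExclusionReport]:
    """Drop subjects with any missing value among the required fields.

    Filtering is staged — genotype/dosage completeness first, then
    phenotype/covariates — and each stage's exclusions are reported, so the
    headline "x% of the sample excluded" figure is auditable. Idempotent.
    """
    required = list(required_fields)
    variant_fields, other_fields = _resolve_required(cohort, required)
    n_input = cohort.n
    field_missing = {
        name: int(_field_series(cohort, name).isna().sum()) for name in required
    }

    keep = cohort.subjects
    stage_excluded: dict[str, int] = {}
    for stage, names in (("variants", variant_fields), ("phenotype_covariates", other_fields)):
        if not names:
            continue
        mask = pd.Series(True, index=keep)
        for name in names:
            mask &= _field_series(cohort, name).loc[keep].notna()
        stage_excluded[stage] = int((~mask).sum())
        keep = keep[mask.to_numpy()]

    if len(keep) == 0:
        worst = max(field_missing, key=field_missing.get)
        raise CohortError(
            f"complete-case filter retained no subjects; most-missing field is "
            f"{worst!r} ({field_missing[worst]}/{n_input} missing)"
        )
    report = ExclusionReport(
        n_input=n_input,
        n_excluded=n_input - len(keep),
        n_retained=len(keep),
        stage_excluded=stage_excluded,
        field_missing=field_missing,
    )
    return cohort.subset(keep), report
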