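"""Score-panel definitions: which variants are scored and how genotypes map to points.

A panel is an ordered collection of variant rules. Each rule describes one
polymorphism and the allele direction that increases dopamine neurotransmission:
for a SNP the rule names the risk (dopamine-increasing) allele and a subject
earns one point per copy; for the DAT 3'-UTR 40-bp VNTR the rule is a
repeat-count predicate — each allele with a repeat count of at most 9 earns one
point, alleles with 10 or more repeats earn none. Per-variant points are always
in {0, 1, 2}, so a panel of V variants yields scores in [0, 2V].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import yaml

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in text tables.
MISSING_GENOTYPE = "./."

#: Repeat counts actually observed for the DAT VNTR; anything else is coded by
#: the same <=9 predicate but flagged, because the rule is an extrapolation there.
EXPECTED_REPEATS = frozenset(range(6, 12))

_PANEL_KEYS = {"name", "variants"}
_VARIANT_KEYS = {"variant_id", "gene", "class", "risk_allele", "vntr_risk_max_repeat", "labels"}


class PanelError(ValueError):
    """Invalid panel configuration or genotype token."""


class MissingGenotypeError(ValueError):
    """A genotype is the missing sentinel where a call is required."""


@dataclass(frozen=True)
class VariantRule:
    """Coding rule for one variant.

    Parameters
    ----------
    variant_id:
        dbSNP identifier, e.g. ``"rs4680"``.
    gene:
        Gene label for reporting (``"COMT"``, ``"DRD2/ANKK1"``, ...).
    variant_class:
        ``"snp"`` or ``"vntr"``.
    risk_allele:
        For SNPs, the nucleotide whose copies are counted (the
        dopamine-increasing allele). ``None`` for VNTRs.
    vntr_risk_max_repeat:
        For VNTRs, the largest repeat count still counted as a risk allele
        (9 for the DAT VNTR: small repeats score 1, large repeats score 0).
    allele_labels:
        Presentation aliases, nucleotide -> amino-acid/label
        (e.g. ``{"A": "Met", "G": "Val"}``). Aliases are accepted on input.
    """

    variant_id: str
    gene: str
    variant_class: str
    risk_allele: str | None = None
    vntr_risk_max_repeat: int | None = None
    allele_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant_class not in ("snp", "vntr"):
            raise PanelError(f"{self.variant_id}: unknown variant class {self.variant_class!r}")
        if self.variant_class == "snp":
            if not self.risk_allele:
                raise PanelError(f"{self.variant_id}: snp rule requires a risk allele")
            if self.vntr_risk_max_repeat is not None:
                raise PanelError(f"{self.variant_id}: snp rule must not carry a VNTR predicate")
        else:
            if self.vntr_risk_max_repeat is None:
                raise PanelError(f"{self.variant_id}: vntr rule requires a repeat predicate")
            if self.risk_allele is not None:
                raise PanelError(f"{self.variant_id}: vntr rule must not carry a risk allele")

    @property
    def is_vntr(self) -> bool:
        return self.variant_class == "vntr"

    @property
    def nonrisk_allele(self) -> str:
        """The non-counted nucleotide of a biallelic SNP (from allele_labels)."""
        if self.is_vntr:
            raise PanelError(f"{self.variant_id}: VNTR has no single non-risk allele")
        others = [a for a in self.allele_labels if a != self.risk_allele]
        if len(others) != 1:
            raise PanelError(
                f"{self.variant_id}: allele_labels must name exactly one non-risk allele"
            )
        return others[0]

    def resolve_allele(self, token: str) -> str:
        """Map a nucleotide or amino-acid alias to the canonical nucleotide."""
        if token in self.allele_labels:
            return token
        for nuc, label in self.allele_labels.items():
            if token == label:
                return nuc
        raise PanelError(f"{self.variant_id}: unknown allele token {token!r}")

    def label(self, allele: str) -> str:
        return self.allele_labels.get(allele, allele)


@dataclass(frozen=True)
class ScorePanel:
    """Ordered, validated collection of variant rules."""

    rules: tuple[VariantRule, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.rules:
            raise PanelError("panel must contain at least one variant")
        ids = [r.variant_id for r in self.rules]
        dupes = {v for v in ids if ids.count(v) > 1}
        if dupes:
            raise PanelError(f"duplicate variant ids in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[VariantRule]:
        return iter(self.rules)

    def __getitem__(self, variant_id: str) -> VariantRule:
        for rule in self.rules:
            if rule.variant_id == variant_id:
                return rule
        raise KeyError(variant_id)

    def __contains__(self, variant_id: str) -> bool:
        return any(r.variant_id == variant_id for r in self.rules)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(r.variant_id for r in self.rules)

    @property
    def max_score(self) -> int:
        """Highest attainable score: two risk alleles at every variant."""
        return 2 * len(self.rules)


def _parse_pair(genotype: str | tuple) -> tuple[str, str]:
    if isinstance(genotype, tuple):
        a, b = genotype
        return str(a), str(b)
    parts = str(genotype).split("/")
    if len(parts) != 2:
        raise PanelError(f"malformed genotype {genotype!r}; expected 'a/b'")
    return parts[0].strip(), parts[1].strip()


def code_snp_genotype(rule: VariantRule, genotype: str | tuple) -> int:
    """Count risk-allele copies (0, 1 or 2) in an unordered allele pair.

    Amino-acid aliases are resolved through the rule's ``allele_labels``
    (``"Met/Val"`` == ``"A/G"`` for rs4680). A missing genotype raises
    :class:`MissingGenotypeError` rather than silently scoring 0.
    """
    a, b = _parse_pair(genotype)
    if a == "." or b == ".":
        raise MissingGenotypeError(f"{rule.variant_id}: genotype is missing")
    if rule.is_vntr:
        raise PanelError(f"{rule.variant_id}: not a SNP rule")
    alleles = (rule.resolve_allele(a), rule.resolve_allele(b))
    return sum(1 for al in alleles if al == rule.risk_allele)


def code_vntr_genotype(rule: VariantRule, genotype: str | tuple) -> int:
    """Score a repeat-count pair: one point per allele with repeats <= the cutoff.

    With the DAT cutoff of 9, 10/10 -> 0, 9/10 -> 1, 9/9 -> 2; the rare 11
    repeat behaves like 10 (0 points) and the rare 6/7/8 repeats like 9
    (1 point each). Repeat counts outside the observed 6-11 range are coded by
    the same predicate but logged, since the rule is an extrapolation there.
    """
    a, b = _parse_pair(genotype)
    if a == "." or b == ".":
        raise MissingGenotypeError(f"{rule.variant_id}: genotype is missing")
    if not rule.is_vntr:
        raise PanelError(f"{rule.variant_id}: not a VNTR rule")
    points = 0
    for tok in (a, b):
        try:
            rep = int(tok)
        except ValueError as exc:
            raise PanelError(f"{rule.variant_id}: repeat count {tok!r} is not an integer") from exc
        if rep <= 0:
            raise PanelError(f"{rule.variant_id}: repeat count must be positive, got {rep}")
        if rep not in EXPECTED_REPEATS:
            logger.warning(
                "%s: repeat count %d outside the observed 6-11 range; "
                "coded by the <=%d rule by extrapolation",
                rule.variant_id, rep, rule.vntr_risk_max_repeat,
            )
        if rep <= rule.vntr_risk_max_repeat:
            points += 1
    return points


def code_genotype(rule: VariantRule, genotype: str | tuple) -> int:
    """Dispatch to the SNP or VNTR coder according to the rule's class."""
    if rule.is_vntr:
        return code_vntr_genotype(rule, genotype)
    return code_snp_genotype(rule, genotype)


def normalize_genotype(rule: VariantRule, genotype: str) -> str:
    """Canonical genotype string: aliases resolved, alleles sorted, '/'-joined."""
    a, b = _parse_pair(genotype)
    if a == "." or b == ".":
        return MISSING_GENOTYPE
    if rule.is_vntr:
        reps = sorted(int(x) for x in (a, b))
        return f"{reps[0]}/{reps[1]}"
    alleles = sorted(rule.resolve_allele(x) for x in (a, b))
    return f"{alleles[0]}/{alleles[1]}"


def _rule_from_mapping(entry: Mapping) -> VariantRule:
    unknown = set(entry) - _VARIANT_KEYS
    if unknown:
        raise PanelError(f"unknown keys in variant entry: {sorted(unknown)}")
    for key in ("variant_id", "gene", "class"):
        if key not in entry:
            raise PanelError(f"variant entry missing required key {key!r}: {entry}")
    return VariantRule(
        variant_id=str(entry["variant_id"]),
        gene=str(entry["gene"]),
        variant_class=str(entry["class"]),
        risk_allele=entry.get("risk_allele"),
        vntr_risk_max_repeat=entry.get("vntr_risk_max_repeat"),
        allele_labels=dict(entry.get("labels") or {}),
    )


def panel_from_mapping(doc: Mapping) -> ScorePanel:
    """Build a panel from an already-parsed configuration mapping."""
    unknown = set(doc) - _PANEL_KEYS
    if unknown:
        raise PanelError(f"unknown top-level keys in panel document: {sorted(unknown)}")
    variants = doc.get("variants")
    if not variants:
        raise PanelError("panel document lists no variants")
    rules = tuple(_rule_from_mapping(v) for v in variants)
    return ScorePanel(rules=rules, name=str(doc.get("name", "panel")))


def load_panel(path) -> ScorePanel:
    """Load and validate a YAML panel file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise PanelError(f"panel file {path} is not a key-value document")
    return panel_from_mapping(doc)


def builtin_panel(name: str) -> ScorePanel:
    """Load one of the shipped panels: ``hs5``, ``stard3`` or ``gsp4``."""
    ref = resources.files("dopagrs.panels").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise PanelError(f"no builtin panel named {name!r}") from exc
    return panel_from_mapping(yaml.safe_load(text))
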