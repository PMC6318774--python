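"""Turn classified variants into categorized findings and gate their return.

Categories: actionable (P/LP or guideline-backed risk allele in a
moderately-to-highly penetrant disease gene with a risk-supporting
genotype), carrier (heterozygous P/LP in an autosomal recessive gene),
nonactionable risk (P/LP in genes conferring risk without effective
intervention, e.g. GBA heterozygotes and Parkinson disease), APOE
(e4-containing diplotypes), and pharmacogenetic (non-reference genotypes
at panel rsIDs). A variant can carry both carrier and nonactionable-risk
categories; actionable and carrier are mutually exclusive.

Return logic follows the participant's consent: nothing for opt-outs,
only actionable findings for actionable-only consent, everything
medically relevant otherwise — except APOE status, which is only
disclosed on specific request, and VUS, which are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core_io import SiteGenotypes
from .models import (
    Category,
    ClassificationLabel,
    Consent,
    Finding,
    GeneRecord,
    Participant,
    PGxPanel,
    REPORTABLE_LABELS,
    VariantRecord,
    Zygosity,
)

APOE_SNP_1 = "rs429358"
APOE_SNP_2 = "rs7412"

PLP_LABELS = frozenset(
    {ClassificationLabel.PATHOGENIC, ClassificationLabel.LIKELY_PATHOGENIC}
)


@dataclass
class ClassifiedVariant:
    """A curated variant with its final classification."""

    variant: VariantRecord
    classification: ClassificationLabel
    triggers: tuple[str, ...] = ()


def determine_actionability(
    variant: VariantRecord,
    classification: ClassificationLabel,
    gene: GeneRecord,
    cohort_variants_for_participant: Sequence[ClassifiedVariant] = (),
) -> bool:
    """Decide whether a classified variant is medically actionable.

    Requires a reportable classification, a gene with an actionable
    disease association of at least moderate penetrance, and a genotype
    that supports disease risk: heterozygous for a dominant gene,
    homozygous (or presumed compound heterozygous) for a recessive gene,
    heterozygous in a gene whose heterozygotes carry guideline-managed
    risk (the MUTYH pattern), or a risk-allele classification backed by
    management guidelines.
    """
    if classification not in REPORTABLE_LABELS:
        return False
    if not gene.actionable_disease:
        return False
    if gene.penetrance_class not in ("high", "moderate"):
        return False
    if classification is ClassificationLabel.RISK_ALLELE:
        return True
    zyg = variant.zygosity
    if zyg is Zygosity.HET and "AD" in gene.inheritance:
        return True
    if zyg is Zygosity.HOM_ALT and "AR" in gene.inheritance:
        return True
    if zyg is Zygosity.HET and gene.het_risk_actionable:
        return True
    if zyg is Zygosity.HET and "AR" in gene.inheritance:
        # presumed compound heterozygote: a second het P/LP variant in the
        # same gene for the same participant (exomes are unphased)
        n_het_plp = sum(
            1
            for cv in cohort_variants_for_participant
            if cv.variant.annotation.gene_symbol == gene.symbol
            and cv.variant.zygosity is Zygosity.HET
            and cv.classification in PLP_LABELS
        )
        if n_het_plp >= 2:
            return True
    return False


def detect_carrier(
    variant: VariantRecord,
    classification: ClassificationLabel,
    gene: GeneRecord,
    is_actionable: bool = False,
) -> bool:
    """A heterozygous P/LP variant in an autosomal recessive gene makes the
    participant a carrier, unless the same variant already counts as
    actionable for them."""
    return (
        classification in PLP_LABELS
        and "AR" in gene.inheritance
        and variant.zygosity is Zygosity.HET
        and not is_actionable
    )


def flag_nonactionable_risk(
    variant: VariantRecord,
    classification: ClassificationLabel,
    gene: GeneRecord,
) -> bool:
    """P/LP variants in genes conferring disease risk with no effective
    intervention (e.g. heterozygous GBA and Parkinson disease)."""
    return classification in PLP_LABELS and bool(gene.nonactionable_risk_disease)


def call_apoe(
    gt_rs429358: Optional[tuple[str, str]],
    gt_rs7412: Optional[tuple[str, str]],
) -> Optional[tuple[str, str]]:
    """Call the APOE diplotype from the two defining SNPs.

    Haplotype table: rs429358-C/rs7412-C is e4, T/C is e3, T/T is e2. With
    unphased data the double-heterozygote is ambiguous between e2/e4 and
    e1/e3; it is reported as e2/e4 by convention (the e1 haplotype is
    vanishingly rare). Returns None (no-call) when either genotype is
    missing; raises on allele combinations implying an e1 haplotype.
    """
    if gt_rs429358 is None or gt_rs7412 is None:
        return None
    if len(gt_rs429358) != 2 or len(gt_rs7412) != 2:
        raise ValueError("APOE genotypes must be biallelic")
    n_e4 = sum(1 for a in gt_rs429358 if a == "C")
    n_e2 = sum(1 for a in gt_rs7412 if a == "T")
    n_e3 = 2 - n_e4 - n_e2
    if n_e3 < 0:
        raise ValueError(
            "APOE genotypes imply an e1 haplotype; cannot call a standard diplotype"
        )
    alleles = ["e2"] * n_e2 + ["e3"] * n_e3 + ["e4"] * n_e4
    return (alleles[0], alleles[1])


def apoe_findings(
    apoe_sites: Mapping[str, SiteGenotypes],
    participants: Sequence[Participant],
) -> list[Finding]:
    """One APOE finding per participant carrying one or two e4 alleles."""
    site1 = apoe_sites.get(APOE_SNP_1)
    site2 = apoe_sites.get(APOE_SNP_2)
    findings = []
    for p in participants:
        gt1 = site1.genotypes.get(p.id) if site1 else None
        gt2 = site2.genotypes.get(p.id) if site2 else None
        diplotype = call_apoe(gt1, gt2)
        if diplotype is None or "e4" not in diplotype:
            continue
        findings.append(
            Finding(
                participant_id=p.id,
                variant_key=f"APOE:{diplotype[0]}/{diplotype[1]}",
                gene_symbol="APOE",
                classification=ClassificationLabel.RISK_ALLELE,
                category=Category.APOE,
                zygosity=(
                    Zygosity.HOM_ALT
                    if diplotype == ("e4", "e4")
                    else Zygosity.HET
                ),
                rationale=(
                    f"APOE {diplotype[0]}/{diplotype[1]}: elevated lifetime "
                    "Alzheimer disease risk"
                ),
            )
        )
    return findings


def pgx_findings(
    sample_id: str,
    site_genotypes: Mapping[str, SiteGenotypes],
    panel: PGxPanel,
) -> list[Finding]:
    """One pharmacogenetic finding per panel rsID at which the participant
    carries a non-reference genotype."""
    findings = []
    for rsid in panel.rsids:
        site = site_genotypes.get(rsid)
        if site is None:
            continue
        gt = site.genotypes.get(sample_id)
        if gt is None:
            continue
        n_alt = sum(1 for a in gt if a != site.ref)
        if n_alt == 0:
            continue
        findings.append(
            Finding(
                participant_id=sample_id,
                variant_key=rsid,
                gene_symbol="",
                classification=ClassificationLabel.NOT_CLASSIFIED,
                category=Category.PGX,
                zygosity=Zygosity.HOM_ALT if n_alt == 2 else Zygosity.HET,
                rationale=panel.annotations.get(rsid, ""),
            )
        )
    return findings


def apply_return_preferences(
    findings: Iterable[Finding], participant: Participant
) -> list[Finding]:
    """Set the returned flag on each finding per the consent matrix."""
    out = []
    for f in findings:
        if f.classification is ClassificationLabel.VUS:
            f.returned = False
        elif participant.consent is Consent.NONE:
            f.returned = False
        elif participant.consent is Consent.ACTIONABLE_ONLY:
            f.returned = f.category is Category.ACTIONABLE
        else:  # all medically relevant
            if f.category is Category.APOE:
                f.returned = participant.apoe_requested
            else:
                f.returned = f.category in (
                    Category.ACTIONABLE,
                    Category.CARRIER,
                    Category.NONACTIONABLE_RISK,
                    Category.PGX,
                )
        out.append(f)
    return out


def generate_findings(
    classified: Sequence[ClassifiedVariant],
    participants: Sequence[Participant],
    catalog: Mapping[str, GeneRecord],
    apoe_sites: Optional[Mapping[str, SiteGenotypes]] = None,
    pgx_sites: Optional[Mapping[str, SiteGenotypes]] = None,
    panel: Optional[PGxPanel] = None,
) -> list[Finding]:
    """Categorize every reportable classified variant, add APOE and
    pharmacogenetic findings, and apply the consent-based return gate."""
    by_participant: dict[str, list[ClassifiedVariant]] = {}
    for cv in classified:
        by_participant.setdefault(cv.variant.participant_id, []).append(cv)

    all_findings: list[Finding] = []
    for p in participants:
        findings: list[Finding] = []
        mine = by_participant.get(p.id, [])
        for cv in mine:
            if cv.classification not in REPORTABLE_LABELS:
                continue
            gene = catalog.get(cv.variant.annotation.gene_symbol)
            if gene is None:
                continue
            actionable = determine_actionability(
                cv.variant, cv.classification, gene, mine
            )
            trail = f"evidence triggers: {'+'.join(cv.triggers) or 'n/a'}"
            if actionable:
                findings.append(
                    Finding(
                        participant_id=p.id,
                        variant_key=cv.variant.key,
                        gene_symbol=gene.symbol,
                        classification=cv.classification,
                        category=Category.ACTIONABLE,
                        zygosity=cv.variant.zygosity,
                        rationale=f"{gene.actionable_disease}; {trail}",
                    )
                )
            elif detect_carrier(cv.variant, cv.classification, gene, actionable):
                findings.append(
                    Finding(
                        participant_id=p.id,
                        variant_key=cv.variant.key,
                        gene_symbol=gene.symbol,
                        classification=cv.classification,
                        category=Category.CARRIER,
                        zygosity=cv.variant.zygosity,
                        rationale=f"carrier, autosomal recessive; {trail}",
                    )
                )
            if flag_nonactionable_risk(cv.variant, cv.classification, gene):
                findings.append(
                    Finding(
                        participant_id=p.id,
                        variant_key=cv.variant.key,
                        gene_symbol=gene.symbol,
                        classification=cv.classification,
                        category=Category.NONACTIONABLE_RISK,
                        zygosity=cv.variant.zygosity,
                        rationale=(
                            f"risk without effective intervention: "
                            f"{gene.nonactionable_risk_disease}; {trail}"
                        ),
                    )
                )
        if apoe_sites:
            findings.extend(apoe_findings(apoe_sites, [p]))
        if pgx_sites and panel:
            findings.extend(pgx_findings(p.id, pgx_sites, panel))
        all_findings.extend(apply_return_preferences(findings, p))
    return all_findings
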