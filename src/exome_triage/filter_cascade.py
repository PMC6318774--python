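"""Filter cascade turning raw annotated calls into the curation queue.

Stages, in order: call quality (Phred and depth minima), consequence
(coding or canonical splice), global MAF with ClinVar rescue of common
founder variants, Mendelian gene-list membership, subpopulation MAF
re-check, phenotype-consistency removal for serious/highly-penetrant/
young-onset genes, gene-level evidence review, an optional curator
artifact blacklist, and finally curation-queue triggering (loss-of-
function type, HGMD exact match, ACMG-59 gene, ClinVar rescue, or a
family/personal-history link to the gene's phenotype).

Every stage conserves counts (input = kept + removed) and is logged in a
stage-by-stage audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import (
    CODING_OR_SPLICE,
    LOF_CONSEQUENCES,
    ClinvarSignificance,
    Consequence,
    FilterConfig,
    GeneRecord,
    Participant,
    SubpopFrequency,
    VariantRecord,
    Zygosity,
)

RESCUE_SIGNIFICANCES = frozenset(
    {ClinvarSignificance.PATHOGENIC, ClinvarSignificance.LIKELY_PATHOGENIC}
)


@dataclass
class AuditEntry:
    stage: str
    n_in: int
    n_kept: int
    n_removed: int


@dataclass
class QueueEntry:
    """A variant queued for manual curation, with the trigger(s) that fired."""

    variant: VariantRecord
    triggers: tuple[str, ...]


@dataclass
class CascadeResult:
    queue: list[QueueEntry]
    survivors: list[VariantRecord]
    rescued_keys: frozenset
    audit: list[AuditEntry]
    decisions: list[tuple[str, str, str, str]] = field(default_factory=list)
    # decisions rows: (variant key + participant, stage, decision, trigger)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": a.stage,
                    "n_in": a.n_in,
                    "n_kept": a.n_kept,
                    "n_removed": a.n_removed,
                }
                for a in self.audit
            ]
        )

    def write_audit_log(self, path) -> None:
        pd.DataFrame(
            self.decisions,
            columns=["variant", "stage", "decision", "trigger"],
        ).to_csv(path, sep="\t", index=False)


def apply_quality_filter(
    variants: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Keep calls meeting both the Phred and the read-depth minima
    (minima are inclusive)."""
    return [
        v
        for v in variants
        if v.phred_qual >= cfg.phred_min and v.depth >= cfg.depth_min
    ]


def apply_consequence_filter(
    variants: Sequence[VariantRecord],
    keep: frozenset = CODING_OR_SPLICE,
) -> list[VariantRecord]:
    """Keep coding or canonical-splice variants (synonymous excluded)."""
    return [v for v in variants if v.annotation.consequence in keep]


def apply_maf_filter(
    variants: Sequence[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition on global MAF: excluded iff either database exceeds the
    threshold (strictly greater; a MAF exactly at 0.5% is kept)."""
    kept, excluded = [], []
    for v in variants:
        if (
            v.annotation.maf_1000g > cfg.maf_threshold
            or v.annotation.maf_exac > cfg.maf_threshold
        ):
            excluded.append(v)
        else:
            kept.append(v)
    return kept, excluded


def clinvar_rescue(
    excluded_by_maf: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Rescue common founder variants: above-threshold MAF but classified
    pathogenic/likely pathogenic in ClinVar with enough review stars."""
    return [
        v
        for v in excluded_by_maf
        if v.annotation.clinvar_significance in RESCUE_SIGNIFICANCES
        and v.annotation.clinvar_stars >= cfg.clinvar_rescue_min_stars
    ]


def apply_gene_list_filter(
    variants: Sequence[VariantRecord], catalog: Mapping[str, GeneRecord]
) -> list[VariantRecord]:
    """Keep variants in the Mendelian search space: OMIM Mendelian genes
    (exception-only genes excluded) or ACMG-59 genes. Genes absent from
    the catalog are dropped."""
    kept = []
    for v in variants:
        gene = catalog.get(v.annotation.gene_symbol)
        if gene is not None and gene.in_mendelian_search_space:
            kept.append(v)
    return kept


def subpopulation_maf_check(
    variant: VariantRecord, cfg: FilterConfig
) -> tuple[bool, Optional[SubpopFrequency]]:
    """Re-check a globally-rare variant against subpopulation MAFs.

    Subpopulations are walked in descending frequency order; entries backed
    by too few alleles (allele number below the floor, or an implied
    alternate-allele count below the floor) are skipped — a frequency based
    on one allele out of 500 is not trusted, and the next-highest
    subpopulation decides instead. Returns (keep, decisive entry).
    """
    entries = sorted(
        variant.annotation.subpop_mafs, key=lambda s: s.af, reverse=True
    )
    for entry in entries:
        alt_count = round(entry.af * entry.an)
        if entry.an < cfg.subpop_min_allele_number:
            continue
        if alt_count < cfg.subpop_min_alt_count:
            continue
        return entry.af <= cfg.maf_threshold, entry
    return True, None


def phenotype_consistency_filter(
    variant: VariantRecord, gene: GeneRecord, participant: Participant
) -> bool:
    """Decide whether to keep a variant in a serious, highly penetrant,
    young-onset disease gene given the participant's phenotype.

    Removal requires a disease-consistent genotype (homozygous for a
    recessive disease or heterozygous for a dominant one) and the absence
    of every gene phenotype term from the participant's record; genes with
    variable onset, or participants younger than the gene's full-penetrance
    age, are exempt. Returns True to keep."""
    if not (
        gene.severity_class == "serious"
        and gene.penetrance_class == "high"
        and gene.onset_class == "young"
    ):
        return True
    disease_consistent = (
        variant.zygosity is Zygosity.HOM_ALT and "AR" in gene.inheritance
    ) or (variant.zygosity is Zygosity.HET and "AD" in gene.inheritance)
    if not disease_consistent:
        return True
    if (
        gene.full_penetrance_age is not None
        and participant.age < gene.full_penetrance_age
    ):
        return True
    if set(gene.phenotype_terms) & set(participant.phenotype_terms):
        return True
    return False


def gene_evidence_filter(variant: VariantRecord, gene: GeneRecord) -> bool:
    """Remove variants in genes whose disease association is provisional
    (GWAS-only / single-report), unless the gene is on the ACMG-59 list.
    Returns True to keep."""
    if "question_provisional" in gene.omim_exception and not gene.on_acmg59:
        return False
    return True


def build_curation_queue(
    variants: Sequence[VariantRecord],
    catalog: Mapping[str, GeneRecord],
    participants: Mapping[str, Participant],
    rescued_keys: Iterable[str] = (),
) -> list[QueueEntry]:
    """Queue variants for manual curation when any trigger fires:
    loss-of-function type, exact HGMD disease-mutation match, ACMG-59
    gene, ClinVar rescue, or a link between the gene's phenotype terms and
    the participant's personal/family history."""
    rescued = frozenset(rescued_keys)
    queue = []
    for v in variants:
        triggers = []
        gene = catalog.get(v.annotation.gene_symbol)
        if v.annotation.consequence in LOF_CONSEQUENCES:
            triggers.append("LoF")
        if v.annotation.hgmd_dm_match:
            triggers.append("HGMD")
        if gene is not None and gene.on_acmg59:
            triggers.append("ACMG59")
        if v.key in rescued:
            triggers.append("rescue")
        participant = participants.get(v.participant_id)
        if (
            gene is not None
            and participant is not None
            and set(gene.phenotype_terms) & participant.history_terms
        ):
            triggers.append("history")
        if triggers:
            queue.append(QueueEntry(variant=v, triggers=tuple(triggers)))
    return queue


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    catalog: Mapping[str, GeneRecord],
    participants: Sequence[Participant],
    cfg: Optional[FilterConfig] = None,
    artifact_blacklist: Iterable[str] = (),
) -> CascadeResult:
    """Run the full cascade and assemble the curation queue.

    ``artifact_blacklist`` holds site keys a curator flagged as alignment
    artifacts after read review; the pipeline consumes the list rather
    than re-inspecting reads.
    """
    cfg = cfg or FilterConfig()
    by_id = {p.id: p for p in participants}
    blacklist = frozenset(artifact_blacklist)
    audit: list[AuditEntry] = []
    decisions: list[tuple[str, str, str, str]] = []

    def tag(v: VariantRecord) -> str:
        return f"{v.key}@{v.participant_id}"

    def log_stage(stage, before, kept, removed, trigger=""):
        audit.append(AuditEntry(stage, len(before), len(kept), len(removed)))
        for v in removed:
            decisions.append((tag(v), stage, "remove", trigger))

    current = list(variants)

    kept = apply_quality_filter(current, cfg)
    log_stage("quality", current, kept, _diff(current, kept))
    current = kept

    kept = apply_consequence_filter(current, frozenset(cfg.coding_consequences))
    log_stage("consequence", current, kept, _diff(current, kept))
    current = kept

    kept, excluded = apply_maf_filter(current, cfg)
    log_stage("maf", current, kept, excluded)
    rescued = clinvar_rescue(excluded, cfg)
    audit.append(AuditEntry("clinvar_rescue", len(excluded), len(rescued), len(excluded) - len(rescued)))
    for v in rescued:
        decisions.append((tag(v), "clinvar_rescue", "rescue", "clinvar"))
    rescued_keys = frozenset(v.key for v in rescued)
    current = kept + rescued

    kept = apply_gene_list_filter(current, catalog)
    log_stage("gene_list", current, kept, _diff(current, kept))
    current = kept

    # Subpopulation re-check only applies to variants that passed the
    # global MAF filter; rescued variants are exempt by construction.
    kept, removed = [], []
    for v in current:
        if v.key in rescued_keys:
            kept.append(v)
            continue
        ok, decisive = subpopulation_maf_check(v, cfg)
        if ok:
            kept.append(v)
        else:
            removed.append(v)
            decisions.append(
                (tag(v), "subpop_maf", "remove", decisive.label if decisive else "")
            )
    audit.append(AuditEntry("subpop_maf", len(current), len(kept), len(removed)))
    current = kept

    kept, removed = [], []
    for v in current:
        gene = catalog[v.annotation.gene_symbol]
        participant = by_id.get(v.participant_id)
        if participant is None or phenotype_consistency_filter(v, gene, participant):
            kept.append(v)
        else:
            removed.append(v)
    log_stage("phenotype_consistency", current, kept, removed, "no-phenotype")
    current = kept

    kept, removed = [], []
    for v in current:
        gene = catalog[v.annotation.gene_symbol]
        (kept if gene_evidence_filter(v, gene) else removed).append(v)
    log_stage("gene_evidence", current, kept, removed, "provisional")
    current = kept

    kept = [v for v in current if v.key not in blacklist]
    log_stage("artifact_blacklist", current, kept, _diff(current, kept), "artifact")
    current = kept

    queue = build_curation_queue(current, catalog, by_id, rescued_keys)
    audit.append(
        AuditEntry("curation_queue", len(current), len(queue), len(current) - len(queue))
    )
    for entry in queue:
        decisions.append(
            (tag(entry.variant), "curation_queue", "queue", "+".join(entry.triggers))
        )

    return CascadeResult(
        queue=queue,
        survivors=current,
        rescued_keys=rescued_keys,
        audit=audit,
        decisions=decisions,
    )


def _diff(before: Sequence[VariantRecord], after: Sequence[VariantRecord]):
    after_ids = {id(v) for v in after}
    return [v for v in before if id(v) not in after_ids]
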