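"""End-to-end wiring: filter -> classify -> report -> summarize."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .acmg_engine import EvidenceAssignment, classify_variant
from .cohort_stats import CohortSummary, summarize_cohort
from .core_io import (
    SiteGenotypes,
    load_default_gene_table,
    load_default_pgx_panel,
    load_filter_config,
    read_cohort_vcf,
    read_evidence_table,
    read_gene_table,
    read_participant_table,
    read_pgx_panel,
    read_site_genotypes,
)
from .filter_cascade import CascadeResult, QueueEntry, run_filter_cascade
from .findings_reporter import (
    APOE_SNP_1,
    APOE_SNP_2,
    ClassifiedVariant,
    generate_findings,
)
from .models import (
    ClassificationLabel,
    FilterConfig,
    Finding,
    GeneRecord,
    Participant,
    PGxPanel,
    VariantRecord,
)


@dataclass
class PipelineResult:
    cascade: CascadeResult
    classified: list
    findings: list
    summary: CohortSummary

    @property
    def classification_labels(self) -> list:
        """One label per reviewed variant: the curated call for queued
        variants, ``not_classified`` for survivors that were never queued."""
        labels = [cv.classification for cv in self.classified]
        n_unqueued = len(self.cascade.survivors) - len(self.cascade.queue)
        labels.extend([ClassificationLabel.NOT_CLASSIFIED] * n_unqueued)
        return labels


def classify_queue(
    queue: Sequence[QueueEntry], evidence: Sequence[EvidenceAssignment]
) -> list[ClassifiedVariant]:
    """Attach curator classifications to the queue; queued variants without
    an evidence assignment stay ``not_classified``."""
    by_key = {a.variant_key: a for a in evidence}
    out = []
    for entry in queue:
        assignment = by_key.get(entry.variant.key)
        label = (
            classify_variant(assignment)
            if assignment is not None
            else ClassificationLabel.NOT_CLASSIFIED
        )
        out.append(ClassifiedVariant(entry.variant, label, entry.triggers))
    return out


def run_pipeline(
    variants: Sequence[VariantRecord],
    participants: Sequence[Participant],
    catalog: Mapping[str, GeneRecord],
    evidence: Sequence[EvidenceAssignment],
    cfg: Optional[FilterConfig] = None,
    apoe_sites: Optional[Mapping[str, SiteGenotypes]] = None,
    pgx_sites: Optional[Mapping[str, SiteGenotypes]] = None,
    panel: Optional[PGxPanel] = None,
    artifact_blacklist: Sequence[str] = (),
) -> PipelineResult:
    cfg = cfg or FilterConfig()
    cascade = run_filter_cascade(
        variants, catalog, participants, cfg, artifact_blacklist
    )
    classified = classify_queue(cascade.queue, evidence)
    findings = generate_findings(
        classified, participants, catalog, apoe_sites, pgx_sites, panel
    )
    result = PipelineResult(cascade, classified, findings, None)
    result.summary = summarize_cohort(
        findings,
        participants,
        catalog,
        classification_labels=result.classification_labels,
        z=cfg.ci_z,
        ci_method=cfg.ci_method,
    )
    return result


def run_pipeline_from_paths(
    vcf_path,
    participants_path,
    evidence_path,
    genes_path=None,
    config_path=None,
    panel_path=None,
) -> PipelineResult:
    """File-based entry point used by the CLI and the acceptance runs."""
    variants = read_cohort_vcf(vcf_path)
    participants = read_participant_table(participants_path)
    evidence = read_evidence_table(evidence_path)
    catalog = (
        read_gene_table(genes_path) if genes_path else load_default_gene_table()
    )
    cfg = load_filter_config(config_path) if config_path else FilterConfig()
    if panel_path:
        panel, _table = read_pgx_panel(panel_path)
    else:
        panel, _table = load_default_pgx_panel()
    apoe_sites = read_site_genotypes(vcf_path, [APOE_SNP_1, APOE_SNP_2])
    pgx_sites = read_site_genotypes(vcf_path, panel.rsids)
    return run_pipeline(
        variants,
        participants,
        catalog,
        evidence,
        cfg,
        apoe_sites=apoe_sites,
        pgx_sites=pgx_sites,
        panel=panel,
    )
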