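"""Readers and writers for every external format the pipeline touches.

Variants travel in VCF 4.2 with a documented per-ALT INFO dialect; gene,
participant and evidence tables are UTF-8 tab-delimited files with a header
row; findings reports are emitted as TSV plus JSON; the filter
configuration round-trips through YAML.

VCF annotation dialect (all keys ``Number=A``, one value per ALT allele)::

    GENE       gene symbol
    TRANSCRIPT transcript identifier
    HGVSC      HGVS cDNA string
    HGVSP      HGVS protein string
    CSQCLASS   consequence class (missense, nonsense, frameshift_ins,
               frameshift_del, inframe_indel, canonical_splice,
               synonymous, other_noncoding)
    MAF1KG     1000 Genomes global MAF (decimal text; "0" when absent)
    MAFEXAC    ExAC global MAF (decimal text; "0" when absent)
    SUBPOP     pipe-separated LABEL:AF:AN triples, or "NA"
    CLNSIG     ClinVar significance (or "absent")
    CLNSTARS   ClinVar review-status stars, 0-4
    HGMDDM     1 when the variant exactly matches an HGMD disease mutation

MAF values are carried as strings rather than VCF Floats so that the exact
decimal text survives the round-trip; single-precision parsing would
perturb values sitting on the 0.5% filter boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .acmg_engine import EvidenceAssignment, parse_codes
from .models import (
    AnnotationBlock,
    ClinvarSignificance,
    Consequence,
    Consent,
    FilterConfig,
    Finding,
    FormatError,
    GeneRecord,
    Participant,
    PGxPanel,
    SubpopFrequency,
    ValidationError,
    VariantRecord,
    Zygosity,
)

logger = logging.getLogger(__name__)

INFO_KEYS = (
    ("GENE", "String", "Gene symbol"),
    ("TRANSCRIPT", "String", "Transcript identifier"),
    ("HGVSC", "String", "HGVS cDNA description"),
    ("HGVSP", "String", "HGVS protein description"),
    ("CSQCLASS", "String", "Consequence class"),
    ("MAF1KG", "String", "1000 Genomes global minor allele frequency"),
    ("MAFEXAC", "String", "ExAC global minor allele frequency"),
    ("SUBPOP", "String", "Subpopulation LABEL:AF:AN triples, pipe-separated"),
    ("CLNSIG", "String", "ClinVar clinical significance"),
    ("CLNSTARS", "Integer", "ClinVar review-status stars"),
    ("HGMDDM", "Integer", "Exact HGMD disease-mutation match (0/1)"),
)

MANDATORY_INFO = tuple(k for k, _, _ in INFO_KEYS)

CONTIGS = tuple(str(c) for c in range(1, 23)) + ("X", "Y", "MT")
_CONTIG_ORDER = {c: i for i, c in enumerate(CONTIGS)}


def _fmt_float(x: float) -> str:
    return f"{x:.10g}"


def _encode_subpops(subs: Sequence[SubpopFrequency]) -> str:
    if not subs:
        return "NA"
    return "|".join(f"{s.label}:{_fmt_float(s.af)}:{s.an}" for s in subs)


def _decode_subpops(text: str) -> tuple[SubpopFrequency, ...]:
    if text in ("NA", "", "."):
        return ()
    out = []
    for triple in text.split("|"):
        parts = triple.split(":")
        if len(parts) != 3:
            raise FormatError(f"malformed SUBPOP triple: {triple!r}")
        out.append(SubpopFrequency(parts[0], float(parts[1]), int(parts[2])))
    return tuple(out)


def _build_vcf_header(samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in CONTIGS:
        header.contigs.add(contig)
    for key, vtype, desc in INFO_KEYS:
        header.info.add(key, "A", vtype, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at the site")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_cohort_vcf(
    records: Iterable[VariantRecord],
    path,
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Write cohort variants to a multi-sample VCF.

    Records sharing a site key must agree on QUAL and annotation (both are
    site-level in VCF); per-sample genotype and depth may differ. When
    ``samples`` is given, every listed sample appears in the VCF even if it
    carries no variant.
    """
    records = list(records)
    if samples is None:
        samples = sorted({r.participant_id for r in records})
    else:
        samples = list(samples)
    sample_set = set(samples)
    for rec in records:
        if rec.participant_id not in sample_set:
            raise ValidationError(
                f"record for unknown sample {rec.participant_id!r}"
            )

    sites: dict[tuple, list[VariantRecord]] = {}
    for rec in records:
        sites.setdefault((rec.chrom, rec.pos, rec.ref, rec.alt), []).append(rec)

    def site_order(item):
        (chrom, pos, ref, alt), _ = item
        return (_CONTIG_ORDER.get(chrom, len(CONTIGS)), pos, ref, alt)

    header = _build_vcf_header(samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for (chrom, pos, ref, alt), carriers in sorted(sites.items(), key=site_order):
            first = carriers[0]
            for other in carriers[1:]:
                if other.annotation != first.annotation:
                    raise ValidationError(
                        f"conflicting annotations at site {first.key}"
                    )
                if other.phred_qual != first.phred_qual:
                    raise ValidationError(
                        f"conflicting site quality at {first.key}"
                    )
            ann = first.annotation
            out = vcf.new_record(
                contig=chrom,
                start=pos - 1,
                alleles=(ref, alt),
                qual=first.phred_qual,
                id=ann.rsid,
            )
            out.info["GENE"] = (ann.gene_symbol,)
            out.info["TRANSCRIPT"] = (ann.transcript or ".",)
            out.info["HGVSC"] = (ann.hgvs_c or ".",)
            out.info["HGVSP"] = (ann.hgvs_p or ".",)
            out.info["CSQCLASS"] = (ann.consequence.value,)
            out.info["MAF1KG"] = (_fmt_float(ann.maf_1000g),)
            out.info["MAFEXAC"] = (_fmt_float(ann.maf_exac),)
            out.info["SUBPOP"] = (_encode_subpops(ann.subpop_mafs),)
            out.info["CLNSIG"] = (ann.clinvar_significance.value,)
            out.info["CLNSTARS"] = (ann.clinvar_stars,)
            out.info["HGMDDM"] = (1 if ann.hgmd_dm_match else 0,)
            by_sample = {c.participant_id: c for c in carriers}
            for sample in samples:
                carrier = by_sample.get(sample)
                if carrier is None:
                    out.samples[sample]["GT"] = (0, 0)
                else:
                    gt = (1, 1) if carrier.zygosity is Zygosity.HOM_ALT else (0, 1)
                    out.samples[sample]["GT"] = gt
                    out.samples[sample]["DP"] = carrier.depth
            vcf.write(out)


def _info_values(rec, key: str, n_alts: int):
    if key not in rec.info:
        raise FormatError(
            f"missing mandatory INFO key {key} at {rec.chrom}:{rec.pos}"
        )
    value = rec.info[key]
    if not isinstance(value, tuple):
        value = (value,)
    if len(value) != n_alts:
        raise FormatError(
            f"INFO key {key} at {rec.chrom}:{rec.pos} carries {len(value)} "
            f"values for {n_alts} ALT allele(s)"
        )
    return value


def read_cohort_vcf(path) -> list[VariantRecord]:
    """Read a cohort VCF into decomposed per-sample variant records.

    Emits one record per (sample, ALT allele) pair with a non-reference
    genotype; multi-allelic sites are decomposed using the per-ALT INFO
    values; reference (0/0) and no-call genotypes produce nothing.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    records: list[VariantRecord] = []
    with vcf:
        line_no = 0
        for rec in vcf:
            line_no += 1
            alts = rec.alts or ()
            if not alts:
                continue
            try:
                values = {
                    key: _info_values(rec, key, len(alts))
                    for key in MANDATORY_INFO
                }
            except FormatError:
                raise
            except Exception as exc:  # malformed INFO payloads
                raise FormatError(
                    f"malformed INFO block at record {line_no} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
            annotations = []
            for i in range(len(alts)):
                annotations.append(
                    AnnotationBlock(
                        gene_symbol=values["GENE"][i],
                        transcript=_dot(values["TRANSCRIPT"][i]),
                        hgvs_c=_dot(values["HGVSC"][i]),
                        hgvs_p=_dot(values["HGVSP"][i]),
                        consequence=Consequence(values["CSQCLASS"][i]),
                        maf_1000g=float(values["MAF1KG"][i]),
                        maf_exac=float(values["MAFEXAC"][i]),
                        subpop_mafs=_decode_subpops(values["SUBPOP"][i]),
                        clinvar_significance=ClinvarSignificance(
                            values["CLNSIG"][i]
                        ),
                        clinvar_stars=int(values["CLNSTARS"][i]),
                        hgmd_dm_match=bool(int(values["HGMDDM"][i])),
                        rsid=rec.id,
                    )
                )
            qual = rec.qual if rec.qual is not None else 0.0
            for sample, sdata in rec.samples.items():
                gt = sdata.get("GT")
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                alt_indices = sorted({a for a in alleles if a > 0})
                for alt_idx in alt_indices:
                    zyg = (
                        Zygosity.HOM_ALT
                        if alleles.count(alt_idx) >= 2
                        else Zygosity.HET
                    )
                    depth = sdata.get("DP")
                    records.append(
                        VariantRecord(
                            participant_id=sample,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alts[alt_idx - 1],
                            phred_qual=qual,
                            depth=int(depth) if depth is not None else 0,
                            zygosity=zyg,
                            annotation=annotations[alt_idx - 1],
                        )
                    )
    return records


def _dot(value: str) -> str:
    return "" if value == "." else value


class SiteGenotypes:
    """Genotypes of every sample at one biallelic site, including hom-ref."""

    def __init__(self, rsid: str, ref: str, alt: str, genotypes: Mapping):
        self.rsid = rsid
        self.ref = ref
        self.alt = alt
        self.genotypes = dict(genotypes)  # sample -> (allele, allele) or None

    def non_reference_samples(self) -> list[str]:
        return [
            s
            for s, gt in self.genotypes.items()
            if gt is not None and any(a != self.ref for a in gt)
        ]


def read_site_genotypes(path, rsids: Iterable[str]) -> dict[str, SiteGenotypes]:
    """Look up per-sample genotypes at specific rsIDs (APOE, PGx panel).

    Unlike :func:`read_cohort_vcf` this keeps homozygous-reference calls,
    which genotype-based reporting (APOE diplotypes, panel lookups) needs.
    """
    wanted = set(rsids)
    out: dict[str, SiteGenotypes] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.id is None or rec.id not in wanted:
                continue
            alleles = rec.alleles
            genotypes = {}
            for sample, sdata in rec.samples.items():
                gt = sdata.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes[sample] = None
                else:
                    genotypes[sample] = tuple(alleles[a] for a in gt)
            out[rec.id] = SiteGenotypes(rec.id, rec.ref, rec.alts[0], genotypes)
    return out


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "symbol",
    "mim_number",
    "inheritance",
    "omim_mendelian",
    "omim_exception",
    "on_acmg59",
    "actionable_disease",
    "penetrance_class",
    "onset_class",
    "severity_class",
    "het_risk_actionable",
    "nonactionable_risk_disease",
    "full_penetrance_age",
    "phenotype_terms",
]


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise ValidationError(f"unknown boolean token: {value!r}")


def _parse_set(value) -> frozenset:
    text = str(value).strip()
    if not text or text == "nan":
        return frozenset()
    return frozenset(t.strip() for t in text.split(",") if t.strip())


def _parse_terms(value) -> tuple[str, ...]:
    text = str(value).strip()
    if not text or text == "nan":
        return ()
    return tuple(t.strip() for t in text.split(";") if t.strip())


def _read_tsv(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def read_gene_table(path) -> dict[str, GeneRecord]:
    """Read the gene metadata catalog; returns a symbol-keyed mapping."""
    df = _read_tsv(path, _GENE_COLUMNS)
    if df.empty:
        logger.warning("gene table %s is empty", path)
        return {}
    catalog: dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        symbol = row["symbol"].strip()
        if symbol in catalog:
            raise ValidationError(f"duplicate gene symbol: {symbol}")
        age = row["full_penetrance_age"].strip()
        catalog[symbol] = GeneRecord(
            symbol=symbol,
            mim_number=row["mim_number"].strip(),
            inheritance=_parse_set(row["inheritance"]),
            omim_mendelian=_parse_bool(row["omim_mendelian"]),
            omim_exception=_parse_set(row["omim_exception"]),
            on_acmg59=_parse_bool(row["on_acmg59"]),
            actionable_disease=row["actionable_disease"].strip(),
            penetrance_class=row["penetrance_class"].strip() or "low",
            onset_class=row["onset_class"].strip() or "adult",
            severity_class=row["severity_class"].strip() or "mild",
            het_risk_actionable=_parse_bool(row["het_risk_actionable"]),
            nonactionable_risk_disease=row["nonactionable_risk_disease"].strip(),
            full_penetrance_age=int(age) if age else None,
            phenotype_terms=_parse_terms(row["phenotype_terms"]),
        )
    return catalog


def write_gene_table(catalog: Mapping[str, GeneRecord], path) -> None:
    rows = []
    for symbol in sorted(catalog):
        g = catalog[symbol]
        rows.append(
            {
                "symbol": g.symbol,
                "mim_number": g.mim_number,
                "inheritance": ",".join(sorted(g.inheritance)),
                "omim_mendelian": str(g.omim_mendelian).lower(),
                "omim_exception": ",".join(sorted(g.omim_exception)),
                "on_acmg59": str(g.on_acmg59).lower(),
                "actionable_disease": g.actionable_disease,
                "penetrance_class": g.penetrance_class,
                "onset_class": g.onset_class,
                "severity_class": g.severity_class,
                "het_risk_actionable": str(g.het_risk_actionable).lower(),
                "nonactionable_risk_disease": g.nonactionable_risk_disease,
                "full_penetrance_age": (
                    "" if g.full_penetrance_age is None else str(g.full_penetrance_age)
                ),
                "phenotype_terms": ";".join(g.phenotype_terms),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


_PARTICIPANT_COLUMNS = [
    "id",
    "age",
    "sex",
    "ethnicity",
    "phenotype_terms",
    "family_history_terms",
    "consent",
    "apoe_requested",
]


def read_participant_table(path) -> list[Participant]:
    df = _read_tsv(path, _PARTICIPANT_COLUMNS)
    participants = []
    for _, row in df.iterrows():
        participants.append(
            Participant(
                id=row["id"].strip(),
                age=int(row["age"]),
                sex=row["sex"].strip(),
                ethnicity=row["ethnicity"].strip(),
                phenotype_terms=_parse_terms(row["phenotype_terms"]),
                family_history_terms=_parse_terms(row["family_history_terms"]),
                consent=Consent(row["consent"].strip()),
                apoe_requested=_parse_bool(row["apoe_requested"]),
            )
        )
    return participants


def write_participant_table(participants: Sequence[Participant], path) -> None:
    rows = [
        {
            "id": p.id,
            "age": str(p.age),
            "sex": p.sex,
            "ethnicity": p.ethnicity,
            "phenotype_terms": ";".join(p.phenotype_terms),
            "family_history_terms": ";".join(p.family_history_terms),
            "consent": p.consent.value,
            "apoe_requested": str(p.apoe_requested).lower(),
        }
        for p in participants
    ]
    pd.DataFrame(rows, columns=_PARTICIPANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


_EVIDENCE_COLUMNS = ["variant_key", "codes", "risk_allele", "notes"]


def read_evidence_table(path) -> list[EvidenceAssignment]:
    df = _read_tsv(path, _EVIDENCE_COLUMNS)
    assignments = []
    for _, row in df.iterrows():
        assignments.append(
            EvidenceAssignment(
                variant_key=row["variant_key"].strip(),
                codes=parse_codes(row["codes"]),
                risk_allele=_parse_bool(row["risk_allele"]),
                notes=row["notes"],
            )
        )
    return assignments


def write_evidence_table(assignments: Sequence[EvidenceAssignment], path) -> None:
    rows = [
        {
            "variant_key": a.variant_key,
            "codes": ",".join(str(c) for c in a.codes),
            "risk_allele": str(a.risk_allele).lower(),
            "notes": a.notes,
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Findings report
# ---------------------------------------------------------------------------

_FINDING_COLUMNS = [
    "participant_id",
    "variant_key",
    "gene_symbol",
    "classification",
    "category",
    "zygosity",
    "returned",
    "rationale",
]


def _finding_to_row(f: Finding) -> dict:
    return {
        "participant_id": f.participant_id,
        "variant_key": f.variant_key,
        "gene_symbol": f.gene_symbol,
        "classification": f.classification.value,
        "category": f.category.value,
        "zygosity": f.zygosity.value if f.zygosity else "",
        "returned": str(f.returned).lower(),
        "rationale": f.rationale,
    }


def write_findings_report(findings: Sequence[Finding], tsv_path, json_path=None) -> None:
    """Write the findings report as TSV (and optionally JSON).

    The report carries the classification, category, returned flag and the
    evidence trail (rationale) for every finding.
    """
    rows = [_finding_to_row(f) for f in findings]
    pd.DataFrame(rows, columns=_FINDING_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")


def read_findings_report(tsv_path) -> list[Finding]:
    df = _read_tsv(tsv_path, _FINDING_COLUMNS)
    findings = []
    for _, row in df.iterrows():
        findings.append(
            Finding(
                participant_id=row["participant_id"],
                variant_key=row["variant_key"],
                gene_symbol=row["gene_symbol"],
                classification=row["classification"],
                category=row["category"],
                zygosity=row["zygosity"] or None,
                returned=_parse_bool(row["returned"]),
                rationale=row["rationale"],
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Config, bundled data, JSON serialization of variants
# ---------------------------------------------------------------------------


def load_filter_config(path) -> FilterConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(FilterConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return FilterConfig(**data)


def save_filter_config(cfg: FilterConfig, path) -> None:
    data = asdict(cfg)
    data["coding_consequences"] = [c.value for c in cfg.coding_consequences]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_default_gene_table() -> dict[str, GeneRecord]:
    """Load the catalog bundled with the package."""
    with resources.as_file(
        resources.files("exome_triage") / "data" / "genes.tsv"
    ) as p:
        return read_gene_table(p)


_PGX_COLUMNS = ["rsid", "gene", "chrom", "pos", "ref", "alt", "maf", "annotation"]


def read_pgx_panel(path) -> tuple[PGxPanel, pd.DataFrame]:
    """Read a pharmacogenetic panel TSV; returns the panel plus site table."""
    df = _read_tsv(path, _PGX_COLUMNS)
    rsids = tuple(df["rsid"])
    annotations = {row["rsid"]: row["annotation"] for _, row in df.iterrows()}
    return PGxPanel(rsids=rsids, annotations=annotations), df


def load_default_pgx_panel() -> tuple[PGxPanel, pd.DataFrame]:
    """Load the bundled synthetic stand-in panel of level-1A-style rsIDs."""
    with resources.as_file(
        resources.files("exome_triage") / "data" / "pgx_panel_synthetic.tsv"
    ) as p:
        return read_pgx_panel(p)


def variant_to_dict(rec: VariantRecord) -> dict:
    d = asdict(rec)
    d["zygosity"] = rec.zygosity.value
    ann = d["annotation"]
    ann["consequence"] = rec.annotation.consequence.value
    ann["clinvar_significance"] = rec.annotation.clinvar_significance.value
    ann["subpop_mafs"] = [list(s) for s in rec.annotation.subpop_mafs]
    return d


def variant_from_dict(d: dict) -> VariantRecord:
    ann = dict(d["annotation"])
    ann["subpop_mafs"] = tuple(SubpopFrequency(*s) for s in ann["subpop_mafs"])
    return VariantRecord(
        participant_id=d["participant_id"],
        chrom=d["chrom"],
        pos=d["pos"],
        ref=d["ref"],
        alt=d["alt"],
        phred_qual=d["phred_qual"],
        depth=d["depth"],
        zygosity=d["zygosity"],
        annotation=AnnotationBlock(**ann),
    )
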