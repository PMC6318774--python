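"""Seeded synthetic-cohort generator with a known truth table.

The generator emulates the study conditions of a 70-participant
average-risk exome cohort: a planted set of curated actionable variants
(one per affected participant, the APC founder allele in two), 150
heterozygous pathogenic/likely-pathogenic carrier variants spread over 60
participants, 21 participants with one or two APOE e4 alleles (18 of them
also carriers), level-1A-style pharmacogenetic genotypes (one to six per
participant), and a benign background whose MAF spectrum, call quality
and consequence mix give every cascade stage visible work. All randomness
flows from one integer seed; a fixed seed regenerates byte-identical
outputs.

Coordinates of planted variants are synthetic but stable: the pipeline
never recomputes consequence from sequence, so exact genomic positions
are not load-bearing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .acmg_engine import EvidenceAssignment, parse_codes
from .core_io import (
    load_default_gene_table,
    load_default_pgx_panel,
    write_cohort_vcf,
    write_evidence_table,
    write_gene_table,
    write_participant_table,
)
from .models import (
    AnnotationBlock,
    ClinvarSignificance,
    Consequence,
    Consent,
    Participant,
    PGxPanel,
    SubpopFrequency,
    ValidationError,
    VariantRecord,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Planted actionable variants (curated set)
# ---------------------------------------------------------------------------

# Each row: gene, chrom, pos, ref, alt, transcript, hgvs_c, hgvs_p,
# consequence, maf_exac, hgmd, evidence codes, risk-allele flag,
# expected classification.
CURATED_ACTIONABLE = [
    ("SDHB", "1", 17355000, "A", "AA", "NM_003000", "c.71dupA", "p.A25fs",
     Consequence.FRAMESHIFT_INS, 0.0, False, "PVS1,PM2", False,
     "likely_pathogenic"),
    ("SDHB", "1", 17356000, "G", "A", "NM_003000", "c.137G>A", "p.R46Q",
     Consequence.MISSENSE, 0.0001, False, "PS3,PS4:moderate,PP3,PP5", False,
     "likely_pathogenic"),
    ("APC", "5", 112175000, "T", "A", "NM_001127510", "c.3920T>A", "p.I1307K",
     Consequence.MISSENSE, 0.0015, True, "PS3,PS4", True, "risk_allele"),
    ("BRCA1", "17", 41209000, "C", "G", "NM_007294", "c.4689C>G", "p.Y1563*",
     Consequence.NONSENSE, 0.0, False, "PVS1,PS4:moderate,PM2", False,
     "pathogenic"),
    ("MUTYH", "1", 45798000, "C", "T", "NM_012222", "c.724C>T", "p.R242C",
     Consequence.MISSENSE, 0.0008, True, "PS3,PS4:moderate,PM2,PM3", False,
     "pathogenic"),
    ("ABCC8", "11", 17450000, "G", "A", "NM_000352", "c.1562G>A", "p.R521Q",
     Consequence.MISSENSE, 0.0001, True, "PS4:moderate,PM2,PM5,PP2", False,
     "likely_pathogenic"),
    ("HNF1A", "12", 121432000, "G", "A", "NM_000545", "c.476G>A", "p.R159Q",
     Consequence.MISSENSE, 0.0, True, "PS3,PS4,PM2,PP1,PP3", False,
     "pathogenic"),
    ("PROS1", "3", 93600000, "A", "G", "NM_000313", "c.586A>G", "p.K196E",
     Consequence.MISSENSE, 0.0012, True, "PS3,PS4,PP5", False, "pathogenic"),
    ("CHEK2", "22", 29091000, "A", "AA", "NM_001005735", "c.1497dupA",
     "p.E500fs", Consequence.FRAMESHIFT_INS, 0.0, False, "PVS1,PM2", False,
     "likely_pathogenic"),
    ("RBM20", "10", 112572000, "C", "T", "NM_001134363", "c.1898C>T",
     "p.P633L", Consequence.MISSENSE, 0.0, False, "PM1,PM2,PP1,PP3", False,
     "likely_pathogenic"),
    ("SLC7A9", "19", 33350000, "G", "A", "NM_014270", "c.544G>A", "p.A182T",
     Consequence.MISSENSE, 0.0011, True, "PS3,PS4", False, "pathogenic"),
]

#: Planting order over 12 participant slots; the APC founder allele is
#: carried by two participants.
_SLOT_VARIANTS = [0, 1, 2, 2, 3, 4, 5, 6, 7, 8, 9, 10]
_HNF1A_SLOT = 7   # personal and family history of diabetes
_RBM20_SLOT = 10  # family history of dilated cardiomyopathy

APOE_LOCI = {
    "rs429358": ("19", 45411941, "T", "C", 0.14),
    "rs7412": ("19", 45412079, "C", "T", 0.075),
}

#: Autosomal recessive genes used for carrier planting (disjoint from the
#: curated actionable genes and from the background pool).
CARRIER_GENES = [
    "ACADM", "ALDOB", "ARSA", "ASL", "ASPA", "BLM", "BTD", "CBS", "CFTR",
    "CPT2", "DHCR7", "FANCC", "G6PC", "GAA", "GALT", "GBA", "GBE1", "GJB2",
    "HBB", "HEXA", "IDUA", "MCOLN1", "MYO7A", "NPC1", "PAH", "POLG",
    "SLC26A4", "SMPD1", "TYR", "USH2A",
]

#: Ordinary OMIM Mendelian genes that soak up the benign background.
BACKGROUND_GENES = [
    "ABCA12", "AGRN", "CAPN3", "COL7A1", "DNAH5", "DST", "DYSF", "EVC",
    "FKTN", "HSPG2", "LAMA2", "LAMB2", "MACF1", "NEB", "OBSCN", "PLEC",
    "POMT1", "SGCA", "SYNE1", "WDR19",
]

#: OMIM exception-category genes planted in the background so the
#: gene-list and gene-evidence filters both do visible work.
EXCEPTION_GENES = ["CD36", "FUT2", "KLKB1", "PTPN22", "TCF7L2", "IL23R",
                   "CLCN2", "NME8"]

_POOL_GENES = sorted(set(CARRIER_GENES) | set(BACKGROUND_GENES) | set(EXCEPTION_GENES))
#: Stable synthetic locus per pool gene: cycled chromosome, spaced bases.
GENE_LOCI = {
    gene: (str((i % 22) + 1), 2_000_000 + 100_000 * i)
    for i, gene in enumerate(_POOL_GENES)
}

_SNV_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
              ("A", "C"), ("G", "T")]

_ETHNICITIES = ["Caucasian", "Southeast Asian", "Indian",
                "African-American", "Hispanic"]
_ETHNICITY_P = [48 / 70, 8 / 70, 6 / 70, 5 / 70, 3 / 70]


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the generated cohort."""

    n_participants: int = 70
    background_mean: float = 30.0
    background_common_fraction: float = 0.8
    plant_curated_set: bool = True
    n_carrier_variants: int = 150
    n_carrier_participants: int = 60
    n_apoe_e4_participants: int = 21
    n_apoe_overlap_carriers: int = 18
    pgx_panel_size: int = 28
    pgx_min_per_participant: int = 1
    pgx_max_per_participant: int = 6
    consent_none: float = 0.05
    consent_actionable_only: float = 0.25
    consent_all: float = 0.70
    n_apoe_requested: int = 2
    seed: int = 1

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.plant_curated_set and self.n_participants < len(_SLOT_VARIANTS):
            raise ValidationError(
                "planting the curated actionable set requires at least "
                f"{len(_SLOT_VARIANTS)} participants"
            )
        if self.n_carrier_participants > self.n_participants:
            raise ValidationError("more carrier participants than participants")
        if self.n_carrier_participants and (
            self.n_carrier_variants < self.n_carrier_participants
        ):
            raise ValidationError(
                "n_carrier_variants must cover every carrier participant"
            )
        if self.n_carrier_variants > self.n_carrier_participants * len(CARRIER_GENES):
            raise ValidationError("carrier planting exceeds gene-pool capacity")
        if self.n_apoe_e4_participants > self.n_participants:
            raise ValidationError("more APOE e4 participants than participants")
        if self.n_apoe_overlap_carriers > min(
            self.n_carrier_participants, self.n_apoe_e4_participants
        ):
            raise ValidationError(
                "carrier/APOE overlap exceeds the smaller planted set"
            )
        if (self.n_apoe_e4_participants - self.n_apoe_overlap_carriers) > (
            self.n_participants - self.n_carrier_participants
        ):
            raise ValidationError("not enough non-carriers for APOE planting")
        if self.pgx_panel_size < 0 or self.pgx_panel_size > 28:
            raise ValidationError("pgx_panel_size must lie in [0, 28]")
        if self.pgx_panel_size and not (
            1 <= self.pgx_min_per_participant
            <= self.pgx_max_per_participant
            <= self.pgx_panel_size
        ):
            raise ValidationError("invalid per-participant PGx range")
        total = self.consent_none + self.consent_actionable_only + self.consent_all
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("consent mix must sum to 1")


def curated_fixture_config(seed: int = 1) -> SyntheticConfig:
    """Preset planting only the curated actionable variants over a benign
    background (no carriers, no APOE e4, no PGx genotypes)."""
    return SyntheticConfig(
        plant_curated_set=True,
        n_carrier_variants=0,
        n_carrier_participants=0,
        n_apoe_e4_participants=0,
        n_apoe_overlap_carriers=0,
        pgx_panel_size=0,
        seed=seed,
    )


@dataclass
class TruthTable:
    """What was planted, per participant, and the categories the pipeline
    is expected to recover."""

    participants: list = field(default_factory=list)
    actionable: dict = field(default_factory=dict)       # pid -> [{gene,key,label}]
    carrier: dict = field(default_factory=dict)          # pid -> [{gene,key}]
    apoe_diplotype: dict = field(default_factory=dict)   # pid -> "e3/e4"
    apoe_e4: list = field(default_factory=list)
    pgx: dict = field(default_factory=dict)              # pid -> [rsid,...]
    expected_categories: dict = field(default_factory=dict)
    background_keys: list = field(default_factory=list)
    common_background_keys: list = field(default_factory=list)

    @property
    def both_carrier_and_apoe(self) -> list:
        return sorted(set(self.carrier) & set(self.apoe_e4))

    @property
    def nonactionable_participants(self) -> list:
        out = set(self.carrier) | set(self.apoe_e4)
        for pid, cats in self.expected_categories.items():
            if "nonactionable_risk" in cats:
                out.add(pid)
        return sorted(out)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    variants: list
    participants: list
    evidence: list
    truth: TruthTable
    catalog: dict
    panel: Optional[PGxPanel]
    panel_table: Optional[object]

    def write(self, out_dir) -> dict:
        """Write the cohort in the formats the pipeline reads; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "participants": out / "participants.tsv",
            "evidence": out / "evidence.tsv",
            "genes": out / "genes.tsv",
            "truth": out / "truth.json",
        }
        write_cohort_vcf(
            self.variants, paths["vcf"], samples=[p.id for p in self.participants]
        )
        write_participant_table(self.participants, paths["participants"])
        write_evidence_table(
            sorted(self.evidence, key=lambda a: a.variant_key), paths["evidence"]
        )
        write_gene_table(self.catalog, paths["genes"])
        self.truth.to_json(paths["truth"])
        if self.panel_table is not None:
            paths["panel"] = out / "pgx_panel.tsv"
            self.panel_table.to_csv(paths["panel"], sep="\t", index=False)
        return paths


def build_curated_fixture(
    participant_ids: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Emit the curated actionable variants and their evidence assignments.

    Returns (records, evidence assignments, per-participant history terms).
    Twelve participant slots are filled in planting order; the APC founder
    variant occupies two slots. The participants planted with the
    monogenic-diabetes and dilated-cardiomyopathy variants receive the
    matching personal/family-history terms so the history trigger has work.
    """
    if participant_ids is None:
        participant_ids = [f"P{i:03d}" for i in range(1, 13)]
    if len(participant_ids) != len(_SLOT_VARIANTS):
        raise ValidationError(
            f"the curated fixture needs exactly {len(_SLOT_VARIANTS)} participants"
        )
    rng = rng or np.random.default_rng(0)
    records: list[VariantRecord] = []
    evidence: dict[str, EvidenceAssignment] = {}
    history: dict[str, dict] = {}
    annotations: dict[int, AnnotationBlock] = {}
    for slot, var_idx in enumerate(_SLOT_VARIANTS):
        (gene, chrom, pos, ref, alt, transcript, hgvs_c, hgvs_p, csq,
         maf_exac, hgmd, codes, risk, _label) = CURATED_ACTIONABLE[var_idx]
        if var_idx not in annotations:
            annotations[var_idx] = AnnotationBlock(
                gene_symbol=gene,
                transcript=transcript,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                consequence=csq,
                maf_1000g=0.0,
                maf_exac=maf_exac,
                clinvar_significance=ClinvarSignificance.ABSENT,
                clinvar_stars=0,
                hgmd_dm_match=hgmd,
            )
        pid = participant_ids[slot]
        rec = VariantRecord(
            participant_id=pid,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            phred_qual=60.0,
            depth=int(rng.integers(25, 90)),
            zygosity=Zygosity.HET,
            annotation=annotations[var_idx],
        )
        records.append(rec)
        if rec.key not in evidence:
            evidence[rec.key] = EvidenceAssignment(
                variant_key=rec.key,
                codes=parse_codes(codes),
                risk_allele=risk,
                notes=f"{gene} {hgvs_c} ({hgvs_p})",
            )
        if slot == _HNF1A_SLOT:
            history[pid] = {
                "phenotype": ("diabetes mellitus",),
                "family": ("diabetes mellitus",),
            }
        if slot == _RBM20_SLOT:
            history[pid] = {
                "phenotype": (),
                "family": ("dilated cardiomyopathy",),
            }
    return records, list(evidence.values()), history


def plant_pgx_genotypes(
    participant_ids: Sequence[str],
    panel_table,
    rng: np.random.Generator,
    lo: int = 1,
    hi: int = 6,
):
    """Plant per-participant non-reference genotypes at panel rsIDs.

    Each participant receives a number of non-reference panel genotypes
    drawn uniformly from [lo, hi]. Returns (variant records, truth mapping
    pid -> sorted rsIDs)."""
    rows = list(panel_table.itertuples(index=False))
    annotations = {}
    for row in rows:
        annotations[row.rsid] = AnnotationBlock(
            gene_symbol=row.gene,
            consequence=Consequence.OTHER_NONCODING,
            maf_1000g=float(row.maf),
            maf_exac=float(row.maf),
            rsid=row.rsid,
        )
    records = []
    truth: dict[str, list] = {}
    for pid in participant_ids:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(rows), size=k, replace=False)
        rsids = []
        for idx in sorted(int(i) for i in chosen):
            row = rows[idx]
            zyg = Zygosity.HOM_ALT if rng.random() < 0.15 else Zygosity.HET
            records.append(
                VariantRecord(
                    participant_id=pid,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    phred_qual=60.0,
                    depth=int(rng.integers(25, 90)),
                    zygosity=zyg,
                    annotation=annotations[row.rsid],
                )
            )
            rsids.append(row.rsid)
        truth[pid] = sorted(rsids)
    return records, truth


def _apoe_records(pid, diplotype, rng, annotations):
    """Variant records encoding one participant's APOE diplotype at the two
    defining SNPs (only non-reference genotypes become records)."""
    n_e4 = diplotype.count("e4")
    n_e2 = diplotype.count("e2")
    records = []
    for rsid, count in (("rs429358", n_e4), ("rs7412", n_e2)):
        if count == 0:
            continue
        chrom, pos, ref, alt, _maf = APOE_LOCI[rsid]
        records.append(
            VariantRecord(
                participant_id=pid,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                phred_qual=60.0,
                depth=int(rng.integers(25, 90)),
                zygosity=Zygosity.HOM_ALT if count == 2 else Zygosity.HET,
                annotation=annotations[rsid],
            )
        )
    return records


_BACKGROUND_CSQ = [
    (Consequence.MISSENSE, 0.55),
    (Consequence.SYNONYMOUS, 0.15),
    (Consequence.OTHER_NONCODING, 0.08),
    (Consequence.NONSENSE, 0.06),
    (Consequence.CANONICAL_SPLICE, 0.05),
    (Consequence.INFRAME_INDEL, 0.05),
    (Consequence.FRAMESHIFT_DEL, 0.06),
]


def generate_cohort(config: Optional[SyntheticConfig] = None) -> SyntheticCohort:
    """Generate a full annotated cohort with a known truth table."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = load_default_gene_table()
    full_panel, full_panel_table = load_default_pgx_panel()

    n = config.n_participants
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    consent_labels = ["none", "actionable_only", "all_medically_relevant"]
    consent_p = [config.consent_none, config.consent_actionable_only, config.consent_all]

    pdata = {}
    for pid in ids:
        pdata[pid] = {
            "age": int(rng.integers(34, 77)),
            "sex": "male" if rng.random() < 36 / 70 else "female",
            "ethnicity": _ETHNICITIES[int(rng.choice(len(_ETHNICITIES), p=_ETHNICITY_P))],
            "phenotype": (),
            "family": (),
            "consent": consent_labels[int(rng.choice(3, p=consent_p))],
            "apoe_requested": False,
        }
    if config.n_apoe_requested:
        chosen = rng.choice(n, size=min(config.n_apoe_requested, n), replace=False)
        for idx in sorted(int(i) for i in chosen):
            pdata[ids[idx]]["consent"] = "all_medically_relevant"
            pdata[ids[idx]]["apoe_requested"] = True

    variants: list[VariantRecord] = []
    evidence: dict[str, EvidenceAssignment] = {}
    truth = TruthTable(participants=list(ids))
    for pid in ids:
        truth.expected_categories[pid] = []

    def add_category(pid, cat):
        if cat not in truth.expected_categories[pid]:
            truth.expected_categories[pid].append(cat)

    # --- curated actionable set ------------------------------------------
    if config.plant_curated_set:
        slot_idx = rng.choice(n, size=len(_SLOT_VARIANTS), replace=False)
        slot_ids = [ids[int(i)] for i in slot_idx]
        records, assignments, history = build_curated_fixture(slot_ids, rng)
        variants.extend(records)
        for a in assignments:
            evidence[a.variant_key] = a
        for pid, terms in history.items():
            pdata[pid]["phenotype"] = terms["phenotype"]
            pdata[pid]["family"] = terms["family"]
        for slot, rec in zip(range(len(_SLOT_VARIANTS)), records):
            label = CURATED_ACTIONABLE[_SLOT_VARIANTS[slot]][-1]
            truth.actionable.setdefault(rec.participant_id, []).append(
                {"gene": rec.annotation.gene_symbol, "key": rec.key, "label": label}
            )
            add_category(rec.participant_id, "actionable")

    # --- recessive-disease carriers --------------------------------------
    carrier_ids: list[str] = []
    if config.n_carrier_participants:
        chosen = rng.choice(n, size=config.n_carrier_participants, replace=False)
        carrier_ids = [ids[int(i)] for i in sorted(int(i) for i in chosen)]
        counts = {pid: 1 for pid in carrier_ids}
        extra = config.n_carrier_variants - config.n_carrier_participants
        capacity = len(CARRIER_GENES)
        while extra > 0:
            pid = carrier_ids[int(rng.integers(0, len(carrier_ids)))]
            if counts[pid] < capacity:
                counts[pid] += 1
                extra -= 1
        carrier_annotations: dict[tuple, AnnotationBlock] = {}
        for pid in carrier_ids:
            gene_idx = rng.choice(len(CARRIER_GENES), size=counts[pid], replace=False)
            for gi in sorted(int(g) for g in gene_idx):
                gene = CARRIER_GENES[gi]
                k = int(rng.integers(0, 6))
                chrom, base = GENE_LOCI[gene]
                pos = base + 100 * k
                ref, alt = "C", "T"
                site = (gene, k)
                if site not in carrier_annotations:
                    carrier_annotations[site] = AnnotationBlock(
                        gene_symbol=gene,
                        transcript=f"NM_{900000 + gi:06d}",
                        hgvs_c=f"c.{100 + 3 * k}C>T",
                        hgvs_p=f"p.Q{34 + k}*",
                        consequence=Consequence.NONSENSE,
                        maf_exac=0.0002,
                        hgmd_dm_match=True,
                    )
                rec = VariantRecord(
                    participant_id=pid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    phred_qual=60.0,
                    depth=int(rng.integers(20, 90)),
                    zygosity=Zygosity.HET,
                    annotation=carrier_annotations[site],
                )
                variants.append(rec)
                if rec.key not in evidence:
                    codes = "PVS1,PM2,PM3" if k % 2 == 0 else "PVS1,PM2"
                    evidence[rec.key] = EvidenceAssignment(
                        variant_key=rec.key, codes=parse_codes(codes),
                        notes=f"{gene} carrier allele",
                    )
                truth.carrier.setdefault(pid, []).append(
                    {"gene": gene, "key": rec.key}
                )
                add_category(pid, "carrier")
                if gene == "GBA":
                    add_category(pid, "nonactionable_risk")

    # --- APOE diplotypes --------------------------------------------------
    apoe_annotations = {
        rsid: AnnotationBlock(
            gene_symbol="APOE",
            consequence=Consequence.MISSENSE,
            maf_1000g=maf,
            maf_exac=maf,
            rsid=rsid,
        )
        for rsid, (_c, _p, _r, _a, maf) in APOE_LOCI.items()
    }
    if config.n_apoe_e4_participants:
        from_carriers = rng.choice(
            len(carrier_ids), size=config.n_apoe_overlap_carriers, replace=False
        ) if config.n_apoe_overlap_carriers else []
        e4_ids = {carrier_ids[int(i)] for i in from_carriers}
        non_carriers = [pid for pid in ids if pid not in set(carrier_ids)]
        n_rest = config.n_apoe_e4_participants - len(e4_ids)
        rest = rng.choice(len(non_carriers), size=n_rest, replace=False)
        e4_ids |= {non_carriers[int(i)] for i in rest}
        e4_options = ["e3/e4", "e4/e4", "e2/e4"]
        other_options = ["e3/e3", "e2/e3", "e2/e2"]
        any_e2 = False
        for pid in ids:
            if pid in e4_ids:
                dip = e4_options[int(rng.choice(3, p=[0.7, 0.2, 0.1]))]
            else:
                dip = other_options[int(rng.choice(3, p=[0.82, 0.15, 0.03]))]
            truth.apoe_diplotype[pid] = dip
            any_e2 = any_e2 or ("e2" in dip)
        if not any_e2:
            # keep both APOE sites present in the VCF
            fallback = next(pid for pid in ids if pid not in e4_ids)
            truth.apoe_diplotype[fallback] = "e2/e3"
        for pid in ids:
            variants.extend(
                _apoe_records(pid, truth.apoe_diplotype[pid], rng, apoe_annotations)
            )
        truth.apoe_e4 = sorted(e4_ids)
        for pid in truth.apoe_e4:
            add_category(pid, "apoe")

    # --- pharmacogenetic panel genotypes ----------------------------------
    panel = None
    panel_table = None
    if config.pgx_panel_size:
        panel_table = full_panel_table.iloc[: config.pgx_panel_size].copy()
        panel = PGxPanel(
            rsids=tuple(panel_table["rsid"]),
            annotations={
                r.rsid: r.annotation for r in panel_table.itertuples(index=False)
            },
        )
        pgx_records, pgx_truth = plant_pgx_genotypes(
            ids,
            panel_table,
            rng,
            config.pgx_min_per_participant,
            config.pgx_max_per_participant,
        )
        variants.extend(pgx_records)
        truth.pgx = pgx_truth
        for pid in ids:
            if pgx_truth.get(pid):
                add_category(pid, "pgx")

    # --- benign background -------------------------------------------------
    bg_pool = sorted(set(BACKGROUND_GENES) | set(EXCEPTION_GENES))
    csq_values = [c for c, _ in _BACKGROUND_CSQ]
    csq_p = [p for _, p in _BACKGROUND_CSQ]
    site_counter: dict[str, int] = {}
    for pid in ids:
        n_bg = int(rng.poisson(config.background_mean))
        for _ in range(n_bg):
            gene = bg_pool[int(rng.integers(0, len(bg_pool)))]
            chrom, base = GENE_LOCI[gene]
            count = site_counter.get(gene, 0)
            site_counter[gene] = count + 1
            pos = base + 50_000 + 10 * count
            csq = csq_values[int(rng.choice(len(csq_values), p=csq_p))]
            ref, alt = _SNV_PAIRS[int(rng.integers(0, len(_SNV_PAIRS)))]
            if csq is Consequence.FRAMESHIFT_DEL:
                ref, alt = ref + alt, ref
            elif csq is Consequence.INFRAME_INDEL:
                ref, alt = ref, ref + "GCA"
            common = rng.random() < config.background_common_fraction
            if common:
                maf_exac = round(float(rng.uniform(0.006, 0.35)), 6)
                maf_1kg = round(float(rng.uniform(0.006, 0.35)), 6)
            else:
                maf_exac = round(float(rng.uniform(0.0, 0.005)), 6)
                maf_1kg = 0.0
            u = rng.random()
            if u < 0.04:
                qual, depth = float(rng.integers(5, 20)), int(rng.integers(15, 80))
            elif u < 0.08:
                qual, depth = float(rng.integers(30, 90)), int(rng.integers(1, 10))
            else:
                qual, depth = float(rng.integers(30, 90)), int(rng.integers(15, 80))
            subpops = ()
            if not common:
                v = rng.random()
                if v < 0.08:
                    subpops = (
                        SubpopFrequency("AFR", round(float(rng.uniform(0.006, 0.02)), 6), 10000),
                    )
                elif v < 0.12:
                    subpops = (
                        SubpopFrequency("EAS", 0.02, 400),
                        SubpopFrequency("AFR", 0.001, 8000),
                    )
            clnsig = ClinvarSignificance.ABSENT
            stars = 0
            if rng.random() < 0.05:
                clnsig = ClinvarSignificance.BENIGN
                stars = int(rng.integers(0, 3))
            rec = VariantRecord(
                participant_id=pid,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                phred_qual=qual,
                depth=depth,
                zygosity=Zygosity.HOM_ALT if rng.random() < 0.1 else Zygosity.HET,
                annotation=AnnotationBlock(
                    gene_symbol=gene,
                    consequence=csq,
                    maf_1000g=maf_1kg,
                    maf_exac=maf_exac,
                    subpop_mafs=subpops,
                    clinvar_significance=clnsig,
                    clinvar_stars=stars,
                ),
            )
            variants.append(rec)
            truth.background_keys.append(rec.key)
            if common:
                truth.common_background_keys.append(rec.key)

    participants = [
        Participant(
            id=pid,
            age=pdata[pid]["age"],
            sex=pdata[pid]["sex"],
            ethnicity=pdata[pid]["ethnicity"],
            phenotype_terms=pdata[pid]["phenotype"],
            family_history_terms=pdata[pid]["family"],
            consent=Consent(pdata[pid]["consent"]),
            apoe_requested=pdata[pid]["apoe_requested"],
        )
        for pid in ids
    ]
    for pid in ids:
        truth.expected_categories[pid] = sorted(truth.expected_categories[pid])

    return SyntheticCohort(
        config=config,
        variants=variants,
        participants=participants,
        evidence=list(evidence.values()),
        truth=truth,
        catalog=catalog,
        panel=panel,
        panel_table=panel_table,
    )
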