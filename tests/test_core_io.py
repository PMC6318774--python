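"""Readers/writers: round-trips, allele decomposition, format errors."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strategies as sts
from factories import make_variant
from exome_triage import core_io
from exome_triage.acmg_engine import Strength
from exome_triage.models import (
    Category,
    ClassificationLabel,
    Consent,
    FilterConfig,
    Finding,
    FormatError,
    ValidationError,
    Zygosity,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=A,Type=String,Description="g">
##INFO=<ID=TRANSCRIPT,Number=A,Type=String,Description="t">
##INFO=<ID=HGVSC,Number=A,Type=String,Description="c">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="p">
##INFO=<ID=CSQCLASS,Number=A,Type=String,Description="csq">
##INFO=<ID=MAF1KG,Number=A,Type=String,Description="m1">
##INFO=<ID=MAFEXAC,Number=A,Type=String,Description="m2">
##INFO=<ID=SUBPOP,Number=A,Type=String,Description="s">
##INFO=<ID=CLNSIG,Number=A,Type=String,Description="cs">
##INFO=<ID=CLNSTARS,Number=A,Type=Integer,Description="st">
##INFO=<ID=HGMDDM,Number=A,Type=Integer,Description="h">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""

MULTIALLELIC_LINE = (
    "1\t100\t.\tG\tA,T\t50\t.\t"
    "GENE=PAH,PAH;TRANSCRIPT=.,.;HGVSC=.,.;HGVSP=.,.;"
    "CSQCLASS=missense,nonsense;MAF1KG=0,0;MAFEXAC=0.001,0.002;"
    "SUBPOP=NA,NA;CLNSIG=absent,absent;CLNSTARS=0,0;HGMDDM=0,1\t"
    "GT:DP\t0/1:30\t0/2:40\n"
)


def test_vcf_round_trip_two_records(tmp_path):
    records = [
        make_variant(participant_id="S1", pos=500, maf_exac=0.005),
        make_variant(
            participant_id="S2",
            pos=900,
            ref="C",
            alt="T",
            zygosity=Zygosity.HOM_ALT,
            gene_symbol="CFTR",
        ),
    ]
    path = tmp_path / "c.vcf"
    core_io.write_cohort_vcf(records, path)
    back = core_io.read_cohort_vcf(path)
    assert sorted(back, key=lambda r: r.pos) == sorted(records, key=lambda r: r.pos)


def test_hom_ref_genotypes_not_emitted(tmp_path):
    path = tmp_path / "c.vcf"
    core_io.write_cohort_vcf(
        [make_variant(participant_id="S1")], path, samples=["S1", "S2"]
    )
    back = core_io.read_cohort_vcf(path)
    assert {r.participant_id for r in back} == {"S1"}


def test_multiallelic_decomposition(tmp_path):
    """A site with two ALT alleles and one het call per allele yields two
    decomposed records with allele-matched annotation."""
    path = tmp_path / "m.vcf"
    path.write_text(VCF_HEADER + MULTIALLELIC_LINE)
    back = core_io.read_cohort_vcf(path)
    assert len(back) == 2
    by_sample = {r.participant_id: r for r in back}
    assert by_sample["S1"].alt == "A"
    assert by_sample["S1"].annotation.consequence.value == "missense"
    assert by_sample["S1"].annotation.maf_exac == 0.001
    assert by_sample["S2"].alt == "T"
    assert by_sample["S2"].annotation.consequence.value == "nonsense"
    assert by_sample["S2"].annotation.hgmd_dm_match is True


def test_het_both_alts_decomposes_to_two_records(tmp_path):
    line = MULTIALLELIC_LINE.replace("0/1:30\t0/2:40", "1/2:30\t0/0:40")
    path = tmp_path / "m.vcf"
    path.write_text(VCF_HEADER + line)
    back = core_io.read_cohort_vcf(path)
    assert len(back) == 2
    assert all(r.participant_id == "S1" for r in back)
    assert {r.alt for r in back} == {"A", "T"}
    assert all(r.zygosity is Zygosity.HET for r in back)


def test_missing_info_key_named_in_error(tmp_path):
    header = VCF_HEADER.replace(
        '##INFO=<ID=GENE,Number=A,Type=String,Description="g">\n', ""
    )
    line = MULTIALLELIC_LINE.replace("GENE=PAH,PAH;", "")
    path = tmp_path / "bad.vcf"
    path.write_text(header + line)
    with pytest.raises(FormatError, match="GENE"):
        core_io.read_cohort_vcf(path)


def test_malformed_vcf_raises_format_error(tmp_path):
    path = tmp_path / "junk.vcf"
    path.write_text("this is not a vcf\n")
    with pytest.raises(FormatError):
        core_io.read_cohort_vcf(path)


@given(sts.variant_lists())
@settings(max_examples=100)
def test_vcf_round_trip_property(tmp_path_factory, records):
    """Write-then-read is the identity on any valid cohort (as a set of
    decomposed records; VCF imposes its own site ordering)."""
    path = tmp_path_factory.mktemp("rt") / "c.vcf"
    core_io.write_cohort_vcf(records, path)
    back = core_io.read_cohort_vcf(path)
    key = lambda r: (r.participant_id, r.chrom, r.pos, r.ref, r.alt)
    assert sorted(back, key=key) == sorted(records, key=key)


@given(st.lists(sts.genes, max_size=8, unique_by=lambda g: g.symbol))
@settings(max_examples=100)
def test_gene_table_round_trip_property(tmp_path_factory, gene_list):
    path = tmp_path_factory.mktemp("rt") / "genes.tsv"
    catalog = {g.symbol: g for g in gene_list}
    core_io.write_gene_table(catalog, path)
    assert core_io.read_gene_table(path) == catalog


@given(st.lists(sts.participants, max_size=8, unique_by=lambda p: p.id))
@settings(max_examples=100)
def test_participant_table_round_trip_property(tmp_path_factory, people):
    path = tmp_path_factory.mktemp("rt") / "participants.tsv"
    core_io.write_participant_table(people, path)
    assert core_io.read_participant_table(path) == people


@given(st.lists(sts.evidence_assignments, max_size=8, unique_by=lambda a: a.variant_key))
@settings(max_examples=100)
def test_evidence_table_round_trip_property(tmp_path_factory, assignments):
    path = tmp_path_factory.mktemp("rt") / "evidence.tsv"
    core_io.write_evidence_table(assignments, path)
    assert core_io.read_evidence_table(path) == assignments


def test_duplicate_gene_symbol_rejected(tmp_path, catalog):
    path = tmp_path / "genes.tsv"
    gene = catalog["PAH"]
    core_io.write_gene_table({"PAH": gene}, path)
    text = path.read_text()
    path.write_text(text + text.splitlines()[1] + "\n")
    with pytest.raises(ValidationError, match="duplicate"):
        core_io.read_gene_table(path)


def test_unknown_inheritance_token_rejected(tmp_path, catalog):
    path = tmp_path / "genes.tsv"
    core_io.write_gene_table({"PAH": catalog["PAH"]}, path)
    path.write_text(path.read_text().replace("AR", "ZZ"))
    with pytest.raises(ValidationError, match="inheritance"):
        core_io.read_gene_table(path)


def test_empty_gene_table_warns(tmp_path, caplog):
    path = tmp_path / "genes.tsv"
    core_io.write_gene_table({}, path)
    with caplog.at_level(logging.WARNING):
        assert core_io.read_gene_table(path) == {}
    assert any("empty" in r.message for r in caplog.records)


def test_unknown_consent_token_rejected(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "id\tage\tsex\tethnicity\tphenotype_terms\tfamily_history_terms\t"
        "consent\tapoe_requested\nP1\t40\tmale\t\t\t\tmaybe\tfalse\n"
    )
    with pytest.raises(ValueError):
        core_io.read_participant_table(path)


def test_evidence_override_round_trips(tmp_path):
    path = tmp_path / "e.tsv"
    path.write_text("variant_key\tcodes\trisk_allele\tnotes\nk1\tPS4:moderate,PM2\tfalse\t\n")
    (assignment,) = core_io.read_evidence_table(path)
    ps4 = next(c for c in assignment.codes if c.code == "PS4")
    assert ps4.override_strength is Strength.MODERATE


def test_findings_report_round_trip(tmp_path):
    findings = [
        Finding("P001", "1:100:A:G", "BRCA1", ClassificationLabel.PATHOGENIC,
                Category.ACTIONABLE, Zygosity.HET, True, "breast cancer risk"),
        Finding("P002", "2:200:C:T", "PAH", ClassificationLabel.LIKELY_PATHOGENIC,
                Category.CARRIER, Zygosity.HET, False, "carrier"),
        Finding("P003", "rs4244285", "", ClassificationLabel.NOT_CLASSIFIED,
                Category.PGX, Zygosity.HOM_ALT, True, "clopidogrel"),
    ]
    tsv, js = tmp_path / "f.tsv", tmp_path / "f.json"
    core_io.write_findings_report(findings, tsv, js)
    assert core_io.read_findings_report(tsv) == findings
    assert js.exists()


def test_filter_config_yaml_round_trip(tmp_path):
    cfg = FilterConfig(maf_threshold=0.01, phred_min=30)
    path = tmp_path / "cfg.yaml"
    core_io.save_filter_config(cfg, path)
    assert core_io.load_filter_config(path) == cfg
    path.write_text("unknown_knob: 1\n")
    with pytest.raises(ValidationError, match="unknown_knob"):
        core_io.load_filter_config(path)


def test_consent_none_participant_gets_nothing_returned(tmp_path):
    """Opt-out participants parse fine and the return gate blanks them."""
    from exome_triage.findings_reporter import apply_return_preferences
    from factories import make_participant

    p = make_participant(consent=Consent.NONE)
    f = Finding("P001", "1:100:A:G", "BRCA1", ClassificationLabel.PATHOGENIC,
                Category.ACTIONABLE, Zygosity.HET, False, "")
    (gated,) = apply_return_preferences([f], p)
    assert gated.returned is False
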