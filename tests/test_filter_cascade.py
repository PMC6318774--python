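"""Filter cascade: per-stage rules, rescue, queue triggers, conservation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strategies as sts
from factories import make_gene, make_participant, make_variant
from exome_triage.filter_cascade import (
    apply_consequence_filter,
    apply_gene_list_filter,
    apply_maf_filter,
    apply_quality_filter,
    build_curation_queue,
    clinvar_rescue,
    gene_evidence_filter,
    phenotype_consistency_filter,
    run_filter_cascade,
    subpopulation_maf_check,
)
from exome_triage.models import (
    ClinvarSignificance,
    Consequence,
    FilterConfig,
    SubpopFrequency,
    Zygosity,
)

CFG = FilterConfig()


@pytest.mark.parametrize(
    "qual, depth, kept",
    [
        (20.0, 10, True),   # minima are inclusive
        (19.0, 50, False),
        (60.0, 9, False),
        (19.9, 9, False),
    ],
)
def test_quality_filter(qual, depth, kept):
    out = apply_quality_filter([make_variant(phred_qual=qual, depth=depth)], CFG)
    assert bool(out) is kept


def test_quality_filter_empty_input():
    assert apply_quality_filter([], CFG) == []


@pytest.mark.parametrize(
    "csq, kept",
    [
        (Consequence.SYNONYMOUS, False),
        (Consequence.CANONICAL_SPLICE, True),
        (Consequence.OTHER_NONCODING, False),
        (Consequence.MISSENSE, True),
        (Consequence.FRAMESHIFT_DEL, True),
    ],
)
def test_consequence_filter(csq, kept):
    out = apply_consequence_filter([make_variant(consequence=csq)])
    assert bool(out) is kept


@pytest.mark.parametrize(
    "maf_1kg, maf_exac, excluded",
    [
        (0.0, 0.006, True),    # either database above threshold excludes
        (0.006, 0.0, True),
        (0.005, 0.005, False), # boundary is strictly greater-than
        (0.0, 0.0, False),     # absent from both databases = rare
    ],
)
def test_maf_filter(maf_1kg, maf_exac, excluded):
    kept, dropped = apply_maf_filter(
        [make_variant(maf_1000g=maf_1kg, maf_exac=maf_exac)], CFG
    )
    assert bool(dropped) is excluded
    assert len(kept) + len(dropped) == 1


@pytest.mark.parametrize(
    "sig, stars, rescued",
    [
        (ClinvarSignificance.PATHOGENIC, 2, True),
        (ClinvarSignificance.LIKELY_PATHOGENIC, 3, True),
        (ClinvarSignificance.PATHOGENIC, 1, False),
        (ClinvarSignificance.BENIGN, 4, False),
        (ClinvarSignificance.ABSENT, 0, False),
    ],
)
def test_clinvar_rescue(sig, stars, rescued):
    v = make_variant(maf_exac=0.012, clinvar_significance=sig, clinvar_stars=stars)
    assert bool(clinvar_rescue([v], CFG)) is rescued


def test_rescue_set_disjoint_from_maf_kept():
    common_rescueable = make_variant(
        pos=10, maf_exac=0.012,
        clinvar_significance=ClinvarSignificance.PATHOGENIC, clinvar_stars=2,
    )
    rare = make_variant(pos=20, maf_exac=0.0001)
    kept, excluded = apply_maf_filter([common_rescueable, rare], CFG)
    rescued = clinvar_rescue(excluded, CFG)
    assert {v.key for v in rescued} <= {v.key for v in excluded}
    assert not ({v.key for v in rescued} & {v.key for v in kept})


def test_gene_list_filter(catalog):
    brace_only = make_variant(pos=10, gene_symbol="TCF7L2")   # multifactorial
    acmg59_exception = make_variant(pos=20, gene_symbol="APC")
    unknown = make_variant(pos=30, gene_symbol="NOSUCHGENE")
    mendelian = make_variant(pos=40, gene_symbol="PAH")
    kept = apply_gene_list_filter(
        [brace_only, acmg59_exception, unknown, mendelian], catalog
    )
    assert {v.annotation.gene_symbol for v in kept} == {"APC", "PAH"}


def test_subpop_check_removes_well_supported_high_frequency():
    v = make_variant(subpop_mafs=(SubpopFrequency("AFR", 0.008, 10_000),))
    keep, decisive = subpopulation_maf_check(v, CFG)
    assert keep is False
    assert decisive.label == "AFR"


def test_subpop_check_small_sample_falls_back_to_next_entry():
    """A frequency backed by one alt allele in 500 is skipped; the
    next-highest subpopulation decides."""
    v = make_variant(
        subpop_mafs=(
            SubpopFrequency("EAS", 0.002, 500),
            SubpopFrequency("AFR", 0.001, 5_000),
        )
    )
    keep, decisive = subpopulation_maf_check(v, CFG)
    assert keep is True
    assert decisive.label == "AFR"


def test_subpop_check_no_data_keeps():
    keep, decisive = subpopulation_maf_check(make_variant(), CFG)
    assert keep is True and decisive is None


def test_phenotype_filter_removes_dominant_het_without_phenotype():
    gene = make_gene(symbol="XDOM", inheritance=frozenset({"AD"}),
                     phenotype_terms=("severe childhood disease",))
    v = make_variant(gene_symbol="XDOM")
    p = make_participant()
    assert phenotype_consistency_filter(v, gene, p) is False


def test_phenotype_filter_keeps_carrier_genotype_in_recessive_gene():
    gene = make_gene(phenotype_terms=("phenylketonuria",))
    v = make_variant()  # het in an AR-only gene: not disease-consistent
    assert phenotype_consistency_filter(v, gene, make_participant()) is True


def test_phenotype_filter_keeps_when_phenotype_matches():
    gene = make_gene(symbol="XDOM", inheritance=frozenset({"AD"}),
                     phenotype_terms=("severe childhood disease",))
    v = make_variant(gene_symbol="XDOM")
    p = make_participant(phenotype_terms=("severe childhood disease",))
    assert phenotype_consistency_filter(v, gene, p) is True


def test_phenotype_filter_age_related_penetrance_exemption():
    gene = make_gene(symbol="XDOM", inheritance=frozenset({"AD"}),
                     full_penetrance_age=60)
    v = make_variant(gene_symbol="XDOM")
    assert phenotype_consistency_filter(v, gene, make_participant(age=45)) is True
    assert phenotype_consistency_filter(v, gene, make_participant(age=70)) is False


def test_gene_evidence_filter(catalog):
    assert gene_evidence_filter(make_variant(), catalog["CLCN2"]) is False
    assert gene_evidence_filter(make_variant(), catalog["BRCA1"]) is True
    assert gene_evidence_filter(make_variant(), catalog["PAH"]) is True


def test_queue_triggers(catalog):
    participants = {
        "P001": make_participant(),
        "P002": make_participant(
            id="P002", family_history_terms=("dilated cardiomyopathy",)
        ),
    }
    no_trigger = make_variant(pos=10, gene_symbol="PAH", hgmd_dm_match=False)
    lof = make_variant(pos=20, gene_symbol="PAH",
                       consequence=Consequence.FRAMESHIFT_INS, ref="A", alt="AT")
    history = make_variant(pos=30, gene_symbol="RBM20", participant_id="P002")
    rescued = make_variant(pos=40, gene_symbol="PAH")
    acmg59 = make_variant(pos=50, gene_symbol="BRCA1",
                          hgmd_dm_match=True)
    queue = build_curation_queue(
        [no_trigger, lof, history, rescued, acmg59],
        catalog,
        participants,
        rescued_keys={rescued.key},
    )
    triggers = {e.variant.pos: set(e.triggers) for e in queue}
    assert 10 not in triggers
    assert triggers[20] == {"LoF"}
    assert triggers[30] == {"history"}
    assert triggers[40] == {"rescue"}
    assert triggers[50] == {"HGMD", "ACMG59"}


def test_quality_and_consequence_filters_commute():
    variants = [
        make_variant(pos=10 * i, phred_qual=q, depth=d, consequence=c)
        for i, (q, d, c) in enumerate(
            [
                (60, 40, Consequence.MISSENSE),
                (10, 40, Consequence.MISSENSE),
                (60, 5, Consequence.SYNONYMOUS),
                (60, 40, Consequence.OTHER_NONCODING),
                (5, 2, Consequence.NONSENSE),
            ],
            start=1,
        )
    ]
    a = apply_consequence_filter(apply_quality_filter(variants, CFG))
    b = apply_quality_filter(apply_consequence_filter(variants), CFG)
    assert a == b


@given(sts.variant_lists(max_size=12))
@settings(max_examples=60)
def test_cascade_shrinkage_and_conservation(catalog, variants):
    """Every stage's output is a subset of its input and counts are
    conserved (in = kept + removed), on arbitrary input cohorts."""
    result = run_filter_cascade(variants, catalog, [make_participant()])
    for entry in result.audit:
        assert entry.n_in == entry.n_kept + entry.n_removed
        if entry.stage not in ("clinvar_rescue",):
            assert entry.n_kept <= entry.n_in
    input_keyset = {(v.participant_id, v.key) for v in variants}
    assert {(v.participant_id, v.key) for v in result.survivors} <= input_keyset
    assert {(e.variant.participant_id, e.variant.key) for e in result.queue} <= {
        (v.participant_id, v.key) for v in result.survivors
    }


def test_planted_actionable_variants_all_queued(curated_cohort, curated_result):
    """Every planted curated variant survives the cascade and is queued."""
    queued = {(e.variant.participant_id, e.variant.key) for e in curated_result.cascade.queue}
    for pid, entries in curated_cohort.truth.actionable.items():
        for entry in entries:
            assert (pid, entry["key"]) in queued


def test_common_benign_background_fully_excluded(curated_cohort, curated_result):
    """Background variants above the MAF threshold without rescue
    credentials never survive the cascade."""
    survivor_keys = {v.key for v in curated_result.cascade.survivors}
    common = set(curated_cohort.truth.common_background_keys)
    assert len(common) > 500  # the spectrum really is mostly common
    assert not (common & survivor_keys)


def test_artifact_blacklist_removes_sites(catalog):
    v1 = make_variant(pos=10)
    v2 = make_variant(pos=20)
    result = run_filter_cascade(
        [v1, v2], catalog, [make_participant()], artifact_blacklist=[v1.key]
    )
    assert {v.key for v in result.survivors} == {v2.key}
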