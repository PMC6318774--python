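"""Finding categorization, APOE diplotyping, panel lookups, consent gating."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from factories import make_gene, make_participant, make_variant
from exome_triage.core_io import SiteGenotypes
from exome_triage.findings_reporter import (
    ClassifiedVariant,
    apply_return_preferences,
    call_apoe,
    detect_carrier,
    determine_actionability,
    flag_nonactionable_risk,
    pgx_findings,
)
from exome_triage.models import (
    Category,
    ClassificationLabel as L,
    Consent,
    Finding,
    PGxPanel,
    Zygosity,
)


def _mutyh_like():
    return make_gene(
        symbol="MUTYH",
        inheritance=frozenset({"AR"}),
        actionable_disease="polyposis / colon cancer risk",
        penetrance_class="moderate",
        onset_class="adult",
        het_risk_actionable=True,
    )


def _ar_carrier_gene(symbol="PAH", **kw):
    return make_gene(symbol=symbol, **kw)


class TestActionability:
    def test_het_pathogenic_with_guideline_backed_het_risk(self):
        v = make_variant(gene_symbol="MUTYH")
        assert determine_actionability(v, L.PATHOGENIC, _mutyh_like()) is True

    def test_het_pathogenic_in_ordinary_recessive_gene_is_not_actionable(self):
        gene = _ar_carrier_gene(actionable_disease="phenylketonuria",
                                penetrance_class="high")
        v = make_variant()
        assert determine_actionability(v, L.PATHOGENIC, gene) is False

    def test_risk_allele_in_managed_gene_is_actionable(self):
        gene = make_gene(symbol="APC", inheritance=frozenset({"AD"}),
                         actionable_disease="colon cancer risk",
                         penetrance_class="moderate", onset_class="adult")
        v = make_variant(gene_symbol="APC")
        assert determine_actionability(v, L.RISK_ALLELE, gene) is True

    def test_presumed_compound_het_in_recessive_gene(self):
        gene = _ar_carrier_gene(actionable_disease="treatable metabolic disease")
        v1 = make_variant(pos=10)
        v2 = make_variant(pos=20, ref="C", alt="T")
        mine = [
            ClassifiedVariant(v1, L.PATHOGENIC),
            ClassifiedVariant(v2, L.LIKELY_PATHOGENIC),
        ]
        assert determine_actionability(v1, L.PATHOGENIC, gene, mine) is True
        # a lone het in the same gene stays non-actionable
        assert determine_actionability(v1, L.PATHOGENIC, gene, mine[:1]) is False

    def test_homozygote_in_actionable_recessive_gene(self):
        gene = _ar_carrier_gene(actionable_disease="treatable metabolic disease")
        v = make_variant(zygosity=Zygosity.HOM_ALT)
        assert determine_actionability(v, L.PATHOGENIC, gene) is True

    def test_vus_never_actionable(self):
        gene = make_gene(actionable_disease="x", inheritance=frozenset({"AR"}))
        assert determine_actionability(make_variant(), L.VUS, gene) is False


class TestCarrierAndRisk:
    def test_het_pathogenic_recessive_is_carrier(self):
        assert detect_carrier(make_variant(), L.PATHOGENIC, _ar_carrier_gene()) is True

    def test_hom_alt_is_not_carrier(self):
        v = make_variant(zygosity=Zygosity.HOM_ALT)
        assert detect_carrier(v, L.PATHOGENIC, _ar_carrier_gene()) is False

    def test_actionable_excludes_carrier(self):
        v = make_variant(gene_symbol="MUTYH")
        assert detect_carrier(v, L.PATHOGENIC, _mutyh_like(), is_actionable=True) is False

    def test_gba_pattern_is_both_carrier_and_nonactionable_risk(self):
        gba = make_gene(symbol="GBA",
                        nonactionable_risk_disease="Parkinson disease")
        v = make_variant(gene_symbol="GBA")
        assert detect_carrier(v, L.PATHOGENIC, gba) is True
        assert flag_nonactionable_risk(v, L.PATHOGENIC, gba) is True

    def test_ordinary_carrier_gene_is_not_risk_flagged(self):
        assert flag_nonactionable_risk(make_variant(), L.PATHOGENIC, _ar_carrier_gene()) is False


class TestApoe:
    @pytest.mark.parametrize(
        "gt1, gt2, expected",
        [
            (("C", "C"), ("C", "C"), ("e4", "e4")),
            (("T", "T"), ("C", "C"), ("e3", "e3")),
            (("T", "C"), ("C", "C"), ("e3", "e4")),
            (("T", "T"), ("T", "T"), ("e2", "e2")),
            (("T", "T"), ("C", "T"), ("e2", "e3")),
            # unphased double heterozygote resolved as e2/e4 by convention
            (("T", "C"), ("C", "T"), ("e2", "e4")),
        ],
    )
    def test_diplotype_table(self, gt1, gt2, expected):
        assert call_apoe(gt1, gt2) == expected

    def test_missing_genotype_is_no_call(self):
        assert call_apoe(None, ("C", "C")) is None

    def test_e1_implying_genotypes_rejected(self):
        with pytest.raises(ValueError):
            call_apoe(("C", "C"), ("T", "T"))


class TestPgx:
    def _sites(self, genotypes_by_rsid):
        return {
            rsid: SiteGenotypes(rsid, "G", "A", {"P001": gt})
            for rsid, gt in genotypes_by_rsid.items()
        }

    def test_counts_non_reference_panel_sites(self):
        panel = PGxPanel(("rs1", "rs2", "rs3", "rs4"),
                         {"rs1": "drug A", "rs2": "drug B"})
        sites = self._sites({
            "rs1": ("G", "A"),
            "rs2": ("A", "A"),
            "rs3": ("G", "G"),
        })
        out = pgx_findings("P001", sites, panel)
        assert {f.variant_key for f in out} == {"rs1", "rs2"}
        assert all(f.category is Category.PGX for f in out)
        assert next(f for f in out if f.variant_key == "rs1").rationale == "drug A"

    def test_all_reference_yields_nothing(self):
        panel = PGxPanel(("rs1",), {})
        assert pgx_findings("P001", self._sites({"rs1": ("G", "G")}), panel) == []


_categories = st.sampled_from(list(Category))
_classifications = st.sampled_from(
    [L.PATHOGENIC, L.LIKELY_PATHOGENIC, L.RISK_ALLELE, L.VUS, L.NOT_CLASSIFIED]
)


@given(
    category=_categories,
    classification=_classifications,
    consent=st.sampled_from(list(Consent)),
    apoe_requested=st.booleans(),
)
@settings(max_examples=200)
def test_return_gate_soundness(category, classification, consent, apoe_requested):
    """No combination of category, classification and consent ever returns a
    finding the consent matrix forbids."""
    if category is Category.ACTIONABLE and classification in (L.VUS, L.NOT_CLASSIFIED):
        classification = L.PATHOGENIC
    if apoe_requested and consent is not Consent.ALL_MEDICALLY_RELEVANT:
        apoe_requested = False
    participant = make_participant(consent=consent, apoe_requested=apoe_requested)
    finding = Finding("P001", "k", "G", classification, category)
    (gated,) = apply_return_preferences([finding], participant)
    if gated.returned:
        assert classification is not L.VUS
        assert consent is not Consent.NONE
        if consent is Consent.ACTIONABLE_ONLY:
            assert category is Category.ACTIONABLE
        if category is Category.APOE:
            assert apoe_requested
    else:
        # anything blocked must have a blocking reason
        assert (
            classification is L.VUS
            or consent is Consent.NONE
            or (consent is Consent.ACTIONABLE_ONLY and category is not Category.ACTIONABLE)
            or (category is Category.APOE and not apoe_requested)
        )


def test_partition_sanity_on_generated_cohort(default_result):
    """Per participant, every reportable classified variant carries at least
    one category, and actionable/carrier are mutually exclusive."""
    reportable = [
        cv for cv in default_result.classified
        if cv.classification in (L.PATHOGENIC, L.LIKELY_PATHOGENIC, L.RISK_ALLELE)
    ]
    by_variant = {}
    for f in default_result.findings:
        if f.category in (Category.ACTIONABLE, Category.CARRIER, Category.NONACTIONABLE_RISK):
            by_variant.setdefault((f.participant_id, f.variant_key), set()).add(f.category)
    for cv in reportable:
        cats = by_variant.get((cv.variant.participant_id, cv.variant.key), set())
        assert cats, f"uncategorized reportable variant {cv.variant.key}"
        assert not ({Category.ACTIONABLE, Category.CARRIER} <= cats)
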