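"""Small record factories shared across the unit tests."""

from exome_triage.models import (
    AnnotationBlock,
    Consent,
    Consequence,
    GeneRecord,
    Participant,
    VariantRecord,
    Zygosity,
)


def make_annotation(**overrides) -> AnnotationBlock:
    base = dict(
        gene_symbol="PAH",
        transcript="NM_000277",
        hgvs_c="c.100A>G",
        hgvs_p="p.K34E",
        consequence=Consequence.MISSENSE,
    )
    base.update(overrides)
    return AnnotationBlock(**base)


def make_variant(**overrides) -> VariantRecord:
    annotation_overrides = {
        k: overrides.pop(k)
        for k in list(overrides)
        if k in AnnotationBlock.__dataclass_fields__
    }
    base = dict(
        participant_id="P001",
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        phred_qual=60.0,
        depth=40,
        zygosity=Zygosity.HET,
        annotation=make_annotation(**annotation_overrides),
    )
    base.update(overrides)
    return VariantRecord(**base)


def make_gene(**overrides) -> GeneRecord:
    base = dict(
        symbol="PAH",
        inheritance=frozenset({"AR"}),
        omim_mendelian=True,
        penetrance_class="high",
        onset_class="young",
        severity_class="serious",
    )
    base.update(overrides)
    return GeneRecord(**base)


def make_participant(**overrides) -> Participant:
    base = dict(
        id="P001",
        age=50,
        sex="female",
        consent=Consent.ALL_MEDICALLY_RELEVANT,
    )
    base.update(overrides)
    return Participant(**base)
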