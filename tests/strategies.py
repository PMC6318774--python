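"""Hypothesis strategies generating valid domain records for round-trips."""

from hypothesis import strategies as st

from exome_triage.acmg_engine import EvidenceAssignment, EvidenceCode, Strength
from exome_triage.models import (
    AnnotationBlock,
    ClinvarSignificance,
    Consent,
    Consequence,
    GeneRecord,
    Participant,
    SubpopFrequency,
    VariantRecord,
    Zygosity,
)

_UPPER = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_WORD = st.text(alphabet=_UPPER + "0123456789", min_size=1, max_size=8)
_TERM = st.text(alphabet="abcdefghijklmnopqrstuvwxyz ", min_size=1, max_size=12).map(
    str.strip
).filter(bool)

# frequencies restricted to 6 decimal places so decimal text survives floats
_maf = st.integers(0, 1_000_000).map(lambda x: x / 1e6)

_subpop = st.builds(
    SubpopFrequency,
    label=st.sampled_from(["AFR", "AMR", "EAS", "EUR", "SAS"]),
    af=_maf,
    an=st.integers(0, 200_000),
)

annotations = st.builds(
    AnnotationBlock,
    gene_symbol=_WORD,
    transcript=_WORD,
    hgvs_c=_WORD,
    hgvs_p=_WORD,
    consequence=st.sampled_from(list(Consequence)),
    maf_1000g=_maf,
    maf_exac=_maf,
    subpop_mafs=st.lists(_subpop, max_size=3, unique_by=lambda s: s.label).map(tuple),
    clinvar_significance=st.sampled_from(list(ClinvarSignificance)),
    clinvar_stars=st.integers(0, 4),
    hgmd_dm_match=st.booleans(),
    rsid=st.none() | st.integers(1, 10**7).map(lambda i: f"rs{i}"),
)

_alleles = st.sampled_from(
    [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("AT", "A"), ("G", "GCA")]
)


@st.composite
def variant_lists(draw, max_size=6):
    """Lists of records at distinct sites (VCF sites are unique per line)."""
    n = draw(st.integers(min_value=0, max_value=max_size))
    records = []
    for i in range(n):
        ref, alt = draw(_alleles)
        records.append(
            VariantRecord(
                participant_id=f"S{draw(st.integers(1, 3))}",
                chrom=draw(st.sampled_from(["1", "7", "X"])),
                pos=1_000 + 17 * i,  # distinct within and across chromosomes
                ref=ref,
                alt=alt,
                phred_qual=float(draw(st.integers(0, 250))),
                depth=draw(st.integers(0, 300)),
                zygosity=draw(st.sampled_from(list(Zygosity))),
                annotation=draw(annotations),
            )
        )
    return records


genes = st.builds(
    GeneRecord,
    symbol=_WORD,
    mim_number=st.sampled_from(["", "123456"]),
    inheritance=st.sets(st.sampled_from(["AD", "AR", "XL"]), min_size=1).map(frozenset),
    omim_mendelian=st.booleans(),
    omim_exception=st.sets(
        st.sampled_from(
            ["bracket_nondisease", "brace_multifactorial", "question_provisional"]
        )
    ).map(frozenset),
    on_acmg59=st.booleans(),
    actionable_disease=st.sampled_from(["", "some disease"]),
    penetrance_class=st.sampled_from(["high", "moderate", "low"]),
    onset_class=st.sampled_from(["young", "adult", "variable"]),
    severity_class=st.sampled_from(["serious", "mild"]),
    het_risk_actionable=st.just(False),
    nonactionable_risk_disease=st.sampled_from(["", "risk disease"]),
    full_penetrance_age=st.none() | st.integers(1, 90),
    phenotype_terms=st.lists(_TERM, max_size=3, unique=True).map(tuple),
)

participants = st.builds(
    Participant,
    id=_WORD,
    age=st.integers(18, 95),
    sex=st.sampled_from(["male", "female"]),
    ethnicity=st.sampled_from(["", "Caucasian", "Hispanic"]),
    phenotype_terms=st.lists(_TERM, max_size=3, unique=True).map(tuple),
    family_history_terms=st.lists(_TERM, max_size=3, unique=True).map(tuple),
    consent=st.sampled_from(list(Consent)),
    apoe_requested=st.just(False),
)

_codes = st.lists(
    st.sampled_from(["PVS1", "PS1", "PS4", "PM2", "PP3", "BA1", "BS1", "BP4"]),
    max_size=5,
    unique=True,
).map(
    lambda names: tuple(
        EvidenceCode(n, Strength.MODERATE if n == "PS4" else None) for n in names
    )
)

evidence_assignments = st.builds(
    EvidenceAssignment,
    variant_key=_WORD,
    codes=_codes,
    risk_allele=st.booleans(),
    notes=st.text(
        alphabet="abcdefghijklmnopqrstuvwxyz ,.", max_size=20
    ).map(str.strip),
)
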