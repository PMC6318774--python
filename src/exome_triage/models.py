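"""Domain objects shared across the triage pipeline.

Every record type used by the pipeline lives here so that the I/O layer,
the filter cascade, the classification engine and the reporters can share
one vocabulary without circular imports. Validation happens at construction
time; downstream code can assume invariants hold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional


class TriageError(Exception):
    """Base class for pipeline errors."""


class FormatError(TriageError):
    """An input file violates the documented format."""


class ValidationError(TriageError):
    """A record violates a domain invariant."""


class Consequence(str, enum.Enum):
    """Pre-computed functional consequence of a variant on its transcript."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    INFRAME_INDEL = "inframe_indel"
    CANONICAL_SPLICE = "canonical_splice"
    SYNONYMOUS = "synonymous"
    OTHER_NONCODING = "other_noncoding"


#: Consequences treated as "coding or canonical splice" by the cascade.
#: Synonymous changes are deliberately excluded: the triage targets
#: protein-altering and splice-disrupting variation.
CODING_OR_SPLICE = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INS,
        Consequence.FRAMESHIFT_DEL,
        Consequence.INFRAME_INDEL,
        Consequence.CANONICAL_SPLICE,
    }
)

#: Consequences treated as likely loss-of-function for curation-queue
#: triggering (insertions and deletions, nonsense, splice).
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INS,
        Consequence.FRAMESHIFT_DEL,
        Consequence.INFRAME_INDEL,
        Consequence.CANONICAL_SPLICE,
    }
)


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


class ClinvarSignificance(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


class ClassificationLabel(str, enum.Enum):
    """Final call for a curated variant."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    RISK_ALLELE = "risk_allele"
    NOT_CLASSIFIED = "not_classified"


#: Labels that can support a reportable finding.
REPORTABLE_LABELS = frozenset(
    {
        ClassificationLabel.PATHOGENIC,
        ClassificationLabel.LIKELY_PATHOGENIC,
        ClassificationLabel.RISK_ALLELE,
    }
)


class Consent(str, enum.Enum):
    NONE = "none"
    ACTIONABLE_ONLY = "actionable_only"
    ALL_MEDICALLY_RELEVANT = "all_medically_relevant"


class Category(str, enum.Enum):
    """Finding category used by the reporter and the consent gate."""

    ACTIONABLE = "actionable"
    CARRIER = "carrier"
    NONACTIONABLE_RISK = "nonactionable_risk"
    APOE = "apoe"
    PGX = "pgx"


class SubpopFrequency(NamedTuple):
    """Allele frequency of one subpopulation, with the allele number
    (total alleles observed) that the frequency was computed from."""

    label: str
    af: float
    an: int


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise ValidationError(
            f"unknown {enum_cls.__name__} token: {value!r}"
        ) from exc


@dataclass(frozen=True)
class AnnotationBlock:
    """Pre-computed annotation attached to one ALT allele.

    Annotation is an input to the pipeline, not a computation: gene,
    consequence, HGVS, population frequencies, ClinVar status and the
    HGMD disease-mutation match flag all travel inside the VCF INFO block.
    Frequencies absent from a database are represented as 0.0 (an
    unobserved variant is treated as rare).
    """

    gene_symbol: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.MISSENSE
    maf_1000g: float = 0.0
    maf_exac: float = 0.0
    subpop_mafs: tuple[SubpopFrequency, ...] = ()
    clinvar_significance: ClinvarSignificance = ClinvarSignificance.ABSENT
    clinvar_stars: int = 0
    hgmd_dm_match: bool = False
    rsid: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(
            self, "consequence", _coerce(self.consequence, Consequence)
        )
        object.__setattr__(
            self,
            "clinvar_significance",
            _coerce(self.clinvar_significance, ClinvarSignificance),
        )
        for name in ("maf_1000g", "maf_exac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        subs = tuple(SubpopFrequency(*s) for s in self.subpop_mafs)
        object.__setattr__(self, "subpop_mafs", subs)
        for sub in subs:
            if not 0.0 <= sub.af <= 1.0:
                raise ValidationError(
                    f"subpopulation frequency must lie in [0, 1], got {sub.af}"
                )
            if sub.an < 0:
                raise ValidationError("allele number must be >= 0")
        if not 0 <= self.clinvar_stars <= 4:
            raise ValidationError(
                f"clinvar_stars must lie in [0, 4], got {self.clinvar_stars}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One called variant for one participant (post allele decomposition)."""

    participant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    phred_qual: float
    depth: int
    zygosity: Zygosity
    annotation: AnnotationBlock

    def __post_init__(self):
        object.__setattr__(self, "zygosity", _coerce(self.zygosity, Zygosity))
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles must differ")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.phred_qual < 0:
            raise ValidationError("phred_qual must be >= 0")
        if self.depth < 0:
            raise ValidationError("depth must be >= 0")

    @property
    def key(self) -> str:
        """Site-level variant key shared by all carriers of the allele."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


INHERITANCE_TOKENS = frozenset({"AD", "AR", "XL"})
EXCEPTION_TOKENS = frozenset(
    {"bracket_nondisease", "brace_multifactorial", "question_provisional"}
)
PENETRANCE_CLASSES = frozenset({"high", "moderate", "low"})
ONSET_CLASSES = frozenset({"young", "adult", "variable"})
SEVERITY_CLASSES = frozenset({"serious", "mild"})


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene metadata driving list membership and actionability.

    ``omim_mendelian`` means the gene carries at least one clear-cut
    Mendelian disease annotation; genes whose only annotations are OMIM
    exception categories (bracketed non-disease, braced multifactorial,
    question-marked provisional) carry ``omim_mendelian=False`` together
    with the exception set, and are excluded from the Mendelian search
    space unless they sit on the ACMG-59 list.
    """

    symbol: str
    mim_number: str = ""
    inheritance: frozenset = frozenset()
    omim_mendelian: bool = False
    omim_exception: frozenset = frozenset()
    on_acmg59: bool = False
    actionable_disease: str = ""
    penetrance_class: str = "low"
    onset_class: str = "adult"
    severity_class: str = "mild"
    het_risk_actionable: bool = False
    nonactionable_risk_disease: str = ""
    full_penetrance_age: Optional[int] = None
    phenotype_terms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "inheritance", frozenset(self.inheritance))
        object.__setattr__(
            self, "omim_exception", frozenset(self.omim_exception)
        )
        object.__setattr__(
            self, "phenotype_terms", tuple(self.phenotype_terms)
        )
        bad = self.inheritance - INHERITANCE_TOKENS
        if bad:
            raise ValidationError(
                f"unknown inheritance token(s) for {self.symbol}: {sorted(bad)}"
            )
        bad = self.omim_exception - EXCEPTION_TOKENS
        if bad:
            raise ValidationError(
                f"unknown OMIM exception token(s) for {self.symbol}: {sorted(bad)}"
            )
        if self.penetrance_class not in PENETRANCE_CLASSES:
            raise ValidationError(
                f"unknown penetrance class: {self.penetrance_class!r}"
            )
        if self.onset_class not in ONSET_CLASSES:
            raise ValidationError(f"unknown onset class: {self.onset_class!r}")
        if self.severity_class not in SEVERITY_CLASSES:
            raise ValidationError(
                f"unknown severity class: {self.severity_class!r}"
            )
        if self.het_risk_actionable and "AR" not in self.inheritance:
            raise ValidationError(
                f"{self.symbol}: het_risk_actionable requires AR inheritance"
            )

    @property
    def in_mendelian_search_space(self) -> bool:
        """True when variants in this gene survive the gene-list filter."""
        return self.omim_mendelian or self.on_acmg59


@dataclass(frozen=True)
class Participant:
    id: str
    age: int
    sex: str
    ethnicity: str = ""
    phenotype_terms: tuple[str, ...] = ()
    family_history_terms: tuple[str, ...] = ()
    consent: Consent = Consent.NONE
    apoe_requested: bool = False

    def __post_init__(self):
        object.__setattr__(self, "consent", _coerce(self.consent, Consent))
        object.__setattr__(
            self, "phenotype_terms", tuple(self.phenotype_terms)
        )
        object.__setattr__(
            self, "family_history_terms", tuple(self.family_history_terms)
        )
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex token: {self.sex!r}")
        if self.apoe_requested and self.consent is not Consent.ALL_MEDICALLY_RELEVANT:
            raise ValidationError(
                f"{self.id}: APOE disclosure requires all_medically_relevant consent"
            )

    @property
    def history_terms(self) -> frozenset:
        """Personal phenotype plus family history, for queue triggering."""
        return frozenset(self.phenotype_terms) | frozenset(
            self.family_history_terms
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade and the summary statistics.

    Defaults reproduce the study conditions: Phred >= 20, depth >= 10,
    MAF exclusion strictly above 0.5%, ClinVar rescue at >= 2 stars,
    and a 95% (z = 1.96) binomial confidence interval.
    """

    phred_min: float = 20.0
    depth_min: int = 10
    maf_threshold: float = 0.005
    clinvar_rescue_min_stars: int = 2
    subpop_min_allele_number: int = 2000
    subpop_min_alt_count: int = 5
    ci_z: float = 1.96
    ci_method: str = "wald"
    coding_consequences: tuple[Consequence, ...] = tuple(sorted(CODING_OR_SPLICE))

    def __post_init__(self):
        for name in (
            "phred_min",
            "depth_min",
            "maf_threshold",
            "clinvar_rescue_min_stars",
            "subpop_min_allele_number",
            "subpop_min_alt_count",
            "ci_z",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.maf_threshold >= 1:
            raise ValidationError("maf_threshold must be < 1")
        if self.ci_method not in ("wald", "wilson", "clopper_pearson"):
            raise ValidationError(f"unknown CI method: {self.ci_method!r}")
        object.__setattr__(
            self,
            "coding_consequences",
            tuple(_coerce(c, Consequence) for c in self.coding_consequences),
        )


@dataclass
class Finding:
    """A categorized, classified variant for one participant."""

    participant_id: str
    variant_key: str
    gene_symbol: str
    classification: ClassificationLabel
    category: Category
    zygosity: Optional[Zygosity] = None
    returned: bool = False
    rationale: str = ""

    def __post_init__(self):
        self.classification = _coerce(self.classification, ClassificationLabel)
        self.category = _coerce(self.category, Category)
        if self.zygosity is not None:
            self.zygosity = _coerce(self.zygosity, Zygosity)
        if self.classification is ClassificationLabel.VUS and self.returned:
            raise ValidationError("a VUS finding can never be returned")
        if self.category is Category.ACTIONABLE and (
            self.classification not in REPORTABLE_LABELS
        ):
            raise ValidationError(
                "actionable findings require a pathogenic, likely pathogenic "
                "or risk-allele classification"
            )


@dataclass(frozen=True)
class PGxPanel:
    """Panel of high-evidence pharmacogenetic rsIDs with drug annotations."""

    rsids: tuple[str, ...]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "rsids", tuple(self.rsids))
        if len(set(self.rsids)) != len(self.rsids):
            raise ValidationError("panel rsIDs must be unique")
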