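"""Deterministic ACMG/AMP evidence-combination classifier.

The engine implements the mechanical half of variant curation: given the
evidence codes a curator assigned to a variant (PVS1, PS1-PS4, PM1-PM6,
PP1-PP5 on the pathogenic side; BA1, BS1-BS4, BP1-BP7 on the benign side),
it applies the published combining rules and returns one of five
classifications, or ``vus`` when the evidence is absent or contradictory.

Two curator-level mechanisms are supported because real curation uses them:

* strength overrides — a code may be applied at a non-default strength
  (e.g. ``PS4:moderate`` when the case-control evidence is thinner than a
  full strong criterion warrants); the engine never downgrades on its own;
* a risk-allele flag — variants such as APC p.I1307K confer a moderate,
  guideline-managed risk rather than Mendelian disease, and the curator may
  override the rule-based output with the ``risk_allele`` label.

The engine only consumes evidence; it never generates it (no automated
population-frequency PM2 calls, no in-silico PP3 scoring).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import ClassificationLabel, ValidationError


class Strength(str, enum.Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


def _expand(prefix: str, n: int, strength: Strength) -> dict:
    return {f"{prefix}{i}": strength for i in range(1, n + 1)}


#: Default strength implied by each code's prefix.
DEFAULT_STRENGTHS: dict[str, Strength] = {
    "PVS1": Strength.VERY_STRONG,
    **_expand("PS", 4, Strength.STRONG),
    **_expand("PM", 6, Strength.MODERATE),
    **_expand("PP", 5, Strength.SUPPORTING),
    "BA1": Strength.STAND_ALONE,
    **_expand("BS", 4, Strength.STRONG),
    **_expand("BP", 7, Strength.SUPPORTING),
}

PATHOGENIC_OVERRIDES = frozenset(
    {Strength.VERY_STRONG, Strength.STRONG, Strength.MODERATE, Strength.SUPPORTING}
)
BENIGN_OVERRIDES = frozenset({Strength.STRONG, Strength.SUPPORTING})

#: Ordering used by monotonicity checks: more benign < more pathogenic.
PATHOGENICITY_ORDER: dict[ClassificationLabel, int] = {
    ClassificationLabel.BENIGN: 0,
    ClassificationLabel.LIKELY_BENIGN: 1,
    ClassificationLabel.VUS: 2,
    ClassificationLabel.LIKELY_PATHOGENIC: 3,
    ClassificationLabel.PATHOGENIC: 4,
}


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG code, optionally at a curator-overridden strength."""

    code: str
    override_strength: Optional[Strength] = None

    def __post_init__(self):
        if self.code not in DEFAULT_STRENGTHS:
            raise ValidationError(f"unknown ACMG evidence code: {self.code!r}")
        if self.override_strength is not None:
            strength = Strength(self.override_strength)
            object.__setattr__(self, "override_strength", strength)
            if self.code == "BA1":
                raise ValidationError("BA1 is stand-alone and not overridable")
            allowed = BENIGN_OVERRIDES if self.is_benign else PATHOGENIC_OVERRIDES
            if strength not in allowed:
                raise ValidationError(
                    f"{self.code} cannot be applied at strength {strength.value}"
                )

    @property
    def is_benign(self) -> bool:
        return self.code.startswith("B")

    @property
    def default_strength(self) -> Strength:
        return DEFAULT_STRENGTHS[self.code]

    @property
    def effective_strength(self) -> Strength:
        return self.override_strength or self.default_strength

    def __str__(self) -> str:
        if self.override_strength is not None:
            return f"{self.code}:{self.override_strength.value}"
        return self.code


def parse_code(token: str) -> EvidenceCode:
    """Parse ``"PS4"`` or ``"PS4:moderate"`` into an :class:`EvidenceCode`."""
    token = token.strip()
    if ":" in token:
        code, strength = token.split(":", 1)
        return EvidenceCode(code.strip(), Strength(strength.strip()))
    return EvidenceCode(token)


def parse_codes(text: str) -> tuple[EvidenceCode, ...]:
    """Parse a comma-separated code list, e.g. ``"PS3,PS4:moderate,PM2"``."""
    if not text or not text.strip():
        return ()
    return tuple(parse_code(t) for t in text.split(",") if t.strip())


@dataclass(frozen=True)
class EvidenceAssignment:
    """Curator-supplied evidence for one variant (keyed chrom:pos:ref:alt)."""

    variant_key: str
    codes: tuple[EvidenceCode, ...] = ()
    risk_allele: bool = False
    notes: str = ""

    def __post_init__(self):
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        names = [c.code for c in codes]
        if len(set(names)) != len(names):
            raise ValidationError(
                f"duplicate evidence codes for {self.variant_key}: {names}"
            )


def _tally(codes: Iterable[EvidenceCode]):
    seen: set[str] = set()
    nvs = ns = nm = nsup = 0
    ba1 = False
    nbs = nbp = 0
    for code in codes:
        if code.code in seen:
            raise ValidationError(f"duplicate evidence code: {code.code}")
        seen.add(code.code)
        strength = code.effective_strength
        if code.is_benign:
            if code.code == "BA1":
                ba1 = True
            elif strength is Strength.STRONG:
                nbs += 1
            else:
                nbp += 1
        else:
            if strength is Strength.VERY_STRONG:
                nvs += 1
            elif strength is Strength.STRONG:
                ns += 1
            elif strength is Strength.MODERATE:
                nm += 1
            else:
                nsup += 1
    return nvs, ns, nm, nsup, ba1, nbs, nbp


def combine_evidence(codes: Iterable[EvidenceCode]) -> ClassificationLabel:
    """Apply the ACMG/AMP combining rules to a set of evidence codes.

    Counts are taken at each code's effective strength, so curator
    overrides participate directly in the rule table. When a
    pathogenic-side rule and a benign-side rule both fire the evidence is
    contradictory and the variant is a VUS, as is an empty or
    insufficient code set.
    """
    nvs, ns, nm, nsup, ba1, nbs, nbp = _tally(codes)

    pathogenic = (
        (nvs >= 1 and (ns >= 1 or nm >= 2 or (nm == 1 and nsup == 1) or nsup >= 2))
        or ns >= 2
        or (ns == 1 and (nm >= 3 or (nm == 2 and nsup >= 2) or (nm == 1 and nsup >= 4)))
    )
    likely_pathogenic = (
        (nvs == 1 and nm == 1)
        or (ns == 1 and 1 <= nm <= 2)
        or (ns == 1 and nsup >= 2)
        or nm >= 3
        or (nm == 2 and nsup >= 2)
        or (nm == 1 and nsup >= 4)
    )
    benign = ba1 or nbs >= 2
    likely_benign = (nbs == 1 and nbp == 1) or nbp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return ClassificationLabel.VUS
    if pathogenic:
        return ClassificationLabel.PATHOGENIC
    if likely_pathogenic:
        return ClassificationLabel.LIKELY_PATHOGENIC
    if benign:
        return ClassificationLabel.BENIGN
    if likely_benign:
        return ClassificationLabel.LIKELY_BENIGN
    return ClassificationLabel.VUS


def classify_variant(assignment: EvidenceAssignment) -> ClassificationLabel:
    """Classify one variant from its curator evidence.

    The risk-allele flag takes precedence over the rule-based output:
    moderate-risk founder variants with published management guidelines
    are labelled ``risk_allele`` regardless of what the combining rules
    would return for the same codes.
    """
    if assignment.risk_allele:
        return ClassificationLabel.RISK_ALLELE
    return combine_evidence(assignment.codes)
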