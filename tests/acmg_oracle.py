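"""Independent brute-force transcription of the ACMG combining rule table.

Used as the oracle against the production evidence-combination engine.
The oracle works directly on strength counts and enumerates the published
rule clauses one by one; it shares no code with the engine.
"""

import itertools

from exome_triage.acmg_engine import EvidenceCode, Strength
from exome_triage.models import ClassificationLabel as L

# clauses of the pathogenic rule: each is a predicate over
# (n very strong, n strong, n moderate, n supporting)
_PATHOGENIC_CLAUSES = [
    lambda vs, s, m, p: vs >= 1 and s >= 1,            # 1 VS + >=1 S
    lambda vs, s, m, p: vs >= 1 and m >= 2,            # 1 VS + >=2 M
    lambda vs, s, m, p: vs >= 1 and m == 1 and p == 1, # 1 VS + 1 M + 1 P
    lambda vs, s, m, p: vs >= 1 and p >= 2,            # 1 VS + >=2 P
    lambda vs, s, m, p: s >= 2,                        # >=2 S
    lambda vs, s, m, p: s == 1 and m >= 3,             # 1 S + >=3 M
    lambda vs, s, m, p: s == 1 and m == 2 and p >= 2,  # 1 S + 2 M + >=2 P
    lambda vs, s, m, p: s == 1 and m == 1 and p >= 4,  # 1 S + 1 M + >=4 P
]

_LIKELY_PATHOGENIC_CLAUSES = [
    lambda vs, s, m, p: vs == 1 and m == 1,            # 1 VS + 1 M
    lambda vs, s, m, p: s == 1 and m in (1, 2),        # 1 S + 1-2 M
    lambda vs, s, m, p: s == 1 and p >= 2,             # 1 S + >=2 P
    lambda vs, s, m, p: m >= 3,                        # >=3 M
    lambda vs, s, m, p: m == 2 and p >= 2,             # 2 M + >=2 P
    lambda vs, s, m, p: m == 1 and p >= 4,             # 1 M + >=4 P
]


def oracle_from_counts(nvs, ns, nm, nsup, ba1, nbs, nbp) -> L:
    pathogenic = any(c(nvs, ns, nm, nsup) for c in _PATHOGENIC_CLAUSES)
    likely = any(c(nvs, ns, nm, nsup) for c in _LIKELY_PATHOGENIC_CLAUSES)
    benign = ba1 or nbs >= 2
    likely_benign = (nbs == 1 and nbp == 1) or nbp >= 2
    if (pathogenic or likely) and (benign or likely_benign):
        return L.VUS
    if pathogenic:
        return L.PATHOGENIC
    if likely:
        return L.LIKELY_PATHOGENIC
    if benign:
        return L.BENIGN
    if likely_benign:
        return L.LIKELY_BENIGN
    return L.VUS


_P_NAMES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
_BS_NAMES = [f"BS{i}" for i in range(1, 5)]
_BP_NAMES = [f"BP{i}" for i in range(1, 8)]


def realize_codes(nvs, ns, nm, nsup, ba1, nbs, nbp):
    """Build a concrete code set realizing the given strength counts,
    using overrides where the natural code names run out."""
    codes = []
    names = iter(_P_NAMES)
    for strength, count in (
        (Strength.VERY_STRONG, nvs),
        (Strength.STRONG, ns),
        (Strength.MODERATE, nm),
        (Strength.SUPPORTING, nsup),
    ):
        for _ in range(count):
            codes.append(EvidenceCode(next(names), strength))
    if ba1:
        codes.append(EvidenceCode("BA1"))
    for name in _BS_NAMES[:nbs]:
        codes.append(EvidenceCode(name))
    for name in _BP_NAMES[:nbp]:
        codes.append(EvidenceCode(name))
    return codes


def enumerate_count_tuples(max_total=6):
    """All realizable strength-count tuples with at most ``max_total`` codes."""
    for nvs, ns, nm, nsup in itertools.product(
        range(3), range(5), range(7), range(6)
    ):
        for ba1 in (0, 1):
            for nbs in range(5):
                for nbp in range(7):
                    total = nvs + ns + nm + nsup + ba1 + nbs + nbp
                    if 0 < total <= max_total:
                        yield nvs, ns, nm, nsup, bool(ba1), nbs, nbp
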