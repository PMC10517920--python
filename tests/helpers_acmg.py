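"""Independent brute-force oracle for the ACMG 2015 combining rules.

Transcribes the published rule table literally as a list of evidence-tier
patterns; a class is reached when the criterion set contains at least the
tiers of one pattern.  Mixed pathogenic-side and benign-side evidence is
contradictory and resolves to uncertain significance.  Kept deliberately
separate from the package engine so the two can be compared exhaustively.
"""

from collections import Counter

from lsdincidence.acmg import (
    ALL_CODES,
    BENIGN_CODES,
    PATHOGENIC_CODES,
    AcmgClass,
    criterion_tier,
)

PATHOGENIC_PATTERNS = [
    {"very_strong": 1, "strong": 1},
    {"very_strong": 1, "moderate": 2},
    {"very_strong": 1, "moderate": 1, "supporting": 1},
    {"very_strong": 1, "supporting": 2},
    {"strong": 2},
    {"strong": 1, "moderate": 3},
    {"strong": 1, "moderate": 2, "supporting": 2},
    {"strong": 1, "moderate": 1, "supporting": 4},
]
LIKELY_PATHOGENIC_PATTERNS = [
    {"very_strong": 1, "moderate": 1},
    {"strong": 1, "moderate": 1},
    {"strong": 1, "supporting": 2},
    {"moderate": 3},
    {"moderate": 2, "supporting": 2},
    {"moderate": 1, "supporting": 4},
]
BENIGN_PATTERNS = [
    {"stand_alone_benign": 1},
    {"strong_benign": 2},
]
LIKELY_BENIGN_PATTERNS = [
    {"strong_benign": 1, "supporting_benign": 1},
    {"supporting_benign": 2},
]


def oracle_classify(criteria) -> AcmgClass:
    codes = frozenset(criteria)
    assert codes <= ALL_CODES
    if codes & PATHOGENIC_CODES and codes & BENIGN_CODES:
        return AcmgClass.VUS
    tiers = Counter(criterion_tier(c) for c in codes)

    def satisfied(patterns):
        return any(
            all(tiers[t] >= need for t, need in p.items()) for p in patterns
        )

    if satisfied(PATHOGENIC_PATTERNS):
        return AcmgClass.PATHOGENIC
    if satisfied(LIKELY_PATHOGENIC_PATTERNS):
        return AcmgClass.LIKELY_PATHOGENIC
    if satisfied(BENIGN_PATTERNS):
        return AcmgClass.BENIGN
    if satisfied(LIKELY_BENIGN_PATTERNS):
        return AcmgClass.LIKELY_BENIGN
    return AcmgClass.VUS
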