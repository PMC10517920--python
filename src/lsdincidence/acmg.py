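"""ACMG/AMP 2015 variant-classification rule engine.

Criterion codes carry an evidence strength derived purely from their prefix
(PVS very strong, PS strong, PM moderate, PP supporting; BA stand-alone
benign, BS strong benign, BP supporting benign).  The engine applies the
published combining rules to a *set* of codes — duplicates collapse, and
strength-modified codes (e.g. PM3 upgraded to strong) are deliberately not
modelled.  Contradictory evidence — any pathogenic-side code together with
any benign-side code — yields uncertain significance, as does an empty or
rule-less set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

try:
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover - py<3.9 fallback
    _resource_files = None

PATHOGENIC_CODES: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES: frozenset[str] = frozenset(
    ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
)
ALL_CODES: frozenset[str] = PATHOGENIC_CODES | BENIGN_CODES

_TIER_BY_PREFIX = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone_benign",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}


class AcmgValidationError(ValueError):
    """Raised for criterion codes outside the 2015 nomenclature."""


class AcmgClass(IntEnum):
    """Five-class pathogenicity scale with its natural total order."""

    BENIGN = 0
    LIKELY_BENIGN = 1
    VUS = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    AcmgClass.BENIGN: "benign",
    AcmgClass.LIKELY_BENIGN: "likely_benign",
    AcmgClass.VUS: "vus",
    AcmgClass.LIKELY_PATHOGENIC: "likely_pathogenic",
    AcmgClass.PATHOGENIC: "pathogenic",
}
_BY_LABEL = {v: k for k, v in _LABELS.items()}


def class_from_label(label: str) -> AcmgClass:
    """Parse a class from its snake-case or human-readable label."""
    norm = label.strip().lower().replace(" ", "_")
    aliases = {
        "uncertain_significance": "vus",
        "uncertain": "vus",
        "benign_or_likely_benign": "likely_benign",
    }
    norm = aliases.get(norm, norm)
    if norm not in _BY_LABEL:
        raise AcmgValidationError(f"unknown class label {label!r}")
    return _BY_LABEL[norm]


def criterion_tier(code: str) -> str:
    """Evidence strength tier, a pure function of the code prefix."""
    for prefix, tier in _TIER_BY_PREFIX.items():
        if code.startswith(prefix) and code in ALL_CODES:
            return tier
    raise AcmgValidationError(f"unknown ACMG criterion code {code!r}")


@dataclass(frozen=True)
class AcmgClassification:
    acmg_class: AcmgClass
    fired_rule: str
    criteria_used: frozenset[str]


def _validate(criteria: Iterable[str]) -> frozenset[str]:
    codes = frozenset(criteria)
    unknown = sorted(codes - ALL_CODES)
    if unknown:
        raise AcmgValidationError(f"unknown ACMG criterion code(s): {unknown}")
    return codes


def classify(criteria: Iterable[str]) -> AcmgClassification:
    """Combine ACMG criterion codes into one of the five classes.

    Pathogenic:
      PVS1 with (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP); or >=2 PS; or
      1 PS with (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP).
    Likely pathogenic:
      PVS1 + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM; 2 PM + >=2 PP;
      1 PM + >=4 PP.
    Benign: BA1, or >=2 BS.  Likely benign: 1 BS + 1 BP, or >=2 BP.
    Mixed pathogenic-side and benign-side evidence, or no rule firing,
    yields VUS.
    """
    codes = _validate(criteria)
    tiers = Counter(criterion_tier(c) for c in codes)
    nvs = tiers["very_strong"]
    ns = tiers["strong"]
    nm = tiers["moderate"]
    np_ = tiers["supporting"]
    ba = tiers["stand_alone_benign"]
    nbs = tiers["strong_benign"]
    nbp = tiers["supporting_benign"]

    has_path = (nvs + ns + nm + np_) > 0
    has_benign = (ba + nbs + nbp) > 0
    if has_path and has_benign:
        return AcmgClassification(AcmgClass.VUS, "conflicting_evidence", codes)

    if nvs >= 1 and (
        ns >= 1 or nm >= 2 or (nm >= 1 and np_ >= 1) or np_ >= 2
    ):
        return AcmgClassification(AcmgClass.PATHOGENIC, "PVS1_combination", codes)
    if ns >= 2:
        return AcmgClassification(AcmgClass.PATHOGENIC, "PS>=2", codes)
    if ns >= 1 and (
        nm >= 3 or (nm >= 2 and np_ >= 2) or (nm >= 1 and np_ >= 4)
    ):
        return AcmgClassification(AcmgClass.PATHOGENIC, "PS_combination", codes)

    if nvs >= 1 and nm >= 1:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PVS1+PM", codes)
    if ns >= 1 and nm >= 1:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PS+PM", codes)
    if ns >= 1 and np_ >= 2:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PS+PP>=2", codes)
    if nm >= 3:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PM>=3", codes)
    if nm >= 2 and np_ >= 2:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PM2+PP2", codes)
    if nm >= 1 and np_ >= 4:
        return AcmgClassification(AcmgClass.LIKELY_PATHOGENIC, "PM+PP>=4", codes)

    if ba >= 1:
        return AcmgClassification(AcmgClass.BENIGN, "BA1", codes)
    if nbs >= 2:
        return AcmgClassification(AcmgClass.BENIGN, "BS>=2", codes)
    if nbs >= 1 and nbp >= 1:
        return AcmgClassification(AcmgClass.LIKELY_BENIGN, "BS+BP", codes)
    if nbp >= 2:
        return AcmgClassification(AcmgClass.LIKELY_BENIGN, "BP>=2", codes)

    return AcmgClassification(AcmgClass.VUS, "no_rule", codes)


def classify_cohort(
    candidate_keys: Sequence[str],
    records: Mapping[str, "EvidenceRecord"],  # noqa: F821 - soft dependency
) -> tuple[dict[str, AcmgClassification], Counter]:
    """Classify every candidate from its assigned criteria; tally classes.

    Deterministic and order-independent: the tally is a pure function of
    the multiset of criterion sets.
    """
    classifications: dict[str, AcmgClassification] = {}
    tally: Counter = Counter({c: 0 for c in AcmgClass})
    for key in candidate_keys:
        rec = records[key]
        result = classify(rec.acmg_criteria)
        classifications[key] = result
        tally[result.acmg_class] += 1
    return classifications, tally


def frequency_criteria(
    max_external_af: float | None,
    ba1_threshold: float = 0.05,
    pm2_threshold: float = 1e-4,
) -> frozenset[str]:
    """Optional frequency-derived criteria (off by default in the pipeline).

    BA1 when the maximum external AF reaches ``ba1_threshold``; PM2 when the
    variant is rare (below ``pm2_threshold``) or absent from all databases.
    """
    if max_external_af is None or max_external_af < pm2_threshold:
        return frozenset({"PM2"})
    if max_external_af >= ba1_threshold:
        return frozenset({"BA1"})
    return frozenset()


# ---------------------------------------------------------------------------
# audit of published classifications

@dataclass(frozen=True)
class ClassAudit:
    """Engine-vs-printed comparison for one published variant row."""

    identifier: str
    printed_class: AcmgClass
    engine_class: AcmgClass
    criteria: frozenset[str]

    @property
    def consistent(self) -> bool:
        return self.printed_class == self.engine_class


def audit_printed_classes(
    rows: Iterable[tuple[str, Iterable[str], str]]
) -> list[ClassAudit]:
    """Re-classify published (identifier, criteria, printed class) rows.

    Rows whose printed class disagrees with the literal combining rules are
    flagged (``consistent`` False) rather than silently matched.
    """
    audits = []
    for identifier, criteria, printed in rows:
        result = classify(criteria)
        audits.append(
            ClassAudit(
                identifier=identifier,
                printed_class=class_from_label(printed),
                engine_class=result.acmg_class,
                criteria=result.criteria_used,
            )
        )
    return audits


def load_unreported_variant_table():
    """Published table of 21 novel variants from the Taiwanese cohort study.

    Returns a pandas DataFrame with the gene, transcript/exon context,
    HGVS-style nucleotide and protein change, disease, cohort and maximum
    external allele frequencies, printed ACMG class and criterion codes.
    Used as an input for auditing the classification engine against
    published calls.
    """
    import pandas as pd

    path = _resource_files("lsdincidence") / "data" / "unreported_variants_tw.tsv"
    return pd.read_csv(str(path), sep="\t")
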