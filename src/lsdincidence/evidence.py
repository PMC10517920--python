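"""Per-variant annotation evidence and the candidate-selection rule.

A variant becomes a disease-causing candidate when either

1. it is asserted pathogenic (or likely pathogenic) in ClinVar, or carried
   as DM / DM? in HGMD; or
2. it is unreported in both databases and more than ``threshold`` of the 13
   in-silico predictors call it deleterious (the "severity score").

The 13 predictors are the standard dbNSFP panel (SIFT, both PolyPhen-2
models, LRT, MutationTaster, MutationAssessor, FATHMM, FATHMM-MKL, PROVEAN,
CADD, MetaSVM, MetaLR and M-CAP).  Their raw scores are binarized upstream;
this module consumes categorical deleterious/tolerated/missing calls, with
a helper for dbNSFP-style codes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "FATHMM-MKL",
    "PROVEAN",
    "CADD",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
)

EXTERNAL_DATABASES: tuple[str, ...] = ("ExAC", "1000Genomes", "gnomAD", "TWB")


class Call(str, Enum):
    DELETERIOUS = "D"
    TOLERATED = "T"
    MISSING = "."


class ClinvarAssertion(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    NOT_REPORTED = "not_reported"


class HgmdClass(str, Enum):
    DM = "DM"
    DM_QUESTIONABLE = "DM?"
    OTHER = "other"
    NOT_REPORTED = "not_reported"


class EvidenceSchemaError(ValueError):
    """Raised for malformed evidence records (unknown tools, bad AFs)."""


class JoinError(KeyError):
    """Raised when evidence and variant keys do not match up."""


@dataclass(frozen=True)
class EvidenceRecord:
    """Database assertions, predictor calls and external AFs for one variant."""

    variant_key: str
    clinvar: ClinvarAssertion = ClinvarAssertion.NOT_REPORTED
    hgmd: HgmdClass = HgmdClass.NOT_REPORTED
    predictor_calls: Mapping[str, Call] = field(default_factory=dict)
    external_afs: Mapping[str, float] = field(default_factory=dict)
    acmg_criteria: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        calls = dict(self.predictor_calls)
        unknown = set(calls) - set(PREDICTORS)
        if unknown:
            raise EvidenceSchemaError(
                f"{self.variant_key}: unknown predictor(s) {sorted(unknown)}"
            )
        # absent tools are treated as missing calls so records stay total
        full = {t: Call(calls.get(t, Call.MISSING)) for t in PREDICTORS}
        object.__setattr__(self, "predictor_calls", full)
        for db, af in self.external_afs.items():
            if af is not None and not 0 <= af <= 1:
                raise EvidenceSchemaError(
                    f"{self.variant_key}: {db} AF {af} outside [0, 1]"
                )
        object.__setattr__(self, "acmg_criteria", frozenset(self.acmg_criteria))

    @property
    def is_unreported(self) -> bool:
        return (
            self.clinvar is ClinvarAssertion.NOT_REPORTED
            and self.hgmd is HgmdClass.NOT_REPORTED
        )


@dataclass(frozen=True)
class SeverityScore:
    """Consensus vote of the 13 predictors: ``score`` deleterious calls."""

    score: int
    n_missing: int

    @property
    def n_tolerated(self) -> int:
        return len(PREDICTORS) - self.score - self.n_missing


@dataclass(frozen=True)
class CandidateDecision:
    accepted: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.accepted


def severity_score(record: EvidenceRecord) -> SeverityScore:
    """Count deleterious predictor calls; missing calls never count."""
    calls = record.predictor_calls
    score = sum(1 for c in calls.values() if c is Call.DELETERIOUS)
    n_missing = sum(1 for c in calls.values() if c is Call.MISSING)
    return SeverityScore(score=score, n_missing=n_missing)


_REPORTED_PATHOGENIC_HGMD = frozenset({HgmdClass.DM, HgmdClass.DM_QUESTIONABLE})


def is_candidate(
    variant_key: str,
    record: EvidenceRecord,
    threshold: int = 7,
    include_likely_pathogenic: bool = True,
) -> CandidateDecision:
    """Two-clause disease-causing-candidate rule.

    Clause 1 fires on a pathogenic ClinVar assertion (likely-pathogenic
    included unless ``include_likely_pathogenic`` is off) or an HGMD DM/DM?
    class.  Clause 2 fires only for variants unreported in both databases
    whose severity score strictly exceeds ``threshold``.  Any other
    assertion (benign, VUS, conflicting, HGMD "other") marks the variant as
    reported, blocking clause 2.
    """
    if variant_key != record.variant_key:
        raise JoinError(
            f"evidence key {record.variant_key!r} does not match variant "
            f"{variant_key!r}"
        )
    clinvar_path = {ClinvarAssertion.PATHOGENIC}
    if include_likely_pathogenic:
        clinvar_path = clinvar_path | {ClinvarAssertion.LIKELY_PATHOGENIC}
    if record.clinvar in clinvar_path or record.hgmd in _REPORTED_PATHOGENIC_HGMD:
        return CandidateDecision(True, "reported_pathogenic")
    if record.is_unreported:
        if severity_score(record).score > threshold:
            return CandidateDecision(True, "unreported_high_severity")
        return CandidateDecision(False, "unreported_low_severity")
    return CandidateDecision(False, "reported_not_pathogenic")


def max_external_af(record: EvidenceRecord) -> float | None:
    """Maximum allele frequency across the external reference databases.

    ``None`` when no database reports the variant.
    """
    present = [
        af
        for af in record.external_afs.values()
        if af is not None and not (isinstance(af, float) and math.isnan(af))
    ]
    return max(present) if present else None


def unreported_variants(
    candidate_keys: Iterable[str], records: Mapping[str, EvidenceRecord]
) -> list[str]:
    """Candidates absent from both ClinVar and HGMD (novel-variant report)."""
    return [k for k in candidate_keys if records[k].is_unreported]


def binarize_dbnsfp(
    raw: Mapping[str, str | float | None], cadd_phred_cutoff: float = 20.0
) -> dict[str, Call]:
    """Map dbNSFP-style predictor outputs onto deleterious/tolerated calls.

    Letter codes: D (and A for MutationTaster, H/M for MutationAssessor) are
    deleterious; T/N/P/L/B are tolerated.  CADD is a phred score, thresholded
    at ``cadd_phred_cutoff``.  ``None``/empty values become missing.
    """
    deleterious = {"D", "A", "H", "M"}
    tolerated = {"T", "N", "P", "L", "B"}
    out: dict[str, Call] = {}
    for tool in PREDICTORS:
        value = raw.get(tool)
        if value is None or value == "" or value == ".":
            out[tool] = Call.MISSING
        elif tool == "CADD":
            out[tool] = (
                Call.DELETERIOUS
                if float(value) >= cadd_phred_cutoff
                else Call.TOLERATED
            )
        elif str(value).upper() in deleterious:
            out[tool] = Call.DELETERIOUS
        elif str(value).upper() in tolerated:
            out[tool] = Call.TOLERATED
        else:
            raise EvidenceSchemaError(f"{tool}: unrecognized call {value!r}")
    return out


# ---------------------------------------------------------------------------
# sidecar I/O

_AF_COLUMNS = {db: f"af_{db.lower()}" for db in EXTERNAL_DATABASES}


def write_evidence_tsv(
    records: Iterable[EvidenceRecord], path: str | Path
) -> None:
    cols = (
        ["variant_key", "clinvar", "hgmd"]
        + list(PREDICTORS)
        + list(_AF_COLUMNS.values())
        + ["acmg_criteria"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            afs = []
            for db in EXTERNAL_DATABASES:
                af = r.external_afs.get(db)
                afs.append("." if af is None else f"{af:.6g}")
            criteria = ";".join(sorted(r.acmg_criteria)) or "."
            fh.write(
                "\t".join(
                    [r.variant_key, r.clinvar.value, r.hgmd.value]
                    + [r.predictor_calls[t].value for t in PREDICTORS]
                    + afs
                    + [criteria]
                )
                + "\n"
            )


def _record_from_fields(fields: Mapping[str, str]) -> EvidenceRecord:
    calls = {
        tool: Call(fields.get(tool, ".") or ".") for tool in PREDICTORS
    }
    afs: dict[str, float] = {}
    for db, col in _AF_COLUMNS.items():
        value = fields.get(col, ".")
        if value not in (".", "", None):
            afs[db] = float(value)
    criteria_field = fields.get("acmg_criteria", ".") or "."
    criteria = (
        frozenset(c for c in criteria_field.split(";") if c)
        if criteria_field != "."
        else frozenset()
    )
    return EvidenceRecord(
        variant_key=fields["variant_key"],
        clinvar=ClinvarAssertion(fields.get("clinvar", "not_reported")),
        hgmd=HgmdClass(fields.get("hgmd", "not_reported")),
        predictor_calls=calls,
        external_afs=afs,
        acmg_criteria=criteria,
    )


def read_evidence(path: str | Path) -> dict[str, EvidenceRecord]:
    """Read an evidence sidecar (TSV, or the JSON dialect) keyed by variant.

    TSV columns: ``variant_key  clinvar  hgmd  <13 predictor columns with
    D/T/. calls>  af_exac  af_1000genomes  af_gnomad  af_twb
    acmg_criteria`` (semicolon-separated codes, ``.`` for none).
    """
    path = Path(path)
    records: dict[str, EvidenceRecord] = {}
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        for rec in doc["records"]:
            r = EvidenceRecord(
                variant_key=rec["variant_key"],
                clinvar=ClinvarAssertion(rec.get("clinvar", "not_reported")),
                hgmd=HgmdClass(rec.get("hgmd", "not_reported")),
                predictor_calls={
                    t: Call(c) for t, c in rec.get("predictor_calls", {}).items()
                },
                external_afs=rec.get("external_afs", {}),
                acmg_criteria=frozenset(rec.get("acmg_criteria", [])),
            )
            records[r.variant_key] = r
        return records
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            r = _record_from_fields(fields)
            records[r.variant_key] = r
    return records
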