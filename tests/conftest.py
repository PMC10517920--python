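"""Shared fixtures: a hand-audited 50-variant funnel bundle and a
synthetic-cohort bundle, both generated on the fly under tmp dirs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from lsdincidence.acmg import AcmgClass
from lsdincidence.evidence import (
    PREDICTORS,
    Call,
    ClinvarAssertion,
    EvidenceRecord,
    HgmdClass,
    write_evidence_tsv,
)
from lsdincidence.panel import GenePanelEntry, Inheritance, write_panel
from lsdincidence.simulate import default_truth, generate_panel, write_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_calls(n_deleterious: int, n_missing: int = 0) -> dict[str, Call]:
    """First ``n_deleterious`` tools vote D, next ``n_missing`` are missing."""
    calls = {}
    for i, tool in enumerate(PREDICTORS):
        if i < n_deleterious:
            calls[tool] = Call.DELETERIOUS
        elif i < n_deleterious + n_missing:
            calls[tool] = Call.MISSING
        else:
            calls[tool] = Call.TOLERATED
    return calls


# ---------------------------------------------------------------------------
# hand-audited funnel bundle: 50 variants with known stage outcomes

FUNNEL_PANEL = [
    GenePanelEntry(
        "GENEA", "Disease A", Inheritance.AR, "NM_A", "1",
        ((1000, 1199), (2000, 2199), (3000, 3199)),
    ),
    GenePanelEntry(
        "GENEB", "Disease B", Inheritance.AR, "NM_B", "2",
        ((5000, 5199), (6000, 6199)),
    ),
    GenePanelEntry(
        "GENEX", "Disease X", Inheritance.XL, "NM_X", "X", ((100, 299),)
    ),
]

# expected hand-computed funnel: 50 ingested, 33 past stage 1 (5 removed as
# X-linked, 6 as AF > 0.05, 4 as > 2 bp from an exon, 2 as > 50 bp indels),
# 15 candidates, class tally P=3 LP=4 VUS=5 LB=1 B=2
FUNNEL_EXPECTED = {
    "ingested": 50,
    "stage1": 33,
    "candidates": 15,
    "tally": {
        AcmgClass.PATHOGENIC: 3,
        AcmgClass.LIKELY_PATHOGENIC: 4,
        AcmgClass.VUS: 5,
        AcmgClass.LIKELY_BENIGN: 1,
        AcmgClass.BENIGN: 2,
    },
}

# evidence for the 33 stage-1 survivors, in order of appearance:
#   10 reported pathogenic (candidates), 5 unreported high-score
#   (candidates), 8 unreported low-score, 6 reported non-pathogenic,
#   4 reported conflicting/other (all high scores, blocked by being reported)
CV, HG = ClinvarAssertion, HgmdClass
_KEPT_EVIDENCE = (
    [
        (CV.PATHOGENIC, HG.NOT_REPORTED, 0, "PVS1;PS1"),
        (CV.PATHOGENIC, HG.NOT_REPORTED, 5, "PVS1;PS1"),
        (CV.NOT_REPORTED, HG.DM, 3, "PVS1;PS1"),
        (CV.LIKELY_PATHOGENIC, HG.NOT_REPORTED, 2, "PS1;PM3"),
        (CV.PATHOGENIC, HG.DM, 6, "PS1;PM3"),
        (CV.NOT_REPORTED, HG.DM_QUESTIONABLE, 1, "PS1;PM3"),
        (CV.NOT_REPORTED, HG.DM, 0, "PS1;PM3"),
        (CV.PATHOGENIC, HG.NOT_REPORTED, 0, ""),
        (CV.NOT_REPORTED, HG.DM, 0, ""),
        (CV.LIKELY_PATHOGENIC, HG.NOT_REPORTED, 0, ""),
    ]
    + [
        (CV.NOT_REPORTED, HG.NOT_REPORTED, 8, ""),
        (CV.NOT_REPORTED, HG.NOT_REPORTED, 13, ""),
        (CV.NOT_REPORTED, HG.NOT_REPORTED, 9, "BA1"),
        (CV.NOT_REPORTED, HG.NOT_REPORTED, 10, "BA1"),
        (CV.NOT_REPORTED, HG.NOT_REPORTED, 8, "BS1;BP1"),
    ]
    + [(CV.NOT_REPORTED, HG.NOT_REPORTED, s, "") for s in range(8)]  # 0..7 fail
    + [
        (CV.BENIGN, HG.NOT_REPORTED, 13, ""),
        (CV.BENIGN, HG.NOT_REPORTED, 12, ""),
        (CV.LIKELY_BENIGN, HG.NOT_REPORTED, 13, ""),
        (CV.LIKELY_BENIGN, HG.NOT_REPORTED, 11, ""),
        (CV.VUS, HG.NOT_REPORTED, 13, ""),
        (CV.VUS, HG.NOT_REPORTED, 10, ""),
    ]
    + [
        (CV.CONFLICTING, HG.NOT_REPORTED, 13, ""),
        (CV.CONFLICTING, HG.NOT_REPORTED, 13, ""),
        (CV.NOT_REPORTED, HG.OTHER, 13, ""),
        (CV.NOT_REPORTED, HG.OTHER, 13, ""),
    ]
)


def _funnel_variants() -> list[tuple[str, int, str, str, int, bool]]:
    """(chrom, pos, ref, alt, AC, kept) rows; AN is 200 (100 samples)."""
    rows = []
    # 29 rare exonic SNVs in GENEA exon 1
    for k in range(29):
        rows.append(("1", 1000 + k, "A", "G", 1, True))
    rows.append(("1", 1040, "A", "G", 10, True))  # AF exactly 0.05: kept
    rows.append(("1", 1200, "A", "G", 1, True))  # 1 bp past exon 1 end
    rows.append(("1", 1201, "A", "G", 1, True))  # 2 bp past exon 1 end
    rows.append(("2", 5000, "GTT", "G", 1, True))  # small in-exon deletion
    # removed: X-linked gene
    for k in range(5):
        rows.append(("X", 100 + k, "A", "G", 1, False))
    # removed: AF > 0.05
    for k, ac in enumerate((11, 12, 20, 40, 80, 199)):
        rows.append(("1", 1050 + k, "A", "G", ac, False))
    # removed: too far from any exon (3, 11, 200, 101 bp)
    for pos in (1202, 1210, 1399, 2300):
        rows.append(("1", pos, "A", "G", 1, False))
    # removed: length change > 50 bp
    rows.append(("2", 5100, "A" + "T" * 60, "A", 1, False))
    rows.append(("2", 5102, "A", "A" + "C" * 55, 1, False))
    return rows


def _write_funnel_vcf(path: Path, rows) -> None:
    n_samples = 100
    samples = [f"P{i:03d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in ("1", "2", "X"):
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, ac, _ in sorted(
            rows, key=lambda r: ({"1": 1, "2": 2, "X": 23}[r[0]], r[1], r[3])
        ):
            n_hom = ac // 2
            n_het = ac % 2
            gts = ["1/1"] * n_hom + ["0/1"] * n_het
            gts += ["0/0"] * (n_samples - len(gts))
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


@dataclass
class FunnelBundle:
    panel_path: Path
    vcf_path: Path
    evidence_path: Path
    expected: dict


@pytest.fixture(scope="session")
def funnel_bundle(tmp_path_factory) -> FunnelBundle:
    tmp = tmp_path_factory.mktemp("funnel")
    rows = _funnel_variants()
    panel_path = tmp / "panel.json"
    write_panel(FUNNEL_PANEL, panel_path)
    vcf_path = tmp / "cohort.vcf"
    _write_funnel_vcf(vcf_path, rows)
    records = []
    kept = [r for r in rows if r[5]]
    assert len(kept) == len(_KEPT_EVIDENCE)
    for (chrom, pos, ref, alt, _, _), (cv, hg, score, crit) in zip(
        kept, _KEPT_EVIDENCE
    ):
        records.append(
            EvidenceRecord(
                variant_key=f"{chrom}-{pos}-{ref}-{alt}",
                clinvar=cv,
                hgmd=hg,
                predictor_calls=make_calls(score),
                external_afs={"TWB": 0.005},
                acmg_criteria=frozenset(c for c in crit.split(";") if c),
            )
        )
    for chrom, pos, ref, alt, _, kept_flag in rows:
        if not kept_flag:
            records.append(
                EvidenceRecord(variant_key=f"{chrom}-{pos}-{ref}-{alt}")
            )
    evidence_path = tmp / "evidence.tsv"
    write_evidence_tsv(records, evidence_path)
    return FunnelBundle(panel_path, vcf_path, evidence_path, FUNNEL_EXPECTED)


# ---------------------------------------------------------------------------
# synthetic cohort bundle (default study conditions, small-ish for speed)

@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("synthetic")
    panel = generate_panel(12, seed=0, n_xl=1, shared_disease_pairs=1)
    truth = default_truth(panel, seed=42, n_individuals=1495)
    paths = write_bundle(truth, panel, tmp)
    return {"panel": panel, "truth": truth, "paths": paths, "dir": tmp}
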