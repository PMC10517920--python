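"""Synthetic diploid cohorts with planted ground truth.

The generator emulates the data a population-sequencing carrier study
consumes: a gene panel with exon models, a multi-sample VCF of diploid
genotypes, and an evidence sidecar (database assertions, predictor calls,
ACMG criteria).  Variants are planted at specified population frequencies
and genotypes drawn per individual from Hardy-Weinberg genotype
probabilities ``(1-f)^2, 2f(1-f), f^2`` — the same model the estimator
assumes — so every downstream quantity (risk allele frequency, carrier
rate, incidence) has a closed-form expectation computable directly from
the truth specification.

Evidence templates are constructed so that the pipeline recovers each
variant's planted class unambiguously: e.g. ``clinvar_pathogenic``
variants pass the candidate rule via their database assertion and carry a
canonical criterion set ({PVS1, PS1} for pathogenic, {PS1, PM3} for likely
pathogenic); ``unreported_lowscore`` variants fail the severity-score
clause and never reach classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .acmg import AcmgClass
from .evidence import (
    PREDICTORS,
    Call,
    ClinvarAssertion,
    EvidenceRecord,
    HgmdClass,
)
from .incidence import (
    GeneIncidence,
    RiskAlleleSet,
    RiskMode,
    disease_incidence,
)
from .panel import GenePanelEntry, Inheritance


class SyntheticSpecError(ValueError):
    """Raised for inconsistent truth specifications."""


TRUE_CLASSES = {"P", "LP", "VUS", "LB", "B"}

_CLASS_TO_ACMG = {
    "P": AcmgClass.PATHOGENIC,
    "LP": AcmgClass.LIKELY_PATHOGENIC,
    "VUS": AcmgClass.VUS,
    "LB": AcmgClass.LIKELY_BENIGN,
    "B": AcmgClass.BENIGN,
}

# canonical criterion sets whose combination recovers each class exactly
_CLASS_CRITERIA = {
    "P": frozenset({"PVS1", "PS1"}),
    "LP": frozenset({"PS1", "PM3"}),
    "VUS": frozenset(),
    "LB": frozenset({"BS1", "BP1"}),
    "B": frozenset({"BA1"}),
}

# template -> (compatible classes, reaches the candidate set)
_TEMPLATES = {
    "clinvar_pathogenic": ({"P", "LP"}, True),
    "hgmd_dm": ({"P", "LP"}, True),
    "unreported_highscore": ({"P", "LP", "VUS"}, True),
    "unreported_lowscore": ({"VUS", "LB", "B"}, False),
    "clinvar_benign": ({"LB", "B"}, False),
}

# number of deleterious predictor calls per template (rest tolerated)
_TEMPLATE_SCORE = {
    "clinvar_pathogenic": 11,
    "hgmd_dm": 10,
    "unreported_highscore": 9,
    "unreported_lowscore": 4,
    "clinvar_benign": 0,
}


@dataclass(frozen=True)
class SyntheticVariant:
    gene_symbol: str
    position: int
    ref: str
    alt: str
    planted_frequency: float
    true_class: str
    evidence_template: str

    def __post_init__(self) -> None:
        if not 0 <= self.planted_frequency < 1:
            raise SyntheticSpecError(
                f"{self.gene_symbol}:{self.position}: planted frequency "
                f"{self.planted_frequency} outside [0, 1)"
            )
        if self.true_class not in TRUE_CLASSES:
            raise SyntheticSpecError(f"unknown true_class {self.true_class!r}")
        if self.evidence_template not in _TEMPLATES:
            raise SyntheticSpecError(
                f"unknown evidence_template {self.evidence_template!r}"
            )
        compatible, _ = _TEMPLATES[self.evidence_template]
        if self.true_class not in compatible:
            raise SyntheticSpecError(
                f"template {self.evidence_template} incompatible with class "
                f"{self.true_class}"
            )

    @property
    def acmg_class(self) -> AcmgClass:
        return _CLASS_TO_ACMG[self.true_class]

    @property
    def is_candidate(self) -> bool:
        return _TEMPLATES[self.evidence_template][1]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted variants plus cohort size and seed."""

    variants: tuple[SyntheticVariant, ...]
    n_individuals: int = 1495
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise SyntheticSpecError("n_individuals must be >= 1")
        object.__setattr__(self, "variants", tuple(self.variants))
        per_gene: dict[str, float] = {}
        seen: set[tuple[str, int, str, str]] = set()
        for v in self.variants:
            per_gene[v.gene_symbol] = per_gene.get(v.gene_symbol, 0.0) + v.planted_frequency
            key = (v.gene_symbol, v.position, v.ref, v.alt)
            if key in seen:
                raise SyntheticSpecError(f"duplicate planted variant {key}")
            seen.add(key)
        for gene, total in per_gene.items():
            if total >= 1.0:
                raise SyntheticSpecError(
                    f"{gene}: planted frequencies sum to {total:.3g} >= 1"
                )
            if total > 0.5:
                # outside the rare-disease regime the generator emulates
                warnings.warn(
                    f"{gene}: planted frequencies sum to {total:.3g} > 0.5",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# panel generation

def generate_panel(
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    n_xl: int = 0,
    shared_disease_pairs: int = 0,
) -> list[GenePanelEntry]:
    """Deterministic panel of non-overlapping synthetic gene models.

    Genes are laid out along chromosomes 1-22 with jittered exon lengths
    (~150 bp) and introns (~1-2 kb).  The last ``n_xl`` genes are marked
    X-linked (and placed on X); the last ``shared_disease_pairs`` pairs of
    AR genes share one disease name, exercising multi-gene pooling.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[GenePanelEntry] = []
    offsets: dict[str, int] = {}
    n_ar = n_genes - n_xl
    shared_genes: dict[int, str] = {}
    for pair in range(shared_disease_pairs):
        name = f"Synthetic shared disorder {pair + 1:02d}"
        a = n_ar - 2 * shared_disease_pairs + 2 * pair
        shared_genes[a] = name
        shared_genes[a + 1] = name
    for i in range(n_genes):
        is_xl = i >= n_ar
        chrom = "X" if is_xl else str((i % 22) + 1)
        start = offsets.get(chrom, 1_000_000)
        exons = []
        pos = start
        for _ in range(exons_per_gene):
            length = int(rng.integers(120, 240))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(1_000, 2_000))
        offsets[chrom] = pos + 10_000
        disease = shared_genes.get(i, f"Synthetic disorder {i + 1:02d}")
        entries.append(
            GenePanelEntry(
                gene_symbol=f"SGENE{i + 1:02d}",
                disease_name=disease,
                inheritance=Inheritance.XL if is_xl else Inheritance.AR,
                transcript_id=f"NM_SYN{i + 1:04d}",
                chromosome=chrom,
                exon_intervals=tuple(exons),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# truth construction helpers

def default_truth(
    panel: Sequence[GenePanelEntry],
    seed: int = 0,
    n_individuals: int = 1495,
    q_range: tuple[float, float] = (0.001, 0.02),
    vus_frequency: float = 0.002,
    benign_frequency: float = 0.01,
) -> SyntheticTruth:
    """Study-conditions truth spec over the AR genes of ``panel``.

    Each AR gene receives two disease-causing variants (one pathogenic via
    a ClinVar assertion, one likely pathogenic via HGMD) splitting a
    per-gene conservative risk frequency drawn from an even grid over
    ``q_range``, plus one unreported high-severity VUS, one benign variant
    and one low-severity unreported variant that the candidate rule must
    reject.  Cohort size defaults to 1495 individuals, the size of the
    motivating biobank study.
    """
    ar = [e for e in panel if e.inheritance is Inheritance.AR]
    if not ar:
        raise SyntheticSpecError("panel has no AR genes")
    lo, hi = q_range
    qs = np.linspace(lo, hi, num=len(ar))
    variants: list[SyntheticVariant] = []
    for entry, q_gene in zip(ar, qs):
        exons = entry.exon_intervals
        sites = [exons[k % len(exons)][0] + 5 + 7 * (k // len(exons)) for k in range(5)]
        q_gene = float(q_gene)
        variants.extend(
            [
                SyntheticVariant(
                    entry.gene_symbol, sites[0], "A", "G",
                    0.6 * q_gene, "P", "clinvar_pathogenic",
                ),
                SyntheticVariant(
                    entry.gene_symbol, sites[1], "C", "T",
                    0.4 * q_gene, "LP", "hgmd_dm",
                ),
                SyntheticVariant(
                    entry.gene_symbol, sites[2], "G", "A",
                    vus_frequency, "VUS", "unreported_highscore",
                ),
                SyntheticVariant(
                    entry.gene_symbol, sites[3], "T", "C",
                    benign_frequency, "B", "clinvar_benign",
                ),
                SyntheticVariant(
                    entry.gene_symbol, sites[4], "AT", "A",
                    0.001, "VUS", "unreported_lowscore",
                ),
            ]
        )
    return SyntheticTruth(
        variants=tuple(variants), n_individuals=n_individuals, seed=seed
    )


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (99, chrom)


def _sorted_variants(
    truth: SyntheticTruth, panel: Sequence[GenePanelEntry]
) -> list[tuple[SyntheticVariant, str]]:
    """Truth variants with their chromosome, in genomic order."""
    by_gene = {e.gene_symbol: e for e in panel}
    out = []
    for v in truth.variants:
        if v.gene_symbol not in by_gene:
            raise SyntheticSpecError(f"gene {v.gene_symbol} not in panel")
        out.append((v, by_gene[v.gene_symbol].chromosome))
    out.sort(key=lambda t: (_chrom_sort_key(t[1]), t[0].position, t[0].alt))
    return out


def variant_key(v: SyntheticVariant, panel: Sequence[GenePanelEntry]) -> str:
    chrom = {e.gene_symbol: e.chromosome for e in panel}[v.gene_symbol]
    return f"{chrom}-{v.position}-{v.ref}-{v.alt}"


# ---------------------------------------------------------------------------
# genotype simulation

def simulate_genotypes(
    truth: SyntheticTruth,
    panel: Sequence[GenePanelEntry],
    path: str | Path,
) -> Path:
    """Write a VCF 4.2 multi-sample cohort drawn from the truth spec.

    Genotypes are sampled per individual from the Hardy-Weinberg genotype
    distribution at each planted frequency, independently across variants
    (no linkage disequilibrium).  Output is deterministic given the truth
    seed: the same spec reproduces a byte-identical file.
    """
    path = Path(path)
    rng = np.random.default_rng(truth.seed)
    n = truth.n_individuals
    ordered = _sorted_variants(truth, panel)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    chroms = sorted({c for _, c in ordered}, key=_chrom_sort_key)
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lsdincidence-synthetic\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v, chrom in ordered:
            f = v.planted_frequency
            probs = [(1 - f) ** 2, 2 * f * (1 - f), f * f]
            gts = rng.choice(3, size=n, p=probs)
            fh.write(
                f"{chrom}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strings[gts])
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# evidence emission

def emit_evidence(
    truth: SyntheticTruth, panel: Sequence[GenePanelEntry]
) -> list[EvidenceRecord]:
    """Expand each planted variant's template into a full evidence record."""
    records = []
    for v, chrom in _sorted_variants(truth, panel):
        template = v.evidence_template
        clinvar = ClinvarAssertion.NOT_REPORTED
        hgmd = HgmdClass.NOT_REPORTED
        if template == "clinvar_pathogenic":
            clinvar = (
                ClinvarAssertion.PATHOGENIC
                if v.true_class == "P"
                else ClinvarAssertion.LIKELY_PATHOGENIC
            )
        elif template == "hgmd_dm":
            hgmd = HgmdClass.DM
        elif template == "clinvar_benign":
            clinvar = (
                ClinvarAssertion.BENIGN
                if v.true_class == "B"
                else ClinvarAssertion.LIKELY_BENIGN
            )
        n_del = _TEMPLATE_SCORE[template]
        calls = {
            tool: Call.DELETERIOUS if i < n_del else Call.TOLERATED
            for i, tool in enumerate(PREDICTORS)
        }
        afs: dict[str, float] = {"TWB": v.planted_frequency}
        if template in ("clinvar_pathogenic", "hgmd_dm", "clinvar_benign"):
            afs["gnomAD"] = round(v.planted_frequency * 0.8, 8)
        records.append(
            EvidenceRecord(
                variant_key=f"{chrom}-{v.position}-{v.ref}-{v.alt}",
                clinvar=clinvar,
                hgmd=hgmd,
                predictor_calls=calls,
                external_afs=afs,
                acmg_criteria=_CLASS_CRITERIA[v.true_class],
            )
        )
    return records


# ---------------------------------------------------------------------------
# closed-form expectations

def expected_report(
    truth: SyntheticTruth,
    panel: Sequence[GenePanelEntry],
    mode: RiskMode | str = RiskMode.CONSERVATIVE,
    denominator: float = 100_000,
) -> dict[str, GeneIncidence]:
    """Closed-form per-disease expectations from planted frequencies.

    Only variants whose template reaches the candidate set contribute;
    qualifying classes follow the risk mode (P+LP, or P+LP+VUS).  This is
    the oracle the pipeline's estimates are checked against.
    """
    mode = RiskMode(mode)
    qualifying = {"P", "LP"} if mode is RiskMode.CONSERVATIVE else {"P", "LP", "VUS"}
    by_gene = {e.gene_symbol: e for e in panel}
    gene_sets: dict[str, RiskAlleleSet] = {}
    for v in truth.variants:
        entry = by_gene.get(v.gene_symbol)
        if entry is None or entry.inheritance is not Inheritance.AR:
            continue
        if not v.is_candidate or v.true_class not in qualifying:
            continue
        prev = gene_sets.get(v.gene_symbol)
        keys = (prev.variant_keys if prev else frozenset()) | {
            variant_key(v, panel)
        }
        q = (prev.q if prev else 0.0) + v.planted_frequency
        gene_sets[v.gene_symbol] = RiskAlleleSet(
            gene_symbol=v.gene_symbol, mode=mode, variant_keys=keys, q=q
        )
    by_disease: dict[str, list[RiskAlleleSet]] = {}
    for gene, gs in gene_sets.items():
        by_disease.setdefault(by_gene[gene].disease_name, []).append(gs)
    return {
        disease: disease_incidence(disease, sets, denominator=denominator)
        for disease, sets in sorted(by_disease.items())
    }


# ---------------------------------------------------------------------------
# spec and bundle I/O

def read_truth(path: str | Path) -> SyntheticTruth:
    """Read a truth spec from YAML or JSON."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    variants = [
        SyntheticVariant(
            gene_symbol=v["gene_symbol"],
            position=int(v["position"]),
            ref=v["ref"],
            alt=v["alt"],
            planted_frequency=float(v["planted_frequency"]),
            true_class=v["true_class"],
            evidence_template=v["evidence_template"],
        )
        for v in doc["variants"]
    ]
    return SyntheticTruth(
        variants=tuple(variants),
        n_individuals=int(doc.get("n_individuals", 1495)),
        seed=int(doc.get("seed", 0)),
    )


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "n_individuals": truth.n_individuals,
        "seed": truth.seed,
        "variants": [
            {
                "gene_symbol": v.gene_symbol,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "planted_frequency": v.planted_frequency,
                "true_class": v.true_class,
                "evidence_template": v.evidence_template,
            }
            for v in truth.variants
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(doc, fh, sort_keys=False)
        else:
            json.dump(doc, fh, indent=1)
            fh.write("\n")


def write_bundle(
    truth: SyntheticTruth,
    panel: Sequence[GenePanelEntry],
    outdir: str | Path,
) -> dict[str, Path]:
    """Materialize the full input bundle (panel, VCF, evidence, truth)."""
    from .evidence import write_evidence_tsv
    from .panel import write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "panel.json",
        "vcf": outdir / "cohort.vcf",
        "evidence": outdir / "evidence.tsv",
        "truth": outdir / "truth.json",
    }
    write_panel(panel, paths["panel"])
    simulate_genotypes(truth, panel, paths["vcf"])
    write_evidence_tsv(emit_evidence(truth, panel), paths["evidence"])
    write_truth(truth, paths["truth"])
    return paths
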