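"""Cohort VCF ingestion and the first-stage variant filter.

Variants are read from a multi-sample diploid VCF, decomposed to biallelic
records, trimmed to parsimonious form, counted (AC/AN over called
genotypes), and annotated against the gene panel with an exon distance.
The stage-1 filter then restricts to rare exonic / near-exonic SNVs and
small indels in autosomal recessive panel genes — the funnel stage that
takes a raw gene-region callset down to the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .panel import GenePanelEntry, Inheritance, _normalize_chrom

# Variants are attributed to a panel gene when they fall within the gene's
# exon span padded by this many bases on either side.
GENE_FLANK_BP = 500


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


class CohortIngestError(ValueError):
    """Raised when a VCF carries neither genotypes nor AC/AN INFO."""


@dataclass(frozen=True)
class CohortVariant:
    """One biallelic variant with cohort allele counts and panel context.

    ``allele_frequency`` is an exact :class:`fractions.Fraction` so that
    AF x AN == AC holds as an integer identity rather than approximately.
    ``exon_distance`` is 0 for a variant overlapping an exon of its gene,
    otherwise the base-pair gap to the nearest exon boundary; ``None`` when
    the variant was not assigned to a panel gene.
    """

    chromosome: str
    position: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    allele_count: int
    allele_number: int
    gene_symbol: str | None = None
    exon_distance: int | None = None

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("require 0 <= AC <= AN")

    @property
    def allele_frequency(self) -> Fraction:
        return Fraction(self.allele_count, self.allele_number)

    @property
    def variant_key(self) -> str:
        return f"{self.chromosome}-{self.position}-{self.ref_allele}-{self.alt_allele}"

    @property
    def variant_class(self) -> VariantClass:
        return classify_alleles(self.ref_allele, self.alt_allele)

    @property
    def length_change(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))


def classify_alleles(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref) and alt.startswith(ref):
        return VariantClass.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantClass.DELETION
    return VariantClass.DELINS


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce a ref/alt pair to parsimonious form.

    Shared suffix bases are removed first, then shared prefix bases (keeping
    at least one base on each side), advancing the position past removed
    prefix bases.  Full left-alignment against the reference sequence is out
    of scope; inputs are assumed left-aligned by the caller (GATK emits
    left-aligned records).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def exon_distance(start: int, end: int, exons: Sequence[tuple[int, int]]) -> int:
    """Distance in bp from the interval [start, end] to the nearest exon.

    0 when the interval overlaps any exon; intervals are 1-based closed.
    """
    best: int | None = None
    for ex_start, ex_end in exons:
        if start <= ex_end and end >= ex_start:
            return 0
        gap = ex_start - end if end < ex_start else start - ex_end
        if best is None or gap < best:
            best = gap
    if best is None:
        raise ValueError("gene has no exons")
    return best


def _assign_gene(
    chrom: str, start: int, end: int, panel: Sequence[GenePanelEntry]
) -> tuple[str | None, int | None]:
    """Attribute a variant to the panel gene whose exons are nearest.

    Only genes on the same contig whose padded span contains the variant are
    considered; among those, the gene with the smallest exon distance wins.
    """
    best_gene: str | None = None
    best_dist: int | None = None
    for entry in panel:
        if entry.chromosome != chrom or not entry.exon_intervals:
            continue
        span_start, span_end = entry.span
        if end < span_start - GENE_FLANK_BP or start > span_end + GENE_FLANK_BP:
            continue
        dist = exon_distance(start, end, entry.exon_intervals)
        if best_dist is None or dist < best_dist:
            best_gene, best_dist = entry.gene_symbol, dist
    return best_gene, best_dist


def read_cohort_vcf(
    path: str | Path, panel: Sequence[GenePanelEntry]
) -> list[CohortVariant]:
    """Read a diploid cohort VCF into annotated :class:`CohortVariant` rows.

    Multiallelic records are decomposed into one row per alternate allele.
    AC counts alternate alleles across all called genotypes; AN counts
    called alleles only, so missing genotypes reduce the denominator rather
    than being imputed.  Sites without genotype columns fall back to the
    AC/AN INFO fields; records offering neither raise
    :class:`CohortIngestError`.  Symbolic and spanning-deletion alleles are
    skipped.
    """
    out: list[CohortVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        has_samples = len(vcf.header.samples) > 0
        for rec in vcf:
            alts = rec.alts or ()
            if not alts:
                continue
            if has_samples:
                an = 0
                ac = [0] * len(alts)
                for sample in rec.samples.values():
                    for allele in sample["GT"]:
                        if allele is None:
                            continue
                        an += 1
                        if allele >= 1:
                            ac[allele - 1] += 1
            else:
                try:
                    info_ac = rec.info.get("AC")
                    info_an = rec.info.get("AN")
                except ValueError:  # INFO keys not declared in the header
                    info_ac = info_an = None
                if info_ac is None or info_an is None:
                    raise CohortIngestError(
                        f"{rec.chrom}:{rec.pos} has neither genotypes nor "
                        "AC/AN INFO fields"
                    )
                ac = list(info_ac) if isinstance(info_ac, tuple) else [info_ac]
                an = int(info_an)
            if an == 0:
                continue
            chrom = _normalize_chrom(rec.chrom)
            for i, alt in enumerate(alts):
                if alt is None or alt.startswith("<") or alt == "*":
                    continue
                pos, ref, alt_trimmed = trim_alleles(rec.pos, rec.ref, alt)
                ref_end = pos + len(ref) - 1
                gene, dist = _assign_gene(chrom, pos, ref_end, panel)
                out.append(
                    CohortVariant(
                        chromosome=chrom,
                        position=pos,
                        ref_allele=ref,
                        alt_allele=alt_trimmed,
                        allele_count=int(ac[i]),
                        allele_number=an,
                        gene_symbol=gene,
                        exon_distance=dist,
                    )
                )
    return out


def stage1_filter(
    variants: Iterable[CohortVariant],
    panel: Sequence[GenePanelEntry],
    af_max: float = 0.05,
    exon_window: int = 2,
    ar_only: bool = True,
    max_indel_bp: int = 50,
) -> list[CohortVariant]:
    """First-stage funnel: rare, (near-)exonic, small variants in AR genes.

    Keeps variants that (i) are assigned to an autosomal recessive panel
    gene (when ``ar_only``), (ii) have cohort allele frequency <= ``af_max``
    (inclusive boundary), (iii) lie within ``exon_window`` bp of an exon,
    and (iv) change at most ``max_indel_bp`` bases of sequence.  Order is
    preserved and the filter is idempotent.  ``af_max`` may be 0, which
    keeps only monomorphic-reference rows (an intentionally empty funnel).
    """
    if not 0 <= af_max <= 1:
        raise ValueError(f"af_max must be in [0, 1], got {af_max}")
    if exon_window < 0:
        raise ValueError("exon_window must be non-negative")
    ar_genes = {e.gene_symbol for e in panel if e.inheritance is Inheritance.AR}
    kept = []
    for v in variants:
        if v.gene_symbol is None or v.exon_distance is None:
            continue
        if ar_only and v.gene_symbol not in ar_genes:
            continue
        if v.allele_frequency > Fraction(af_max).limit_denominator(10**9):
            continue
        if v.exon_distance > exon_window:
            continue
        if v.length_change > max_indel_bp:
            continue
        kept.append(v)
    return kept


def write_variants_tsv(variants: Iterable[CohortVariant], path: str | Path) -> None:
    """Write variants as TSV keyed by CHROM-POS-REF-ALT."""
    with open(path, "w") as fh:
        fh.write(
            "variant_key\tchromosome\tposition\tref\talt\tvariant_class\t"
            "gene_symbol\texon_distance\tAC\tAN\tAF\n"
        )
        for v in variants:
            fh.write(
                f"{v.variant_key}\t{v.chromosome}\t{v.position}\t"
                f"{v.ref_allele}\t{v.alt_allele}\t{v.variant_class.value}\t"
                f"{v.gene_symbol or '.'}\t"
                f"{'.' if v.exon_distance is None else v.exon_distance}\t"
                f"{v.allele_count}\t{v.allele_number}\t"
                f"{float(v.allele_frequency):.12g}\n"
            )


def with_gene_annotation(
    variant: CohortVariant, panel: Sequence[GenePanelEntry]
) -> CohortVariant:
    """Return a copy of ``variant`` (re-)annotated against ``panel``."""
    gene, dist = _assign_gene(
        variant.chromosome,
        variant.position,
        variant.position + len(variant.ref_allele) - 1,
        panel,
    )
    return replace(variant, gene_symbol=gene, exon_distance=dist)
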