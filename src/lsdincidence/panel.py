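"""Disease-gene panel handling.

A panel maps genes to diseases, inheritance modes, transcripts and exon
intervals.  Intervals are 1-based closed genomic coordinates (hg38 in the
intended application, but the code is reference-agnostic).  Panels can be
read from a single JSON document or from a BED file of exons (0-based
half-open, converted on read) paired with a TSV gene map.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Inheritance(str, Enum):
    """Mode of inheritance of the disease associated with a gene."""

    AR = "AR"  # autosomal recessive
    XL = "XL"  # X-linked
    AD = "AD"  # autosomal dominant


class PanelSchemaError(ValueError):
    """Raised when a panel file violates the documented schema."""


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene of a disease panel.

    Parameters
    ----------
    gene_symbol : str
        HGNC-style symbol, unique within a panel.
    disease_name : str
        Disease caused by biallelic (AR) or hemizygous (XL) loss of the gene.
        Several genes may share a disease name; their risk alleles are pooled
        when incidence is computed per disease.
    inheritance : Inheritance
        AR entries drive the incidence model; XL/AD entries are retained so
        that restricting to AR genes is an explicit, auditable step.
    transcript_id : str
        Reference transcript (e.g. RefSeq NM_ accession).
    chromosome : str
        Contig name without the ``chr`` prefix.
    exon_intervals : tuple of (start, end)
        1-based closed exon intervals, sorted and non-overlapping.
    """

    gene_symbol: str
    disease_name: str
    inheritance: Inheritance
    transcript_id: str
    chromosome: str
    exon_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for i, (start, end) in enumerate(self.exon_intervals):
            if end < start:
                raise PanelSchemaError(
                    f"{self.gene_symbol}: exon {i + 1} has end < start "
                    f"({start}-{end})"
                )
            if prev_end is not None and start <= prev_end:
                raise PanelSchemaError(
                    f"{self.gene_symbol}: exon intervals overlap or are "
                    f"unsorted near exon {i + 1}"
                )
            prev_end = end
        if not isinstance(self.inheritance, Inheritance):
            raise PanelSchemaError(
                f"{self.gene_symbol}: invalid inheritance "
                f"{self.inheritance!r}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        if not self.exon_intervals:
            raise ValueError(f"{self.gene_symbol} has no exons")
        return self.exon_intervals[0][0], self.exon_intervals[-1][1]


def _normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _check_unique_symbols(entries: Sequence[GenePanelEntry]) -> None:
    seen: set[str] = set()
    for e in entries:
        if e.gene_symbol in seen:
            raise PanelSchemaError(f"duplicate gene_symbol {e.gene_symbol!r}")
        seen.add(e.gene_symbol)


def read_panel(path: str | Path, bed_map: str | Path | None = None) -> list[GenePanelEntry]:
    """Read a panel from JSON, or from BED + gene-map TSV.

    JSON schema::

        {"genes": [{"gene_symbol": ..., "disease_name": ...,
                    "inheritance": "AR"|"XL"|"AD", "transcript_id": ...,
                    "chromosome": ..., "exons": [[start, end], ...]}, ...]}

    with exons in 1-based closed coordinates.  When ``path`` ends in
    ``.bed``, exon intervals are taken from the BED file (0-based half-open,
    converted here) and per-gene metadata from the TSV at ``bed_map`` with
    columns ``gene_symbol  disease_name  inheritance  transcript_id``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        if bed_map is None:
            raise PanelSchemaError("BED panel requires a gene-map TSV")
        return _read_panel_bed(path, Path(bed_map))
    return _read_panel_json(path)


def _read_panel_json(path: Path) -> list[GenePanelEntry]:
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelSchemaError(f"{path}: not valid JSON ({exc})") from exc
    entries = []
    for rec in doc.get("genes", []):
        try:
            inh = Inheritance(rec["inheritance"])
        except (KeyError, ValueError) as exc:
            raise PanelSchemaError(
                f"{path}: bad inheritance for {rec.get('gene_symbol')}"
            ) from exc
        entries.append(
            GenePanelEntry(
                gene_symbol=rec["gene_symbol"],
                disease_name=rec["disease_name"],
                inheritance=inh,
                transcript_id=rec.get("transcript_id", ""),
                chromosome=_normalize_chrom(str(rec["chromosome"])),
                exon_intervals=tuple(
                    (int(s), int(e)) for s, e in rec["exons"]
                ),
            )
        )
    _check_unique_symbols(entries)
    return entries


def _read_panel_bed(bed_path: Path, map_path: Path) -> list[GenePanelEntry]:
    meta: dict[str, dict[str, str]] = {}
    with open(map_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            meta[row["gene_symbol"]] = row
    exons: dict[str, list[tuple[str, int, int]]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelSchemaError(f"{bed_path}:{lineno}: need 4 BED columns")
            chrom, start0, end0, gene = fields[:4]
            start, end = int(start0) + 1, int(end0)  # to 1-based closed
            if end < start:
                raise PanelSchemaError(
                    f"{bed_path}:{lineno}: interval end < start"
                )
            exons.setdefault(gene, []).append((_normalize_chrom(chrom), start, end))
    entries = []
    for gene, ivals in exons.items():
        if gene not in meta:
            raise PanelSchemaError(f"gene {gene!r} in BED but not in gene map")
        chroms = {c for c, _, _ in ivals}
        if len(chroms) != 1:
            raise PanelSchemaError(f"gene {gene!r} spans multiple contigs")
        row = meta[gene]
        entries.append(
            GenePanelEntry(
                gene_symbol=gene,
                disease_name=row["disease_name"],
                inheritance=Inheritance(row["inheritance"]),
                transcript_id=row.get("transcript_id", ""),
                chromosome=chroms.pop(),
                exon_intervals=tuple(sorted((s, e) for _, s, e in ivals)),
            )
        )
    _check_unique_symbols(entries)
    return entries


def write_panel(entries: Iterable[GenePanelEntry], path: str | Path) -> None:
    """Serialize a panel to the JSON schema accepted by :func:`read_panel`."""
    doc = {
        "genes": [
            {
                "gene_symbol": e.gene_symbol,
                "disease_name": e.disease_name,
                "inheritance": e.inheritance.value,
                "transcript_id": e.transcript_id,
                "chromosome": e.chromosome,
                "exons": [list(iv) for iv in e.exon_intervals],
            }
            for e in entries
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def ar_entries(panel: Iterable[GenePanelEntry]) -> list[GenePanelEntry]:
    """Entries whose disease is autosomal recessive."""
    return [e for e in panel if e.inheritance is Inheritance.AR]
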