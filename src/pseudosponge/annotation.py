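"""Gene models on toy chromosomes.

Coordinates are 0-based, half-open throughout (BED convention): a gene
spanning ``[start, end)`` occupies bases ``start .. end-1``.  Exons are
stored sorted and pairwise disjoint; the exonic length (the ``L`` of the
RPKM formula) is the sum of exon widths, not the genomic span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

GENE_CLASSES = ("pseudogene", "mRNA", "lincRNA", "miRNA")


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, class, strand, span and exon structure."""

    gene_id: str
    gene_class: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end}) for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"{self.gene_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s}, {e}) outside span of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap or are unsorted")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start


def by_class(genes: Iterable[GeneRecord], gene_class: str) -> list[GeneRecord]:
    return [g for g in genes if g.gene_class == gene_class]


def annotations_to_frame(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    """Flatten gene records into a table (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_class": [g.gene_class for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "n_exons": [g.n_exons for g in genes],
            "exonic_length": [g.exonic_length for g in genes],
            "exon_starts": [",".join(str(s) for s, _ in g.exons) for g in genes],
            "exon_ends": [",".join(str(e) for _, e in g.exons) for g in genes],
        }
    )


def frame_to_annotations(frame: pd.DataFrame) -> list[GeneRecord]:
    """Inverse of :func:`annotations_to_frame`."""
    genes = []
    for row in frame.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                gene_class=row.gene_class,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes
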