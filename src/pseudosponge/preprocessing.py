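"""Expression preprocessing.

Fixed stage order: cross-class overlap exclusion -> RPKM -> missing-value
filter -> log2 transform.  RPKM = 1e9 * C / (N * L) where C is the read
count of a gene in a sample, N the sample's total mapped reads and L the
gene's exonic length in bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneRecord
from .errors import DomainError, ScaleError
from .matrices import CountMatrix, ExpressionMatrix

LOG_PSEUDOCOUNT = 1e-5


def _spans_overlap(a: GeneRecord, b: GeneRecord) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def exclude_overlapping_genes(annotations: list[GeneRecord]) -> list[GeneRecord]:
    """Drop every pseudogene overlapping an mRNA span and vice versa.

    The rule is symmetric and strand-agnostic; half-open adjacency
    ([100,200) next to [200,300)) is not overlap.  Other gene classes
    pass through untouched.
    """
    removed: set[str] = set()
    by_chrom: dict[str, dict[str, list[GeneRecord]]] = {}
    for g in annotations:
        if g.gene_class in ("pseudogene", "mRNA"):
            by_chrom.setdefault(g.chrom, {"pseudogene": [], "mRNA": []})[g.gene_class].append(g)
    for chrom, groups in by_chrom.items():
        pseudos = sorted(groups["pseudogene"], key=lambda g: g.start)
        mrnas = sorted(groups["mRNA"], key=lambda g: g.start)
        # sweep: for each pseudogene, scan mRNAs that can still overlap
        j = 0
        for p in pseudos:
            while j < len(mrnas) and mrnas[j].end <= p.start:
                j += 1
            k = j
            while k < len(mrnas) and mrnas[k].start < p.end:
                if _spans_overlap(p, mrnas[k]):
                    removed.add(p.gene_id)
                    removed.add(mrnas[k].gene_id)
                k += 1
    return [g for g in annotations if g.gene_id not in removed]


def compute_rpkm(counts: CountMatrix, annotations: list[GeneRecord]) -> ExpressionMatrix:
    """RPKM = 1e9 * C / (N * L); missing counts stay missing."""
    lengths = {g.gene_id: g.exonic_length for g in annotations}
    missing_genes = [g for g in counts.gene_ids if g not in lengths]
    if missing_genes:
        raise DomainError(f"genes without annotation: {missing_genes[:5]}")
    L = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    if (L <= 0).any():
        raise DomainError("every gene needs exonic_length > 0")
    N = counts.per_sample_total.to_numpy(dtype=float)
    if (N <= 0).any():
        raise DomainError("per_sample_total must be > 0 for every sample")
    rpkm = 1e9 * counts.counts.to_numpy(dtype=float) / (N[None, :] * L[:, None])
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids), scale="rpkm"
    )


def filter_missing(expr: ExpressionMatrix, max_missing_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop genes missing in strictly more than the given fraction of samples."""
    frac = expr.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    return ExpressionMatrix(expr.values.loc[keep].copy(), scale=expr.scale)


def log_transform(expr: ExpressionMatrix, pseudocount: float = LOG_PSEUDOCOUNT) -> ExpressionMatrix:
    """value -> log2(value + pseudocount).  Refuses to run twice."""
    if expr.scale != "rpkm":
        raise ScaleError("log_transform expects an rpkm-scale matrix")
    return ExpressionMatrix(np.log2(expr.values + pseudocount), scale="log2")


def preprocess(
    counts: CountMatrix,
    annotations: list[GeneRecord],
    max_missing_fraction: float = 0.5,
    pseudocount: float = LOG_PSEUDOCOUNT,
):
    """Run the full stage order; returns (kept annotations, rpkm, log2 expr).

    The RPKM matrix is restricted to the genes surviving overlap
    exclusion; the missing filter then applies to both scales so the two
    returned matrices share a gene set.
    """
    kept = exclude_overlapping_genes(annotations)
    kept_ids = [g.gene_id for g in kept if g.gene_id in set(counts.gene_ids)]
    sub = CountMatrix(counts.counts.loc[kept_ids], counts.per_sample_total)
    rpkm = compute_rpkm(sub, kept)
    rpkm = filter_missing(rpkm, max_missing_fraction)
    logged = log_transform(rpkm, pseudocount)
    return kept, rpkm, logged
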