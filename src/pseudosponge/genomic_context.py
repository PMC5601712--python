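"""Structural and evolutionary characterization of candidate pseudogenes.

Transcript length / exon counts, per-base exon-averaged conservation,
flanking protein-coding genes within a window, and the cis-acting
co-expression network between pseudogenes and their neighbors.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRecord
from .errors import DomainError
from .matrices import ExpressionMatrix


class ConservationTrack:
    """Per-base conservation scores over sorted, non-overlapping intervals.

    Built from a bedGraph-style table (chrom, start, end, score); bases
    not covered by any interval are unscored and excluded from averages.
    """

    def __init__(self, table: pd.DataFrame):
        if ((table["score"] < 0) | (table["score"] > 1)).any():
            raise DomainError("conservation scores must lie in [0, 1]")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in table.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise DomainError(f"overlapping conservation intervals on {chrom}")
            self._by_chrom[chrom] = (starts, ends, sub["score"].to_numpy(dtype=float))

    def interval_sums(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of per-base scores, number of scored bases) over [start, end)."""
        if chrom not in self._by_chrom:
            return 0.0, 0
        starts, ends, scores = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0, 0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float((scores[lo:hi] * ov).sum()), int(ov.sum())


def exon_conservation_score(gene: GeneRecord, track: ConservationTrack) -> float:
    """Mean conservation over the gene's scored exonic bases (base = unit).

    Unscored bases count in neither numerator nor denominator; returns
    NaN when no exonic base is scored.
    """
    total, n = 0.0, 0
    for s, e in gene.exons:
        t, k = track.interval_sums(gene.chrom, s, e)
        total += t
        n += k
    return total / n if n else float("nan")


def span_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge distance of half-open spans; 0 when touching/overlapping."""
    return max(0, max(a_start - b_end, b_start - a_end))


def neighboring_pcgs(
    pseudogenes: list[GeneRecord], pcgs: list[GeneRecord], window: int = 500_000
) -> pd.DataFrame:
    """All same-chromosome (pseudogene, PCG) pairs within ``window`` bp."""
    rows = []
    pcg_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in pcgs:
        pcg_by_chrom.setdefault(g.chrom, []).append(g)
    for p in pseudogenes:
        for g in pcg_by_chrom.get(p.chrom, []):
            d = span_distance(p.start, p.end, g.start, g.end)
            if d <= window:
                rows.append((p.gene_id, g.gene_id, d))
    return pd.DataFrame(rows, columns=["pseudogene_id", "pcg_id", "distance"])


def cis_network(
    neighbors: pd.DataFrame, expr: ExpressionMatrix, pcc_threshold: float = 0.6
) -> pd.DataFrame:
    """Neighbor pairs whose expression Pearson r reaches the threshold."""
    rows = []
    values = expr.values
    known = set(values.index)
    for p, g, d in zip(neighbors["pseudogene_id"], neighbors["pcg_id"], neighbors["distance"]):
        if p not in known or g not in known:
            warnings.warn(f"skipping pair ({p}, {g}): gene missing from expression", stacklevel=2)
            continue
        a = values.loc[p].to_numpy(dtype=float)
        b = values.loc[g].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            warnings.warn(f"skipping pair ({p}, {g}): fewer than 3 complete samples", stacklevel=2)
            continue
        r = float(stats.pearsonr(a[ok], b[ok]).statistic)
        if r >= pcc_threshold:
            rows.append((p, g, d, r))
    return pd.DataFrame(rows, columns=["pseudogene_id", "pcg_id", "distance", "pcc"])


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    Exact permutation enumeration when the combined size is <= 20 (ties
    handled through midranks); otherwise the normal approximation with
    tie correction.  Returns (Mann-Whitney U of the first sample, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    if n_a + n_b <= 20:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
        us = np.array(
            [
                ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
                for comb in itertools.combinations(range(n_a + n_b), n_a)
            ]
        )
        eps = 1e-9
        p_low = float(np.mean(us <= u_obs + eps))
        p_high = float(np.mean(us >= u_obs - eps))
        p = min(1.0, 2 * min(p_low, p_high))
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def feature_summary(genes: list[GeneRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene transcript length / exon count plus class-vs-class tests.

    Returns (per-gene table, pairwise Wilcoxon comparison table for both
    features between every pair of represented gene classes).
    """
    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_class": [g.gene_class for g in genes],
            "transcript_length": [g.exonic_length for g in genes],
            "n_exons": [g.n_exons for g in genes],
        }
    )
    rows = []
    classes = [c for c in table["gene_class"].unique()]
    for c1, c2 in itertools.combinations(classes, 2):
        for feature in ("transcript_length", "n_exons"):
            va = table.loc[table["gene_class"] == c1, feature]
            vb = table.loc[table["gene_class"] == c2, feature]
            stat, p = group_compare(va, vb)
            rows.append((feature, c1, c2, float(va.median()), float(vb.median()), stat, p))
    comparisons = pd.DataFrame(
        rows, columns=["feature", "class_a", "class_b", "median_a", "median_b", "statistic", "p"]
    )
    return table, comparisons


def conservation_ecdf(scores) -> pd.DataFrame:
    """Empirical CDF of per-gene conservation scores, as a (score, ecdf) table."""
    s = np.sort(np.asarray([x for x in scores if not np.isnan(x)], dtype=float))
    if s.size == 0:
        return pd.DataFrame(columns=["score", "ecdf"])
    return pd.DataFrame({"score": s, "ecdf": np.arange(1, s.size + 1) / s.size})
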