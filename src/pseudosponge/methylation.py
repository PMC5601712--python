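"""Gene-body methylation analysis.

Probe->gene-body assignment, detection-p filtering, gene-level beta
averaging, the co-methylation network over candidate ceRNA pairs, the
tumor/normal differential-expression rule (fold change > 1.5 and
FDR < 0.01), and group contrasts of methylation levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRecord
from .errors import DomainError, ScaleError
from .genomic_context import group_compare
from .matrices import ExpressionMatrix, GeneMethylation, MethylationMatrix, normal_samples, tumor_samples

FC_THRESHOLD = 1.5
DE_FDR_THRESHOLD = 0.01
MEAN_PSEUDOCOUNT = 1e-5


def assign_probes_to_gene_body(
    probe_positions: pd.DataFrame, annotations: list[GeneRecord]
) -> pd.DataFrame:
    """Probe -> gene multimap: a probe joins every gene body containing it.

    Gene body = the full half-open gene span; a probe at the end
    coordinate is outside.  Returns columns probe_id, gene_id.
    """
    rows = []
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotations:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, sub in probe_positions.groupby("chrom"):
        genes = genes_by_chrom.get(chrom, [])
        if not genes:
            continue
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        ids = np.array([g.gene_id for g in genes])
        pos = sub["pos"].to_numpy(dtype=np.int64)
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] < ends[None, :])
        pi, gi = np.nonzero(inside)
        rows.extend(zip(sub.index.to_numpy()[pi], ids[gi]))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id"])


def gene_methylation_level(
    meth: MethylationMatrix, assignment: pd.DataFrame, detection_alpha: float = 0.05
) -> GeneMethylation:
    """Per gene x sample mean beta over detection-passing assigned probes.

    A probe contributes to a cell only when its detection p < alpha; a
    cell with no passing probe is NaN.
    """
    if assignment.empty:
        raise DomainError("probe assignment is empty")
    passing = meth.detection_p.to_numpy() < detection_alpha
    beta = meth.beta.to_numpy(dtype=float)
    usable = passing & ~np.isnan(beta)
    beta_ok = np.where(usable, beta, 0.0)
    probe_index = {p: i for i, p in enumerate(meth.beta.index)}
    genes = sorted(assignment["gene_id"].unique())
    levels = np.full((len(genes), beta.shape[1]), np.nan)
    counts = np.zeros((len(genes), beta.shape[1]), dtype=int)
    by_gene = assignment.groupby("gene_id")["probe_id"].agg(list)
    for gi, gene in enumerate(genes):
        rows = [probe_index[p] for p in by_gene[gene] if p in probe_index]
        if not rows:
            continue
        n = usable[rows].sum(axis=0)
        total = beta_ok[rows].sum(axis=0)
        with np.errstate(invalid="ignore"):
            levels[gi] = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        counts[gi] = n
    cols = meth.beta.columns
    return GeneMethylation(
        levels=pd.DataFrame(levels, index=genes, columns=cols),
        n_probes=pd.DataFrame(counts, index=genes, columns=cols),
    )


def comethylation_network(
    candidates: pd.DataFrame,
    gene_meth: GeneMethylation,
    pcc_threshold: float = 0.2,
    alpha: float = 0.05,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Edges between candidate pair members co-methylated across samples.

    Pearson r over pairwise-complete gene-level methylation; an edge
    needs r >= threshold and correlation-test p < alpha.  The network
    never adds pairs — it only filters the candidate list.
    """
    levels = gene_meth.levels[samples] if samples is not None else gene_meth.levels
    rows = []
    known = set(levels.index)
    pair_iter = candidates[["pseudogene_id", "mrna_id"]].drop_duplicates().itertuples(index=False)
    for p, g in pair_iter:
        if p not in known or g not in known:
            warnings.warn(f"skipping pair ({p}, {g}): no methylation level", stacklevel=2)
            continue
        a = levels.loc[p].to_numpy(dtype=float)
        b = levels.loc[g].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            warnings.warn(
                f"skipping pair ({p}, {g}): fewer than 3 complete observations", stacklevel=2
            )
            continue
        res = stats.pearsonr(a[ok], b[ok])
        if res.statistic >= pcc_threshold and res.pvalue < alpha:
            rows.append((p, g, float(res.statistic), float(res.pvalue), int(ok.sum())))
    return pd.DataFrame(rows, columns=["pseudogene_id", "mrna_id", "pcc", "p", "n_samples"])


def differential_expression(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Tumor/normal DE per gene on RPKM-scale values.

    Symmetric fold change max(r, 1/r) of group means (pseudocount added
    to both), Wilcoxon rank-sum p, BH adjustment; DE means fold change
    > 1.5 and FDR < 0.01.  Direction is 'up' when tumor mean exceeds
    normal mean.
    """
    if expr.scale != "rpkm":
        raise ScaleError("differential_expression expects rpkm-scale values")
    t_ids = [s for s in tumor_samples(labels) if s in expr.values.columns]
    n_ids = [s for s in normal_samples(labels) if s in expr.values.columns]
    if len(t_ids) < 3 or len(n_ids) < 3:
        raise DomainError("need at least 3 samples per condition")
    rows = []
    for gene in expr.values.index:
        tv = expr.values.loc[gene, t_ids].to_numpy(dtype=float)
        nv = expr.values.loc[gene, n_ids].to_numpy(dtype=float)
        tv, nv = tv[~np.isnan(tv)], nv[~np.isnan(nv)]
        if tv.size == 0 or nv.size == 0:
            continue
        mt = tv.mean() + MEAN_PSEUDOCOUNT
        mn = nv.mean() + MEAN_PSEUDOCOUNT
        ratio = mt / mn
        fc = max(ratio, 1.0 / ratio)
        direction = "up" if ratio > 1 else "down"
        _, p = group_compare(tv, nv)
        rows.append((gene, fc, direction, p))
    out = pd.DataFrame(rows, columns=["gene_id", "fold_change", "direction", "p"])
    from .cerna import bh_adjust

    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["is_de"] = (out["fold_change"] > FC_THRESHOLD) & (out["fdr"] < DE_FDR_THRESHOLD)
    return out


def methylation_group_contrast(
    gene_meth: GeneMethylation, grouping: tuple[str, list, list]
) -> tuple[float, float, tuple[float, float]]:
    """Wilcoxon contrast of methylation between two groups.

    ``grouping`` is ('samples', ids_a, ids_b) — pooling the gene-level
    values of two sample groups (e.g. tumor vs normal) — or
    ('genes', ids_a, ids_b) — comparing per-gene mean levels of two gene
    sets (e.g. DE vs non-DE pseudogenes).  Returns (statistic, p,
    (mean_a, mean_b)).
    """
    kind, ids_a, ids_b = grouping
    levels = gene_meth.levels
    if kind == "samples":
        va = levels[list(ids_a)].to_numpy(dtype=float).ravel()
        vb = levels[list(ids_b)].to_numpy(dtype=float).ravel()
    elif kind == "genes":
        va = levels.loc[list(ids_a)].mean(axis=1, skipna=True).to_numpy(dtype=float)
        vb = levels.loc[list(ids_b)].mean(axis=1, skipna=True).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown grouping kind {kind!r}")
    va = va[~np.isnan(va)]
    vb = vb[~np.isnan(vb)]
    if va.size == 0 or vb.size == 0:
        raise DomainError("both groups must be non-empty")
    stat, p = group_compare(va, vb)
    return stat, p, (float(va.mean()), float(vb.mean()))
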