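"""Candidate ceRNA pair discovery.

Three-step pipeline: (1) build pseudogene-miRNA-mRNA triples whose miRNA
and mRNA are disease-listed; (2) score every distinct pseudogene-mRNA
pair sharing at least one miRNA with an upper-tail hypergeometric test
on the shared-miRNA count, BH-corrected; (3) keep the top decile of the
FDR-significant pairs by Pearson co-expression, requiring a significant
positive correlation.

Hypergeometric notation: the universe holds N miRNAs (all miRNAs
associated with any pseudogene or mRNA after disease filtering), the
pseudogene interacts with M of them, the mRNA with L, and x are shared:

    P(X >= x) = 1 - sum_{i<x} C(L,i) C(N-L,M-i) / C(N,M)
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ScaleError
from .matrices import ExpressionMatrix


def shared_mirna_pvalue(M: int, L: int, x: int, N: int) -> float:
    """Upper-tail probability of sharing >= x miRNAs by chance.

    Evaluated as the tail sum of the hypergeometric pmf in log space
    (log-binomials via gammaln + logsumexp), so large universes do not
    overflow.  x = 0 returns 1 by the empty-sum convention.
    """
    M, L, x, N = int(M), int(L), int(x), int(N)
    if N < 0 or M < 0 or L < 0 or x < 0:
        raise DomainError("all hypergeometric arguments must be non-negative")
    if M > N or L > N:
        raise DomainError(f"M={M}, L={L} cannot exceed the universe N={N}")
    if x > min(M, L):
        raise DomainError(f"x={x} exceeds min(M, L)={min(M, L)}")
    if x == 0:
        return 1.0
    lf = gammaln(np.arange(N + 2, dtype=float) + 1.0)

    def logc(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return lf[a] - lf[b] - lf[a - b]

    denom = logc(N, M)
    terms = [logc(L, i) + logc(N - L, M - i) - denom for i in range(x, min(M, L) + 1)]
    terms = [t for t in terms if t > -math.inf]
    if not terms:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(terms))))


def _shared_mirna_pvalues_vec(M: np.ndarray, L: np.ndarray, x: np.ndarray, N: int) -> np.ndarray:
    """Vectorized tail sums over many pairs (one shared gammaln table)."""
    lf = gammaln(np.arange(N + 2, dtype=float) + 1.0)

    def logc(a, b):
        a = np.asarray(a, dtype=int)
        b = np.asarray(b, dtype=int)
        bad = (b < 0) | (b > a)
        with np.errstate(invalid="ignore"):
            out = lf[a] - lf[np.clip(b, 0, None)] - lf[np.clip(a - b, 0, None)]
        return np.where(bad, -np.inf, out)

    out = np.empty(len(M))
    denom = logc(N, M)
    for k in range(len(M)):
        hi = min(M[k], L[k])
        if x[k] == 0:
            out[k] = 1.0
            continue
        i = np.arange(x[k], hi + 1)
        terms = logc(L[k], i) + logc(N - L[k], M[k] - i) - denom[k]
        terms = terms[np.isfinite(terms)]
        out[k] = min(1.0, math.exp(logsumexp(terms))) if terms.size else 0.0
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_triples(interactions: pd.DataFrame, disease: dict) -> pd.DataFrame:
    """All (pseudogene, miRNA, mRNA) triples with a disease-listed bridge.

    ``interactions`` columns: mirna_id, target_id, target_class.  The
    miRNA must target both ends and be disease-listed; the mRNA must be
    disease-listed; pseudogenes are not disease-filtered.
    """
    cols = ["pseudogene_id", "mirna_id", "mrna_id"]
    if interactions.empty:
        return pd.DataFrame(columns=cols)
    disease_mirnas = set(disease["disease_mirnas"])
    disease_mrnas = set(disease["disease_mrnas"])
    if not disease_mirnas or not disease_mrnas:
        warnings.warn("empty disease set: no triples can be built", stacklevel=2)
        return pd.DataFrame(columns=cols)
    edges = interactions[interactions["mirna_id"].isin(disease_mirnas)]
    psg = edges[edges["target_class"] == "pseudogene"][["mirna_id", "target_id"]].rename(
        columns={"target_id": "pseudogene_id"}
    )
    mrna = edges[(edges["target_class"] == "mRNA") & edges["target_id"].isin(disease_mrnas)][
        ["mirna_id", "target_id"]
    ].rename(columns={"target_id": "mrna_id"})
    triples = psg.merge(mrna, on="mirna_id").drop_duplicates()
    return triples[cols].sort_values(cols).reset_index(drop=True)


def score_shared_mirnas(triples: pd.DataFrame, universe: str = "global") -> pd.DataFrame:
    """Hypergeometric test per distinct pseudogene-mRNA pair in the triples.

    Returns a table with columns pseudogene_id, mrna_id, M, L, x, N, p,
    fdr.  ``universe`` = 'global' uses all miRNAs in the triple set as N;
    'pair' uses the union of the two genes' miRNA sets.
    """
    cols = ["pseudogene_id", "mrna_id", "M", "L", "x", "N", "p", "fdr"]
    if triples.empty:
        return pd.DataFrame(columns=cols)
    psg_sets = triples.groupby("pseudogene_id")["mirna_id"].agg(set)
    mrna_sets = triples.groupby("mrna_id")["mirna_id"].agg(set)
    all_mirnas = set(triples["mirna_id"])
    pairs = triples[["pseudogene_id", "mrna_id"]].drop_duplicates().reset_index(drop=True)
    M = np.array([len(psg_sets[p]) for p in pairs["pseudogene_id"]])
    L = np.array([len(mrna_sets[g]) for g in pairs["mrna_id"]])
    x = np.array(
        [len(psg_sets[p] & mrna_sets[g]) for p, g in zip(pairs["pseudogene_id"], pairs["mrna_id"])]
    )
    if universe == "global":
        N = len(all_mirnas)
        pvals = _shared_mirna_pvalues_vec(M, L, x, N)
        Ns = np.full(len(pairs), N)
    elif universe == "pair":
        Ns = np.array(
            [len(psg_sets[p] | mrna_sets[g]) for p, g in zip(pairs["pseudogene_id"], pairs["mrna_id"])]
        )
        pvals = np.array([shared_mirna_pvalue(m, l, xx, n) for m, l, xx, n in zip(M, L, x, Ns)])
    else:
        raise ValueError(f"unknown universe {universe!r}")
    out = pairs.assign(M=M, L=L, x=x, N=Ns, p=pvals)
    # pairs sharing no miRNA never arise here (triples imply x >= 1)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out[cols]


def correlation_filter(
    pairs: pd.DataFrame,
    expr: ExpressionMatrix,
    top_fraction: float = 0.10,
    samples: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep the top-correlated decile of the given (already significant) pairs.

    Adds columns pcc, pcc_p, pcc_fdr, pcc_threshold, passed.  The
    threshold is the value at ascending rank n - ceil(top_fraction*n) + 1
    of the pair correlations, so exactly ceil(top_fraction*n) pairs pass
    when correlations are distinct; ties at the threshold are all kept.
    A pair passes only with a positive correlation whose BH-adjusted
    two-sided test p is below ``alpha`` — ceRNA co-regulation is a
    positive co-expression claim.
    """
    if expr.scale != "log2":
        raise ScaleError("correlation_filter expects log2-scale expression")
    if pairs.empty:
        return pairs.assign(pcc=[], pcc_p=[], pcc_fdr=[], pcc_threshold=[], passed=[])
    values = expr.values[samples] if samples is not None else expr.values
    if values.shape[1] < 3:
        raise DomainError("need at least 3 samples for correlation")
    missing = (set(pairs["pseudogene_id"]) | set(pairs["mrna_id"])) - set(values.index)
    if missing:
        raise DomainError(f"pair genes absent from expression matrix: {sorted(missing)[:5]}")
    r = np.empty(len(pairs))
    pr = np.empty(len(pairs))
    for k, (p, g) in enumerate(zip(pairs["pseudogene_id"], pairs["mrna_id"])):
        a = values.loc[p].to_numpy(dtype=float)
        b = values.loc[g].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            raise DomainError(f"pair ({p}, {g}) has fewer than 3 complete samples")
        res = stats.pearsonr(a[ok], b[ok])
        r[k], pr[k] = res.statistic, res.pvalue
    fdr = bh_adjust(pr)
    n = len(pairs)
    k_keep = math.ceil(top_fraction * n)
    threshold = np.sort(r)[n - k_keep]
    passed = (r >= threshold) & (r > 0) & (fdr < alpha)
    return pairs.assign(pcc=r, pcc_p=pr, pcc_fdr=fdr, pcc_threshold=threshold, passed=passed)


def identify_candidates(
    interactions: pd.DataFrame,
    disease: dict,
    expr: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    top_fraction: float = 0.10,
    samples: list[str] | None = None,
    universe: str = "global",
):
    """Full discovery pipeline.

    Returns ``(candidates, passing_triples)``: a scored pair table (all
    hypergeometric-tested pairs, with ``passed`` True for those that
    survived FDR < ``fdr_threshold`` plus the correlation filter) and
    the triples induced by the passing pairs.
    """
    triples = build_triples(interactions, disease)
    # the expression profiles define the gene universe: pairs whose ends
    # did not survive preprocessing cannot be correlation-tested
    expressed = set(expr.values.index)
    triples = triples[
        triples["pseudogene_id"].isin(expressed) & triples["mrna_id"].isin(expressed)
    ].reset_index(drop=True)
    scored = score_shared_mirnas(triples, universe=universe)
    if scored.empty:
        empty = scored.assign(pcc=[], pcc_p=[], pcc_fdr=[], pcc_threshold=[], passed=[])
        return empty, triples.iloc[0:0]
    significant = scored[scored["fdr"] < fdr_threshold].reset_index(drop=True)
    if significant.empty:
        candidates = scored.assign(
            pcc=np.nan, pcc_p=np.nan, pcc_fdr=np.nan, pcc_threshold=np.nan, passed=False
        )
        return candidates, triples.iloc[0:0]
    filtered = correlation_filter(significant, expr, top_fraction=top_fraction, samples=samples)
    candidates = scored.merge(
        filtered[["pseudogene_id", "mrna_id", "pcc", "pcc_p", "pcc_fdr", "pcc_threshold", "passed"]],
        on=["pseudogene_id", "mrna_id"],
        how="left",
    )
    candidates["passed"] = candidates["passed"].eq(True)
    passing = candidates[candidates["passed"]]
    keys = set(zip(passing["pseudogene_id"], passing["mrna_id"]))
    mask = [
        (p, g) in keys for p, g in zip(triples["pseudogene_id"], triples["mrna_id"])
    ]
    return candidates, triples[np.array(mask, dtype=bool)].reset_index(drop=True) if len(triples) else triples
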