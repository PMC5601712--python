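"""Survival analysis of ceRNA triples.

Per-node univariate Cox proportional-hazards fits (Newton iteration on
the partial likelihood, Breslow tie handling by default, Efron
optional), composite per-sample risk scores (sum of node beta times
log-expression), a median split into high/low risk, Kaplan-Meier curves
and the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import DomainError, FitError
from .matrices import ExpressionMatrix

_BETA_CAP = 20.0


@dataclass
class CoxFit:
    """Univariate Cox fit: beta is the log hazard ratio (risk coefficient)."""

    node_id: str
    beta: float
    se: float
    p: float
    converged: bool
    n_events: int


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    surv = survival[["sample_id", "time", "event"]].copy()
    if surv["sample_id"].duplicated().any():
        raise DomainError("duplicate sample ids in survival table")
    if (surv["time"] <= 0).any():
        raise DomainError("survival times must be > 0")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise DomainError("event must be 0 (censored) or 1 (death)")
    return surv


def _breslow_score_info(beta, x, time, event, efron: bool):
    """Score and information of the univariate partial likelihood."""
    order = np.argsort(-time, kind="stable")  # descending time
    x = x[order]
    time = time[order]
    event = event[order]
    w = np.exp(beta * x)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    score = 0.0
    info = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        # block [i, j) shares the same time; risk set = everything up to j-1
        ev = np.nonzero(event[i:j])[0] + i
        d = len(ev)
        if d:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xe = x[ev]
            if efron and d > 1:
                w_e = w[ev]
                t0, t1, t2 = w_e.sum(), (w_e * xe).sum(), (w_e * xe * xe).sum()
                for k in range(d):
                    f = k / d
                    a0 = S0 - f * t0
                    a1 = S1 - f * t1
                    a2 = S2 - f * t2
                    score += -a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                score += xe.sum()
            else:
                score += xe.sum() - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return score, info


def univariate_cox(
    expr_vector, survival: pd.DataFrame, ties: str = "breslow", node_id: str = "x", max_iter: int = 50
) -> CoxFit:
    """Newton fit of the single-covariate Cox partial likelihood.

    ``expr_vector`` is a pandas Series indexed by sample id (or an array
    aligned with the survival table).  Monotone-likelihood divergence is
    reported as converged=False with the beta capped.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    surv = _check_survival(survival)
    if isinstance(expr_vector, pd.Series):
        x = expr_vector.reindex(surv["sample_id"]).to_numpy(dtype=float)
    else:
        x = np.asarray(expr_vector, dtype=float)
        if len(x) != len(surv):
            raise DomainError("covariate length does not match survival table")
    ok = ~np.isnan(x)
    x, time, event = x[ok], surv["time"].to_numpy(dtype=float)[ok], surv["event"].to_numpy(dtype=int)[ok]
    if event.sum() < 2:
        raise FitError("need at least 2 observed events")
    if np.ptp(x) == 0:
        raise FitError("constant covariate: Cox coefficient not identifiable")
    x = x - x.mean()  # centering for numerical stability; beta unchanged
    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        score, info = _breslow_score_info(beta, x, time, event, efron=(ties == "efron"))
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) > _BETA_CAP:
            beta = np.sign(beta) * _BETA_CAP
            break
        if abs(step) < 1e-9:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    p = 2 * stats.norm.sf(abs(beta) / se) if np.isfinite(se) and se > 0 else np.nan
    return CoxFit(node_id=node_id, beta=float(beta), se=float(se), p=float(p), converged=converged, n_events=int(event.sum()))


@dataclass
class TripleRiskModel:
    """Composite risk model of one pseudogene-miRNA-mRNA triple."""

    pseudogene_id: str
    mirna_id: str
    mrna_id: str
    node_betas: dict[str, float]
    risk_scores: pd.Series
    group: pd.Series  # 'high' / 'low'
    logrank_stat: float
    logrank_p: float
    cox_p: float
    significant: bool = False


def risk_scores_from_fits(nodes: list[str], fits: dict[str, CoxFit], expr: ExpressionMatrix) -> pd.Series:
    """Per-sample linear predictor: sum over nodes of beta * log-expression."""
    if expr.scale != "log2":
        raise DomainError("risk scores are defined on log2 expression")
    missing = [n for n in nodes if n not in expr.values.index]
    if missing:
        raise DomainError(f"nodes absent from expression: {missing}")
    score = np.zeros(expr.values.shape[1])
    for n in nodes:
        v = expr.values.loc[n].to_numpy(dtype=float)
        v = np.where(np.isnan(v), np.nanmean(v), v)
        score = score + fits[n].beta * v
    return pd.Series(score, index=expr.values.columns, name="risk_score")


def median_split(scores: pd.Series) -> pd.Series:
    """'high' for scores strictly above the median, else 'low'."""
    med = float(np.median(scores.to_numpy()))
    group = pd.Series(np.where(scores.to_numpy() > med, "high", "low"), index=scores.index, name="group")
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise DomainError("degenerate risk-score split: all scores on one side of the median")
    return group


def kaplan_meier(survival: pd.DataFrame, group: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group, as (time, survival) tables."""
    surv = _check_survival(survival).set_index("sample_id")
    curves = {}
    for name in group.unique():
        ids = group.index[group == name]
        sub = surv.loc[[i for i in ids if i in surv.index]]
        if sub.empty:
            raise DomainError(f"group {name!r} has no survival records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return curves


def logrank_test(survival: pd.DataFrame, group: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    surv = _check_survival(survival).set_index("sample_id")
    names = list(pd.unique(group))
    if len(names) != 2:
        raise DomainError(f"log-rank test needs exactly 2 groups, got {len(names)}")
    sub = {n: surv.loc[[i for i in group.index[group == n] if i in surv.index]] for n in names}
    for n, frame in sub.items():
        if frame.empty:
            raise DomainError(f"group {n!r} is empty")
    res = _ll_logrank(
        sub[names[0]]["time"],
        sub[names[1]]["time"],
        event_observed_A=sub[names[0]]["event"],
        event_observed_B=sub[names[1]]["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def evaluate_triples(
    triples: pd.DataFrame,
    expr: ExpressionMatrix,
    survival: pd.DataFrame,
    alpha: float = 0.05,
    ties: str = "breslow",
) -> list[TripleRiskModel]:
    """Risk-score every triple and rank by log-rank p.

    Per triple: univariate Cox per node, composite risk score, median
    split, log-rank p, and the Cox Wald p of the composite score refit
    as a single covariate.  Significant means both p-values < alpha.
    """
    if triples.empty:
        return []
    surv = _check_survival(survival)
    shared = [s for s in expr.values.columns if s in set(surv["sample_id"])]
    if len(shared) < 4:
        raise DomainError("too few samples shared between expression and survival")
    expr_s = ExpressionMatrix(expr.values[shared], scale=expr.scale)
    surv_s = surv[surv["sample_id"].isin(shared)].reset_index(drop=True)
    fits: dict[str, CoxFit] = {}

    def fit(node: str) -> CoxFit:
        if node not in fits:
            vec = expr_s.values.loc[node]
            fits[node] = univariate_cox(vec, surv_s, ties=ties, node_id=node)
        return fits[node]

    models = []
    for row in triples.itertuples(index=False):
        nodes = [row.pseudogene_id, row.mirna_id, row.mrna_id]
        node_fits = {n: fit(n) for n in nodes}
        scores = risk_scores_from_fits(nodes, node_fits, expr_s)
        group = median_split(scores)
        lr_stat, lr_p = logrank_test(surv_s, group)
        cox_p = univariate_cox(scores, surv_s, ties=ties, node_id="risk_score").p
        models.append(
            TripleRiskModel(
                pseudogene_id=row.pseudogene_id,
                mirna_id=row.mirna_id,
                mrna_id=row.mrna_id,
                node_betas={n: node_fits[n].beta for n in nodes},
                risk_scores=scores,
                group=group,
                logrank_stat=lr_stat,
                logrank_p=lr_p,
                cox_p=cox_p,
                significant=bool(lr_p < alpha and cox_p < alpha),
            )
        )
    models.sort(key=lambda m: m.logrank_p)
    return models


def models_to_frame(models: list[TripleRiskModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        rows.append(
            {
                "pseudogene_id": m.pseudogene_id,
                "mirna_id": m.mirna_id,
                "mrna_id": m.mrna_id,
                "beta_pseudogene": m.node_betas[m.pseudogene_id],
                "beta_mirna": m.node_betas[m.mirna_id],
                "beta_mrna": m.node_betas[m.mrna_id],
                "n_high": int((m.group == "high").sum()),
                "n_low": int((m.group == "low").sum()),
                "logrank_stat": m.logrank_stat,
                "logrank_p": m.logrank_p,
                "cox_p": m.cox_p,
                "significant": m.significant,
            }
        )
    return pd.DataFrame(rows)
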