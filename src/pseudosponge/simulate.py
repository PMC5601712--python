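"""Synthetic cohort generator with planted ceRNA structure.

Emulates the data a pseudogene-sponge study consumes — gene annotations,
miRNA-target edges, disease gene lists, tumor/normal RNA-seq counts,
450k-style methylation, clinical survival and a drug->miRNA table — with
known planted ground truth so every downstream stage can be tested for
parameter recovery:

* planted pseudogene-mRNA pairs share many miRNAs *and* are co-expressed
  (the true sponges);
* "sharing-only" pseudogene modules share miRNA sets with several mRNAs
  but are not co-expressed, mirroring the roughly 10:1 attrition between
  shared-miRNA-significant pairs and top-correlated pairs that motivates
  the correlation filter;
* a subset of planted pseudogenes is differentially expressed
  (up in tumor) and hypomethylated in tumor;
* one planted triple carries non-zero log-hazards so survival analysis
  has a signal to find.

Every generator is deterministic given the config: each draws from its
own child stream of ``SeedSequence(config.seed)``, so generators can be
called in any order or in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import GeneRecord, by_class
from .errors import ConfigError, PlacementError
from .matrices import CountMatrix, ExpressionMatrix, MethylationMatrix, make_sample_info

# child-stream keys, one per generator
_STREAM_ANNOT = 1
_STREAM_INTER = 2
_STREAM_EXPR = 3
_STREAM_METH = 4
_STREAM_SURV = 5
_STREAM_DRUG = 6
_STREAM_CONS = 7


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    The defaults are a desk-scale cohort that keeps the 3:1 tumor/normal
    imbalance of typical TCGA expression sets.
    """

    seed: int = 20170804
    n_pseudogenes: int = 50
    n_mrnas: int = 500
    n_mirnas: int = 150
    n_lincrnas: int = 50
    n_tumor: int = 90
    n_normal: int = 30
    n_planted_pairs: int = 10
    # miRNA-sharing pseudogene modules without co-expression; together with
    # the planted pairs they recreate the ~10:1 ratio of shared-miRNA
    # significant pairs to truly co-expressed pairs.
    n_sharing_only_pairs: int = 140
    shared_mirna_planted: int = 12
    shared_mirna_background: float = 2.0
    rho_expression: float = 0.6
    rho_methylation: float = 0.5
    de_log2fc: float = 1.5
    n_de_pseudogenes: int = 6
    planted_cox_betas: dict = field(default=None)  # type: ignore[assignment]
    risk_beta: float = 0.8
    mirna_risk_beta: float = -0.5
    censoring_rate: float = 0.3
    nb_mean: float = 300.0
    nb_dispersion: float = 0.05
    log_sigma: float = 1.0
    missing_rate: float = 0.01
    n_high_missing_genes: int = 5
    genome_length: int = 1_500_000
    n_chromosomes: int = 5
    probes_per_gene: int = 3
    detection_fail_rate: float = 0.02
    baseline_hazard: float = 0.1
    n_drugs: int = 40
    drug_mirnas_per_drug: float = 8.0
    disease_fraction: float = 0.7

    def validate(self) -> None:
        counts = dict(
            n_pseudogenes=self.n_pseudogenes,
            n_mrnas=self.n_mrnas,
            n_mirnas=self.n_mirnas,
            n_lincrnas=self.n_lincrnas,
            n_tumor=self.n_tumor,
            n_normal=self.n_normal,
            n_planted_pairs=self.n_planted_pairs,
            n_chromosomes=self.n_chromosomes,
            probes_per_gene=self.probes_per_gene,
            genome_length=self.genome_length,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        for name in ("rho_expression", "rho_methylation"):
            rho = getattr(self, name)
            if not (-1 < rho < 1):
                raise ConfigError(f"{name} must be in (-1, 1), got {rho}")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError(f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        if self.shared_mirna_planted > self.n_mirnas:
            raise ConfigError("shared_mirna_planted exceeds the number of miRNAs")
        if self.n_planted_pairs > min(self.n_pseudogenes, self.n_mrnas):
            raise ConfigError("more planted pairs than available pseudogenes/mRNAs")
        if self.n_de_pseudogenes > self.n_planted_pairs:
            raise ConfigError("n_de_pseudogenes exceeds n_planted_pairs")
        if self.nb_dispersion < 0 or self.nb_mean <= 0:
            raise ConfigError("negative-binomial parameters out of range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth of the planted signal, used by recovery tests."""

    true_pairs: list[tuple[str, str]]
    true_de_pseudogenes: set[str]
    true_comethylated_pairs: list[tuple[str, str]]
    true_risk_nodes: dict[str, float]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# annotations


def _make_exons(rng: np.random.Generator, start: int, end: int, n_exons: int):
    """Partition [start, end) into n_exons exons separated by introns."""
    length = end - start
    n_blocks = 2 * n_exons - 1
    if length < n_blocks:
        n_exons, n_blocks = 1, 1
    # random positive block widths summing to length
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_blocks - 1, replace=False)) if n_blocks > 1 else np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [length])) + start
    exons = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_blocks, 2))
    return exons


_CLASS_SPANS = {
    # (min span, max span, min exons, max exons)
    "mRNA": (2000, 8000, 3, 10),
    "pseudogene": (600, 3000, 1, 4),
    "lincRNA": (1000, 4000, 1, 3),
    "miRNA": (80, 120, 1, 1),
}


def generate_annotations(config: SimulationConfig) -> list[GeneRecord]:
    """Place pseudogenes, mRNAs, lincRNAs and miRNAs on toy chromosomes.

    Genes are laid out left to right with random gaps, so spans never
    overlap; raises :class:`PlacementError` if a chromosome fills up.
    """
    config.validate()
    rng = _rng(config, _STREAM_ANNOT)
    specs = (
        [("pseudogene", f"PSG{i+1:04d}") for i in range(config.n_pseudogenes)]
        + [("mRNA", f"GENE{i+1:04d}") for i in range(config.n_mrnas)]
        + [("lincRNA", f"LINC{i+1:04d}") for i in range(config.n_lincrnas)]
        + [("miRNA", f"miR-{i+1:03d}") for i in range(config.n_mirnas)]
    )
    order = rng.permutation(len(specs))
    cursors = {f"chr{c+1}": 0 for c in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    genes: list[GeneRecord] = []
    for k, idx in enumerate(order):
        gene_class, gene_id = specs[idx]
        lo, hi, emin, emax = _CLASS_SPANS[gene_class]
        span = int(rng.integers(lo, hi + 1))
        n_exons = int(rng.integers(emin, emax + 1))
        gap = int(rng.integers(100, 1000))
        chrom = chrom_names[k % config.n_chromosomes]
        start = cursors[chrom] + gap
        end = start + span
        if end > config.genome_length:
            raise PlacementError(
                f"genome_length={config.genome_length} too small: {chrom} overflows "
                f"after {len(genes)} genes"
            )
        cursors[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneRecord(gene_id, gene_class, chrom, strand, start, end, _make_exons(rng, start, end, n_exons))
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# interactions, disease lists, truth


def generate_interactions(annotations, config: SimulationConfig):
    """Bipartite miRNA->target edges, disease lists and the planted truth.

    Planted pairs each receive ``shared_mirna_planted`` common miRNAs;
    sharing-only pseudogene modules reuse one miRNA set across several
    partner mRNAs; everything else shares miRNAs at the background rate
    ``shared_mirna_background`` (expected overlap of two random target
    sets of degree sqrt(background * n_mirnas)).
    """
    config.validate()
    rng = _rng(config, _STREAM_INTER)
    pseudos = [g.gene_id for g in by_class(annotations, "pseudogene")]
    mrnas = [g.gene_id for g in by_class(annotations, "mRNA")]
    mirnas = [g.gene_id for g in by_class(annotations, "miRNA")]
    if not (pseudos and mrnas and mirnas):
        raise ConfigError("annotations must contain pseudogenes, mRNAs and miRNAs")

    base_degree = max(3, int(round(math.sqrt(config.shared_mirna_background * config.n_mirnas))))
    # skewed miRNA popularity: hub miRNAs appear in many target sets
    weights = rng.gamma(0.8, size=len(mirnas))
    weights /= weights.sum()

    def draw_mirnas(k: int) -> set[str]:
        k = min(k, len(mirnas))
        picks = rng.choice(len(mirnas), size=k, replace=False, p=weights)
        return {mirnas[i] for i in picks}

    target_sets: dict[str, set[str]] = {}
    for t in pseudos + mrnas:
        d = 1 + rng.poisson(base_degree - 1)
        target_sets[t] = draw_mirnas(d)

    # planted co-expressed sponge pairs
    psg_pool = [str(p) for p in rng.permutation(pseudos)]
    mrna_pool = [str(g) for g in rng.permutation(mrnas)]
    planted_psg = psg_pool[: config.n_planted_pairs]
    planted_mrna = mrna_pool[: config.n_planted_pairs]
    true_pairs = list(zip(planted_psg, planted_mrna))
    extra = max(3, base_degree - config.shared_mirna_planted)
    bridge_mirnas: dict[tuple[str, str], set[str]] = {}
    for p, g in true_pairs:
        shared = {str(m) for m in rng.choice(mirnas, size=config.shared_mirna_planted, replace=False)}
        bridge_mirnas[(p, g)] = shared
        target_sets[p] = shared | draw_mirnas(extra)
        target_sets[g] = shared | draw_mirnas(extra)

    # sharing-only modules: one pseudogene shares its miRNA set with
    # several mRNAs, but no expression correlation is planted
    sharing_psg = psg_pool[config.n_planted_pairs :]
    sharing_mrna = mrna_pool[config.n_planted_pairs :]
    sharing_pairs: list[tuple[str, str]] = []
    forced_mirnas: set[str] = set().union(*bridge_mirnas.values()) if bridge_mirnas else set()
    if sharing_psg and config.n_sharing_only_pairs > 0:
        module_sets = {
            p: {str(m) for m in rng.choice(mirnas, size=min(config.shared_mirna_planted, len(mirnas)), replace=False)}
            for p in sharing_psg
        }
        for p in sharing_psg:
            target_sets[p] = module_sets[p] | draw_mirnas(extra)
            forced_mirnas |= module_sets[p]
        n_pairs = min(config.n_sharing_only_pairs, len(sharing_mrna))
        for j in range(n_pairs):
            p = sharing_psg[j % len(sharing_psg)]
            g = sharing_mrna[j]
            target_sets[g] = module_sets[p] | draw_mirnas(extra)
            sharing_pairs.append((p, g))

    edges = sorted(
        (m, t, "pseudogene" if t in set(pseudos) else "mRNA")
        for t, ms in target_sets.items()
        for m in ms
    )
    interactions = pd.DataFrame(edges, columns=["mirna_id", "target_id", "target_class"])

    # disease lists: everything planted/shared is disease-listed, plus a
    # random fraction of the rest
    forced_mrnas = set(planted_mrna) | {g for _, g in sharing_pairs}
    disease_mrnas = forced_mrnas | {g for g in mrnas if rng.random() < config.disease_fraction}
    disease_mirnas = forced_mirnas | {m for m in mirnas if rng.random() < config.disease_fraction}

    de_psg = set(planted_psg[: config.n_de_pseudogenes])
    if config.planted_cox_betas is not None:
        risk_nodes = dict(config.planted_cox_betas)
        known = {g.gene_id for g in annotations}
        missing = set(risk_nodes) - known
        if missing:
            raise ConfigError(f"planted_cox_betas refers to unknown genes: {sorted(missing)}")
    else:
        p0, g0 = true_pairs[0]
        m0 = sorted(bridge_mirnas[(p0, g0)])[0]
        risk_nodes = {p0: config.risk_beta, g0: config.risk_beta, m0: config.mirna_risk_beta}

    truth = PlantedTruth(
        true_pairs=true_pairs,
        true_de_pseudogenes=de_psg,
        true_comethylated_pairs=list(true_pairs),
        true_risk_nodes=risk_nodes,
    )
    disease = {"disease_mrnas": disease_mrnas, "disease_mirnas": disease_mirnas}
    return interactions, disease, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(annotations, truth: PlantedTruth, config: SimulationConfig):
    """Negative-binomial counts with planted co-expression and DE.

    Planted pairs share a per-sample latent factor so their log-scale
    Pearson correlation targets ``rho_expression`` (count noise
    attenuates it somewhat); true DE pseudogenes get a ``de_log2fc``
    shift in tumor samples.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPR)
    gene_ids = [g.gene_id for g in annotations]
    idx = {g: i for i, g in enumerate(gene_ids)}
    samples = [f"T{i+1:03d}" for i in range(config.n_tumor)] + [
        f"N{i+1:03d}" for i in range(config.n_normal)
    ]
    info = make_sample_info(samples, ["tumor"] * config.n_tumor + ["normal"] * config.n_normal)
    n_genes, n_samples = len(gene_ids), len(samples)

    base = rng.normal(math.log2(config.nb_mean), 1.5, size=n_genes)
    latent = rng.normal(size=(n_genes, n_samples))
    rho = config.rho_expression
    for p, g in truth.true_pairs:
        z = rng.normal(size=n_samples)
        for gid in (p, g):
            latent[idx[gid]] = math.sqrt(abs(rho)) * np.sign(rho) * z + math.sqrt(
                1 - abs(rho)
            ) * rng.normal(size=n_samples)

    log2_mu = base[:, None] + config.log_sigma * latent
    tumor_mask = np.array([s.startswith("T") for s in samples])
    for gid in truth.true_de_pseudogenes:
        log2_mu[idx[gid], tumor_mask] += config.de_log2fc
    mu = np.exp2(log2_mu)

    if config.nb_dispersion > 0:
        lam = rng.gamma(1.0 / config.nb_dispersion, scale=mu * config.nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    # scattered missingness plus a handful of high-missing genes so the
    # missing-fraction filter has something to remove
    if config.missing_rate > 0:
        counts[rng.random(size=counts.shape) < config.missing_rate] = np.nan
    protected = {g for pair in truth.true_pairs for g in pair} | set(truth.true_risk_nodes)
    droppable = [g.gene_id for g in by_class(annotations, "mRNA") if g.gene_id not in protected]
    n_drop = min(config.n_high_missing_genes, len(droppable))
    for gid in rng.choice(droppable, size=n_drop, replace=False) if n_drop else []:
        counts[idx[gid], rng.random(n_samples) < 0.65] = np.nan

    frame = pd.DataFrame(counts, index=gene_ids, columns=samples)
    return CountMatrix(frame), info


# ---------------------------------------------------------------------------
# methylation


def generate_methylation(annotations, truth: PlantedTruth, config: SimulationConfig) -> MethylationMatrix:
    """Logit-normal beta values on probes placed inside gene bodies.

    Co-methylated pairs share a latent logit factor at
    ``rho_methylation``; true DE pseudogenes are hypomethylated in tumor
    (normal methylation higher). A ``detection_fail_rate`` fraction of
    probe x sample cells draws a failing detection p-value (>= 0.05).
    """
    config.validate()
    rng = _rng(config, _STREAM_METH)
    body_genes = [g for g in annotations if g.gene_class != "miRNA" and g.span_length > config.probes_per_gene]
    samples = [f"T{i+1:03d}" for i in range(config.n_tumor)] + [
        f"N{i+1:03d}" for i in range(config.n_normal)
    ]
    n_samples = len(samples)
    tumor_mask = np.array([s.startswith("T") for s in samples])

    gene_ids = [g.gene_id for g in body_genes]
    idx = {g: i for i, g in enumerate(gene_ids)}
    base = rng.normal(-0.4, 0.7, size=len(gene_ids))
    sigma_m = 0.8
    latent = rng.normal(size=(len(gene_ids), n_samples))
    rho = config.rho_methylation
    for p, g in truth.true_comethylated_pairs:
        if p not in idx or g not in idx:
            continue
        z = rng.normal(size=n_samples)
        for gid in (p, g):
            latent[idx[gid]] = math.sqrt(abs(rho)) * np.sign(rho) * z + math.sqrt(
                1 - abs(rho)
            ) * rng.normal(size=n_samples)
    logit_gene = base[:, None] + sigma_m * latent
    for gid in truth.true_de_pseudogenes:
        if gid in idx:
            logit_gene[idx[gid], tumor_mask] -= 1.0  # tumor hypomethylation

    probe_ids, probe_chrom, probe_pos, rows_beta = [], [], [], []
    k = 0
    for g in body_genes:
        positions = np.sort(rng.integers(g.start, g.end, size=config.probes_per_gene))
        offsets = rng.normal(0, 0.4, size=config.probes_per_gene)
        for j in range(config.probes_per_gene):
            k += 1
            probe_ids.append(f"cg{k:06d}")
            probe_chrom.append(g.chrom)
            probe_pos.append(int(positions[j]))
            noise = rng.normal(0, 0.3, size=n_samples)
            rows_beta.append(expit(logit_gene[idx[g.gene_id]] + offsets[j] + noise))

    beta = pd.DataFrame(np.vstack(rows_beta), index=probe_ids, columns=samples)
    fail = rng.random(size=beta.shape) < config.detection_fail_rate
    detp = np.where(fail, rng.uniform(0.05, 1.0, size=beta.shape), rng.uniform(0.0, 0.01, size=beta.shape))
    detection_p = pd.DataFrame(detp, index=probe_ids, columns=samples)
    positions = pd.DataFrame({"chrom": probe_chrom, "pos": probe_pos}, index=probe_ids)
    return MethylationMatrix(beta, detection_p, positions)


# ---------------------------------------------------------------------------
# survival


def generate_survival(expression, truth: PlantedTruth, config: SimulationConfig) -> pd.DataFrame:
    """Exponential event times with hazard exp(sum beta * z-scored log expr).

    Censoring is an independent exponential clock calibrated so roughly
    ``censoring_rate`` of subjects are censored.  Returns a table with
    columns sample_id, time, event (1 = death observed).
    """
    config.validate()
    rng = _rng(config, _STREAM_SURV)
    if isinstance(expression, CountMatrix):
        values = np.log2(expression.counts + 1.0)
    elif isinstance(expression, ExpressionMatrix):
        values = expression.values if expression.scale == "log2" else np.log2(expression.values + 1e-5)
    elif isinstance(expression, pd.DataFrame):
        values = expression
    else:
        raise TypeError(f"unsupported expression container {type(expression).__name__}")
    missing = set(truth.true_risk_nodes) - set(values.index)
    if missing:
        raise ConfigError(f"risk nodes absent from expression: {sorted(missing)}")

    samples = list(values.columns)
    lp = np.zeros(len(samples))
    for node, beta in truth.true_risk_nodes.items():
        x = values.loc[node].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        sd = x.std()
        if sd > 0:
            lp += beta * (x - x.mean()) / sd
    hazard = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    c = config.censoring_rate
    if c > 0:
        # geometric-mean hazard: calibrates the marginal censoring fraction
        # without letting a few high-risk subjects dominate the rate
        censor_rate = config.baseline_hazard * float(np.exp(np.mean(lp))) * c / (1 - c)
        censor_time = rng.exponential(1.0 / censor_rate, size=len(samples))
    else:
        censor_time = np.full(len(samples), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"sample_id": samples, "time": time, "event": event})


def simulate_survival_from_covariate(
    x: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    baseline_hazard: float = 0.1,
    censoring_rate: float = 0.2,
) -> pd.DataFrame:
    """Single-covariate proportional-hazards draw, for calibration studies."""
    x = np.asarray(x, dtype=float)
    hazard = baseline_hazard * np.exp(beta * x)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        censor_rate = baseline_hazard * float(np.exp(np.mean(beta * x))) * censoring_rate / (1 - censoring_rate)
        censor_time = rng.exponential(1.0 / censor_rate, size=len(x))
    else:
        censor_time = np.full(len(x), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"sample_id": [f"S{i+1:04d}" for i in range(len(x))], "time": time, "event": event})


# ---------------------------------------------------------------------------
# drug table


def generate_drug_table(annotations, config: SimulationConfig) -> pd.DataFrame:
    """Random drug->miRNA regulation rows (direction up/down), deduplicated."""
    config.validate()
    rng = _rng(config, _STREAM_DRUG)
    mirnas = [g.gene_id for g in by_class(annotations, "miRNA")]
    if not mirnas:
        raise ConfigError("annotations contain no miRNAs")
    rows = []
    for d in range(config.n_drugs):
        drug = f"SM{d+1:03d}"
        k = min(1 + rng.poisson(config.drug_mirnas_per_drug - 1), len(mirnas))
        for m in rng.choice(mirnas, size=k, replace=False):
            direction = "up" if rng.random() < 0.5 else "down"
            rows.append((drug, m, direction, "synthetic evidence"))
    table = pd.DataFrame(rows, columns=["drug", "mirna_id", "direction", "evidence"])
    table = table.drop_duplicates(subset=["drug", "mirna_id"], keep="first").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# conservation


def generate_conservation_track(annotations, config: SimulationConfig) -> pd.DataFrame:
    """Per-base conservation over exons, bedGraph-style intervals.

    Class-dependent means (protein-coding genes most conserved, then
    pseudogenes, then lincRNAs) so class comparisons have a planted
    direction.  A random ~10% of exonic segments is left unscored, the
    way real conservation tracks have gaps.
    """
    config.validate()
    rng = _rng(config, _STREAM_CONS)
    means = {"mRNA": 0.75, "pseudogene": 0.35, "lincRNA": 0.18, "miRNA": 0.6}
    rows = []
    for g in annotations:
        for s, e in g.exons:
            pos = s
            while pos < e:
                seg = min(int(rng.integers(20, 80)), e - pos)
                if rng.random() > 0.10:  # ~10% of segments unscored
                    score = float(np.clip(rng.normal(means[g.gene_class], 0.15), 0.0, 1.0))
                    rows.append((g.chrom, pos, pos + seg, round(score, 4)))
                pos += seg
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return track.sort_values(["chrom", "start"]).reset_index(drop=True)
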