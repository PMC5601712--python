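# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions that matter for reproducing the
outputs.

## The synthetic cohort

The generator is the pipeline's study system: a desk-scale tumor/normal
cohort in which the quantities every stage is supposed to find are
planted and therefore known.

**Scale.** 50 pseudogenes, 500 mRNAs, 150 miRNAs, 50 lincRNAs on five
toy chromosomes of 1.5 Mb; 90 tumor and 30 normal samples, keeping the
~3:1 tumor/normal imbalance typical of TCGA-style expression sets.
Class-dependent gene sizes (mRNAs 2–8 kb with 3–10 exons, pseudogenes
0.6–3 kb with 1–4 exons, lincRNAs between, miRNA hairpins ~100 bp) give
the structural contrasts their expected direction. Genes are placed left
to right with random gaps, so spans never overlap; the overlap-exclusion
stage is exercised by dedicated test constructions instead.

**Interaction network.** Each target draws its miRNA set from a skewed
popularity distribution (gamma weights), with degree
≈ √(background · n_miRNAs) ≈ 17 so two random targets share about two
miRNAs. Two kinds of structure are added on top:

* *planted pairs* (10): a pseudogene and an mRNA share 12 bridge miRNAs
  **and** a latent expression factor targeting a Pearson correlation of
  0.6 on the log scale;
* *sharing-only modules* (140 pairs): a pseudogene shares its 12-miRNA
  set with several mRNAs but gets no expression correlation.

The sharing-only modules are what make the correlation filter earn its
keep: miRNA sharing alone is significant for ~150 pairs per cohort, of
which only the planted decile is truly co-expressed — a deliberate
~10:1 attrition between sharing-significant and co-expressed pairs,
the regime the top-decile rule is designed for. Disease lists contain
all planted/shared members plus a random 70% of the rest, so the
disease filter prunes without destroying the signal.

**Counts.** Negative binomial via gamma–Poisson mixing with dispersion
α = 0.05 (variance µ + αµ²), per-gene baseline log2-means
N(log2 300, 1.5), per-gene biological log2-sd 1.0. Planted-pair members
load on a shared standard-normal factor with weight √ρ. Count noise
attenuates the realized log-scale correlation of a ρ = 0.6 pair to
≈ 0.5–0.55, which is the point: recovery is tested against what the
pipeline actually sees. 1% of cells are missing at random and five
non-planted mRNAs are missing in ~65% of samples, so the missing-value
filter removes something real.

**Differential expression.** Six of the ten planted pseudogenes get a
+1.5 log2 shift in tumor (fold change ≈ 2.8, comfortably past the 1.5
gate) and a −1.0 logit shift of tumor methylation (tumor
hypomethylation, i.e. normal samples are the more methylated group).

**Methylation.** Three probes per gene body; probe beta =
logistic(gene logit + probe offset + N(0, 0.3) noise), gene logit
baseline N(−0.4, 0.7) with per-sample sd 0.8. Co-methylated pairs (the
planted pairs) share a latent logit factor at ρ = 0.5. 2% of
probe × sample cells draw a failing detection p (≥ 0.05), the rest
p < 0.01, exercising the detection filter.

**Survival.** Event times are exponential with hazard
h₀·exp(Σ β·z), z the z-scored log2 expression of the risk nodes; the
default plants one triple (pseudogene +0.8, mRNA +0.8, miRNA −0.5).
Censoring is an independent exponential clock whose rate is calibrated
against the geometric-mean hazard so that roughly the configured 30%
of subjects are censored; an arithmetic-mean calibration would let a few
high-risk subjects drag the marginal censoring fraction far above its
target. The negative miRNA coefficient exists so the drug stage
exercises the up-regulation branch.

**What is not emulated.** Real genomic coordinates, 450k probe-region
vocabulary (TSS200/5'UTR/Body), batch effects, GC/length biases,
isoforms, clinical covariates, and the scale of real cohorts
(≈ 500 samples, 485k probes). Passing tests therefore demonstrate the
statistical machinery and its calibration, not robustness to the
technical artifacts of real TCGA data.

## Statistical conventions

* **Hypergeometric test.** P(X ≥ x) computed as a log-space tail sum
  (gammaln binomials + logsumexp); x = 0 returns 1 by the empty-sum
  convention; pairs sharing no miRNA are never tested, so they do not
  dilute the BH correction. The miRNA universe N is global — all
  distinct miRNAs in the disease-filtered triple set — with a
  pair-specific union available as an option.
* **Correlation filter.** Computed on tumor samples only by default
  (co-expression in disease tissue is the claim being made; all-sample
  correlation is a caller option). With n significant pairs the
  threshold is the value at ascending rank n − ⌈0.1·n⌉ + 1, so exactly
  ⌈0.1·n⌉ pairs pass when correlations are distinct (750 → 75; 10 → 1)
  and ties at the threshold are all retained. A passing pair must also
  have a positive correlation with BH-adjusted two-sided p < 0.05 —
  ceRNA de-repression is a positive co-expression claim, so strong
  negative correlations never pass.
* **Rank-sum test.** Exact permutation enumeration (midranks for ties,
  two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))) when the combined
  size is ≤ 20, tie-corrected normal approximation otherwise.
* **Fold change.** max(r, 1/r) of untransformed RPKM group means with a
  10⁻⁵ pseudocount on both means; both directions count as DE.
* **Gene-level methylation.** Mean beta over assigned, detection-passing
  probes; a cell with no passing probe is missing, and correlations use
  pairwise-complete samples (pairs with < 3 complete observations are
  skipped with a warning). Gene body = the full gene span.
* **Cox fits.** Own Newton iteration on the univariate partial
  likelihood with Breslow tie handling by default and Efron as an
  option; the installed proportional-hazards library is used as an
  independent cross-check in the tests (it fixes Efron ties, and on
  tie-free data the two coincide to 4 decimals). Covariates are centered
  before iteration; monotone-likelihood divergence is reported as
  converged = False with the coefficient capped at ±20. Kaplan–Meier
  curves and the log-rank test are delegated to lifelines.
* **Risk score.** Σ over the triple's nodes of β·(log2 expression) —
  the linear predictor of the univariate fits; "high risk" means
  strictly above the median score, so the median sample itself falls in
  the low group and group sizes differ by at most one for distinct
  scores. An all-equal score vector is a degenerate-split error. The
  triple's "Cox p" is the Wald p of the composite score refit as a
  single covariate.
* **BH correction** delegates to statsmodels (`fdr_bh`) and is verified
  against the textbook step-up definition in the tests.

## Problem sizes used in checks

The acceptance recomputation simulates five full cohorts at the default
scale, 100 replicates of the Cox recovery study (β = 0.8, n = 300, 20%
censoring), 1,000 replicates of the log-rank null, and a 750-pair
percentile check; the exhaustive hypergeometric validation covers all
parameter combinations with universes up to N = 12. These sizes give
stable rates while keeping a full run in the low tens of seconds.

## Known limitations

* Marginal (per-node) Cox coefficients of correlated nodes are not the
  planted joint effects: omitted-covariate attenuation and
  non-collapsibility shift them, so recovery guarantees are stated for
  the single-covariate design only.
* The censoring clock is calibrated, not exact, for non-null hazards;
  realized censoring drifts a few points from the configured fraction.
* The sharing-only modules give non-planted pseudogenes inflated miRNA
  degrees by design; degree-matched nulls are not modeled.
* Exact rank-sum enumeration is combinatorial and is capped at a
  combined 20 observations; beyond that the normal approximation is
  used even where an exact test would still be feasible.
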