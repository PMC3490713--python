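# Methods

This note records the statistical model implemented by `mirti`, the
choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish.

## Mutual information estimation

The influence channels all reduce to mutual information between two
expression profiles over the same samples. Densities are estimated by
discretization: each profile is mapped to `n_bins` codes
(default 8) and MI is the plug-in estimate on the joint histogram.
Equal-frequency binning is the default — bins are assigned from ordinal
ranks with stable tie-breaking, which (i) makes the estimate invariant
under strictly monotone transforms of either profile when values are
distinct, (ii) gives `MI(x, x)` the analytic value `log(n_bins)` when
the sample count divides evenly, and (iii) is robust for cohorts of
~100-150 samples, where 8 bins put ~12-18 observations in each
marginal bin. Equal-width binning and base-2 logarithms are available
through `MIEstimatorConfig`; natural logarithms (nats) are the default
since no analysis depends on the unit.

The plug-in estimator has a positive bias of roughly
`(n_bins − 1)² / (2n)` nats for independent profiles (~0.25 nats at
n = 100). Nothing in the pipeline interprets MI absolutely — scores are
compared to a within-network quantile — so the bias cancels where it
matters. Zero-variance profiles carry no information and score MI = 0
rather than raising, so a flat probe cannot abort a whole cohort.

## Influence score and module extraction

`miRTI(miR, t) = Corrmir · W · max CorrFPI` as defined in the README.
Decisions worth recording:

* The Pearson negativity filter applies only to the miRNA-target
  channel; `W` and `CorrFPI` use raw MI. Co-expression among protein
  partners is evidence regardless of sign, whereas a positive
  miRNA-target correlation contradicts repression.
* A gene is not its own FPI partner; the `max` over an empty partner
  set is 0, so FPI-isolated targets are structurally silenced in both
  network channels.
* The retention threshold is the 75th percentile (linear
  interpolation) of the *strictly positive* scores, applied globally
  and strictly (`>`). Zeros are structural — the product annihilates on
  any missing channel — so including them would make the quantile
  depend on decoy density rather than on the score distribution.
* All MI values for a build are computed through one discretization
  cache; rebuilding with the same inputs is bit-identical.

Degree-preserving randomization supports two nulls. `mode="margins"`
rewires the FPI by double edge swaps (10×|E| successful swaps) and the
target relation by checkerboard swaps preserving both miRNA out-degrees
and gene in-degrees; it breaks expression coupling while keeping every
degree, which is the right null for module-level enrichment questions.
`mode="mirna_degree"` keeps miRNA out-degrees and FPI degrees but
redraws target genes uniformly; this is the null for the topology
analysis, because a null that preserves gene in-degrees leaves each
gene's (degree, targeting-count) pair — and hence their correlation —
unchanged by construction.

## Topology summary statistic

The degree-vs-targeting and clustering-vs-targeting summaries are
signed per-protein Pearson correlations (Spearman optional). A
trend-line alternative — correlating bin means over exact-degree bins
with a ≥5-protein floor — is kept in the report for plotting, but it is
not the test statistic: with ~15 bins its null distribution has a
standard deviation near 0.25, so randomized networks regularly produce
|r| > 0.3 by chance alone, while the per-protein statistic is tight
(null |r| ≲ 0.1 at 600 proteins) and equally sensitive to the planted
coupling. Betweenness centrality is computed on request and reported
descriptively only.

## Activity centers

`ActivityScore` multiplies the neighborhood mean of `CorrFPI · R` by
its maximum, so a high score needs both a generally active neighborhood
and at least one strongly co-expressed, strongly differentially
expressed partner. `R = −log10(p)` from a two-sided Welch t-test
(pooled-variance optional); p-values are floored at the smallest
positive double, and genes with no variance in either group get
`p = 1`. The principal-regulator threshold is the mean score over genes
with at least one FPI partner — isolated genes score an exact 0 for
structural reasons and would otherwise dilute the mean — with the
gene's own DE p-value (threshold 0.05) separating transcriptional from
putative post-translational centers.

The resampling stability check redraws an 80% stratified subsample of
both sample groups per round, recomputes the t-tests, rebuilds the
score profile against the fixed CorrFPI map, and reports the mean
pairwise squared Pearson correlation across rounds. On the default
synthetic cohort this is ~0.72-0.87 depending on the generator seed:
the planted class effect shifts targets by 1.2 expression units against
a within-group spread near 1.9, and t-tests on ~24/56-sample subsamples
move the top scores with a coefficient of variation around 0.3. The
statistic is reproducible bit-for-bit from its seed.

## Elastic-net influence regression

Per patient (and for the activity profile), the gene-indexed response
is regressed on the miRTI design matrix with the elastic-net penalty at
mixing `α = 0.5`, a 100-value log-spaced λ path from `λ_max` down to
`λ_max · 10⁻³`, and λ chosen to minimize 10-fold cross-validated MSE
(folds are a seeded shuffle of genes; ties resolve to the sparser λ).
Fits use coordinate descent via scikit-learn's `enet_path`; for the
ridge end (`α = 0`), where no finite λ zeroes the fit, the path top is
computed with the mixing floored at 10⁻³.

Predictors are **not** standardized by default. The miRTI weights are
themselves evidence: a column holding strong influence scores over a
module should count for more than a near-zero decoy column, and
unit-variance scaling erases exactly that distinction (it reduces the
weighted design to little more than a binary target mask). With raw
columns, the planted drivers carry the top coefficient magnitudes for
~90% of patient-driver events on the default cohort, versus ~55% when
standardized. `standardize=True` restores the conventional scaling,
with coefficients mapped back to the original scale. An intercept is
always included; per-patient fits are independent of execution order.

## Survival and classification

Risk stratification is agglomerative clustering of patients with
correlation distance (1 − Pearson) and average linkage, cut at two
clusters — the standard recipe for expression profiles, both
configurable. The group comparison reports the two-group log-rank
chi-square and p (lifelines) and a hazard ratio from a single-covariate
Cox fit on the group indicator; comparisons where a group has no events
are flagged degenerate. The SVM check is a linear-kernel classifier
with `C = 1`, features z-scored inside each training fold, stratified
CV, mean fold accuracy.

## Synthetic cohorts

Defaults: 600 genes, 50 miRNAs, 30/60/10 normal/primary/metastatic
samples, 12 disjoint co-expression modules of 15 genes, 5 driver
miRNAs, repression slope 1.0, gene noise SD 0.5, degree-coupling
exponent κ = 1, hazard ratio 2.8 with uniform censoring tuned to ~50%
events. Values the model leaves open were fixed once:

* **Decoy targeting density** — 12 decoy pairs per miRNA, scaling
  sequence-prediction density (~300 conserved targets per miRNA over
  ~20k genes) to the 600-gene universe. Decoys are drawn with
  probability ∝ degree^κ and have no expression linkage.
* **Class and risk effects** — drivers shift by 1.2 units in cancer
  (a strong log-scale effect, Cohen's d ≈ 1.2 on the miRNA itself),
  plus a sign-alternating ±1.2 risk program with opposite polarity in
  the high- and low-risk groups, so each risk group is a coherent
  expression pattern rather than a mean offset (correlation-distance
  clustering is mean-invariant and cannot see a uniform shift).
* **Network** — dense intra-module subgraphs (edge probability 0.6) on
  a preferential-attachment background (2 edges per new node).

What the cohorts emulate: negative miRNA-target correlation, neighbor
co-expression, class-linked differential expression, degree-coupled
targeting, risk-linked survival. What they do not: measurement-platform
artifacts, batch effects, miRNA families and shared seed sequences,
correlated modules, non-exponential hazards, or the scale of a real
transcriptome (~26k genes). Only the *degree* coupling has a planted
sign; the clustering-coefficient correlation is emergent and small, so
its sign on synthetic data is uninformative. Passing tests establish
that each stage recovers the structure it assumes at realistic effect
sizes — not that any specific biological dataset would yield the same
rankings.

## Degenerate inputs and numerics

Influence networks with no positive scores, constant feature matrices,
and graphs too small to rewire raise `DegenerateDataError` (CLI exit
code 3), distinct from input errors (exit 2). MI round-off is clipped
at 0. Constant regression responses short-circuit to all-zero
coefficients with λ recorded as 0. Quantiles use linear interpolation
throughout. Every stochastic routine takes an explicit seed and is
reproducible bit-for-bit; nothing reads global random state.
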