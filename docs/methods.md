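# Methods

This note documents the models implemented in `assemblage`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Inference framework

Community assembly is partitioned per pair of samples in two stages.

**Stage 1 — phylogenetic turnover.** The observed abundance-weighted
βMNTD (and βMPD for the basal analogue) is standardized against a null
that randomizes phylogenetic relatedness: a single random permutation of
taxa across the tips of the tree per null run, applied jointly to the rows
and columns of the patristic matrix, shared by every sample pair in the
run. This shuffle preserves observed α- and β-diversity exactly (the
community table is untouched) and the multiset of pairwise distances. The
deviation (βNTI for βMNTD, βNRI for βMPD) is (obs − null mean)/null sd
over `n_null` runs (default 1000). |deviation| > 2 — approximately the
two-sided 5% standard-normal critical value 1.96 — flags deterministic
assembly: < −2 homogeneous selection, > +2 variable selection.

*Species-pool scoping.* The shuffle universe is explicit. Without a pool
argument it is every taxon column of the supplied table, including
taxa with zero total abundance — a table's columns declare the regional
pool, which is why the I/O layer deliberately retains zero-only taxa and
rare-taxon filtering is a separate, explicit step. With a pool (a set of
samples, e.g. the low-N and high-N microcosm series analysed separately),
the universe is the union of taxa present in those samples. This matters:
restricting the universe to the taxa of the compared samples alone
destroys the clustering signal the method exists to measure, because the
null then permutes selected taxa among themselves.

**Stage 2 — compositional turnover.** Pairs not classified by Stage 1
(|βNTI| < 2) are partitioned by Bray-Curtis Raup-Crick. Each sample is
reassembled under a two-phase null that preserves its richness and total
count: (1) occupancy — taxa drawn without replacement with probability
proportional to occurrence frequency in the pool, until the observed
richness is reached; (2) abundance — each drawn taxon is seeded with one
individual and the remaining individuals are assigned in proportion to
pool relative abundances. Phase 1 uses the exponential-keys construction
(argmin of Exp(1)/w), which is distributionally identical to sequential
weighted draws; phase 2 uses a single multinomial, identical in
distribution to assigning individuals one at a time. RC_bray =
2·((n_below + ½·n_ties)/n_null) − 1, with ties counted half so RC = 0 is
attainable; n_null defaults to 999. RC > +0.95 → dispersal limitation
coupled with drift; RC < −0.95 → homogenizing dispersal in an open system,
*weak homogeneous selection* in a closed one (`dispersal_possible=False`,
the correct setting for isolated microcosms); |RC| ≤ 0.95 → undominated.

*Thresholds are strict inequalities on both sides.* A deviation of exactly
±2 or an RC of exactly ±0.95 is assigned to the undominated side and
logged — a measure-zero event for continuous statistics, but the rule must
be deterministic. Pairs whose null sd is below 1e-10 are flagged undefined
rather than ±∞, excluded from the aggregate fractions, and counted. The
summary always reports all seven categories (including `undefined` and the
flag-exclusive weak-selection/homogenizing-dispersal pair), so fractions
are auditable and sum to 1 over defined pairs by construction.

## Phylogenetic signal

Niche optima are abundance-weighted means of the environmental axis
(optimum_i = Σ_s x_is·axis_s / Σ_s x_is). Two signal tests are provided:

* **Pagel's λ** scales the off-diagonal of the Brownian covariance
  (shared root-path lengths; tip variances unchanged). The likelihood is
  profiled analytically over the root state and rate σ², and λ is
  optimized on [0, 1] (the covariance is positive-definite throughout that
  interval for trees with positive terminal branches; estimates above 1
  are not meaningful for the λ-BM generative model used here). The LR
  statistic against λ = 0 is referred to the ½χ²₀ + ½χ²₁ boundary mixture
  — conservative relative to plain χ²₁. Agreement with
  `phytools::phylosig` is verified in the test suite.
* **Mantel correlogram** on Euclidean niche distances over patristic
  distance classes: distances standardized by their maximum, classes of
  width 0.02 (half-open, last closed, 50 classes), per-class statistic
  r = −cor(niche distance, within-class indicator), so positive r at a
  short class means close relatives share niches. p-values are two-tailed
  permutation tests (taxa relabelled; (count+1)/(n_perm+1)); classes with
  fewer than 10 pairs are reported untested; a progressive correction
  multiplies the k-th tested class's p by k, capped at 1. Agreement with
  `vegan::mantel.correlog` (r, class structure, pair counts) is verified
  in the test suite. Under Brownian traits the expected pattern is
  significant positive r at the shortest classes fading with depth;
  deep classes may show significant *negative* values (saturated trait
  divergence), so "signal absent at depth" is asserted as "no significant
  positive autocorrelation".

## Diversity and group statistics

Faith's PD includes the path to the root (this matters for single-tip
samples, whose PD is then the tip depth; their tip-shuffle null is
constant on ultrametric trees and is flagged undefined). ses.PD uses the
same tip-shuffle null as the β-deviations.

The Mantel test permutes one matrix's rows/columns jointly; the default
tail is `greater` (a positive association is the alternative of interest
when regressing turnover on time or environmental distance). The
mean-deviation test uses independent random sign flips (symmetry under
H₀), two-tailed on the mean. PERMDISP embeds the dissimilarity matrix by
principal coordinates, handles negative eigenvalues by subtracting the
imaginary-axis contribution from squared centroid distances (verified
against `vegan::betadisper` on Bray-Curtis input), and permutes group
labels with centroids recomputed per permutation. Signed deviation
matrices (βNTI) are shifted by |min| before embedding, with a log message
— the appropriate transformation for signed dissimilarities is genuinely
underdetermined, and results should be read as dispersion comparisons of
the shifted matrix. Segmented regression fits independent OLS on either
side of a user-fixed breakpoint, the boundary sample included in both
segments (matching printed ranges like 0–10.5 and 10.5–28); slope bands
are case-resampling percentile bootstraps. Natural-log transforms of
pairwise differences replace zero differences (within-level pairs) by half
the smallest positive difference, with a warning.

## Synthetic data: what it emulates

The generator produces the full causal chain the inference assumes:
phylogeny → heritable niche → environmental filtering → sampled counts.

* **Tree** — a Yule process grown to `n_tips` with an extra exponential
  waiting time so terminal branches are positive. An optional
  ultrametricity-preserving *crown compression* (node depth t ↦ T·(t/T)^δ)
  concentrates splits near the present. This matters scientifically: on a
  plain clock-like Yule tree, local tip density is nearly uniform, so a
  trait-selected set of taxa is barely closer in nearest-taxon distance
  than a random set of the same size and βNTI has almost no power to
  detect selection. Real SSU-rRNA trees are not clock-like — they show
  tight terminal crowns on long stems — and δ = 0.5 reproduces that
  contrast. The canonical recovery experiments use δ = 0.5.
* **Traits** — multivariate normal with covariance σ²·(λC_off + diag C),
  C the shared-path matrix; λ is applied to the covariance rather than the
  tree (mathematically equivalent, easier to verify).
* **Communities** — sampling weight base_i · exp(−(z_i − E)²/(2σ_w²)),
  `n_individuals` drawn multinomially; base abundances log-normal
  (meanlog 0, sdlog 1). Scenario defaults: homogeneous selection uses one
  environment equal to a randomly drawn taxon's optimum (selection favours
  an occupied — hence typically phylogenetically clustered — region of
  niche space; a quantile or mean of the trait distribution often
  straddles clades and makes recovery a lottery of the tree draw) with
  σ_w = 0.15 trait sd; variable selection spreads environments over
  mean ± 2 sd; neutral sets σ_w = ∞; dispersal limitation additionally
  restricts each sample to an independent Bernoulli(0.1) subset of the
  pool (sparse local pools — at inclusion 0.5 the RC signature is
  indistinguishable from neutral sampling). The pulse-series generator
  maps traits linearly onto ln-time optima over the sampling window
  (default 0.5 h–144 h, the classic rewetting design) and draws replicate
  bottles per time point.
* **Canonical recovery conditions** (`scenario_dataset`): 1000-taxon pool,
  12 samples, 50 individuals per sample. The large pool-to-richness ratio
  is essential — it is the regime in which these null models operate on
  real data, where a sample's richness is a small fraction of the regional
  pool; shallow sampling also makes presence stochastic *within* the
  selected set, creating the nearest-relative turnover that βNTI measures.

**What passing recovery tests do not show.** The generator draws
independent multinomial samples — it has no spatial structure, no temporal
autocorrelation between consecutive samples, no compositional biases of
PCR/sequencing, and its trait model is a single 1-D niche axis. Recovery
of the generating regime here demonstrates internal consistency of the
inference chain under its own assumptions, not robustness to the
violations real data present.

## Numerical choices and calibration facts

* Null sd below 1e-10 ⇒ undefined; β-deviation matrices carry a zero
  diagonal by convention.
* βNTI/βNRI are invariant to uniform branch-length rescaling (numerator
  and null scale together; asserted to 1e-8).
* Permutation p-values are (count + 1)/(n_perm + 1), never zero.
* RC_bray computed on tables that the null itself generated has a small
  positive bias of roughly +3/n_samples, because the pool is re-estimated
  from a finite table and chance over-representation correlates the null
  draws (at 21 samples ≈ +0.15, at 60 ≈ +0.04). The self-consistency
  check therefore uses 60-sample tables; on real datasets the analogous
  caveat is that RC values from small sample sets are conservative toward
  +1.
* λ optimization: bounded scalar search with tolerance 1e-8; endpoints 0
  and 1 evaluated explicitly and the best of the three kept, so
  logL(λ̂) ≥ max(logL(0), logL(1)) − 1e-8 by construction.
* Problem sizes used by the validation suite and acceptance script:
  neutral calibration at 100 tips × 12 samples × 999 nulls; process
  recovery at 1000 tips × 12 samples × 999 nulls, labels pooled over
  replicate pools; λ recovery over 20 replicates of 100 tips; calibration
  suites over 200 null runs each. These sizes give stable aggregate
  statistics at desk scale while exercising every code path.

## Known limitations

* Only 1-D niche axes; no multivariate niche or Blomberg's K.
* The RC null conditions on observed richness and totals; it is not a
  fixed-fixed swap algorithm, and incidence-based classic Raup-Crick is
  out of scope.
* PERMDISP on signed matrices depends on the shift convention (above).
* λ is estimated on [0, 1]; trees whose structure supports λ > 1 are
  truncated to the boundary.
* Pipelines treat the tree as given; inferring it is upstream of this
  package.
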