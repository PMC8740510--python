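# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic communities, and the numerical and
design choices that were genuinely open.

## Diversity estimators

All estimators run on raw counts; **no rarefaction is applied anywhere**.
Unequal sequencing depth therefore propagates into richness estimators
(Chao1, ACE, observed OTUs) exactly as it does in any unrarefied analysis;
the synthetic generator keeps depth within a few percent across samples, so
this matters little for the shipped benchmarks, but users of real data
should be aware of it.

* Shannon entropy is reported in nats by default (`base` exposed).
* "Simpson" is the dominance form *D* = Σ pᵢ² by default — small values
  mean a diverse community.  The unbiased estimator
  Σ nᵢ(nᵢ−1)/(N(N−1)) and the Gini–Simpson complement 1 − *D* are
  available by flag.  The default was chosen because dominance values for
  diverse 16S communities fall in the 0.005–0.08 range, which is the
  magnitude this kind of survey reports.
* Chao1 uses the classic form S_obs + F₁²/(2F₂), switching to the
  bias-corrected S_obs + F₁(F₁−1)/2 only when F₂ = 0 to avoid the zero
  division.
* ACE uses the classic rare/abundant split at 10 reads with
  γ² = max(0, (S_rare/C)·Σ i(i−1)Fᵢ / (N_rare(N_rare−1)) − 1), and falls
  back to Chao1 when the rare-class coverage C is zero (all rare OTUs
  singletons).
* Compact letter displays come from all pairwise Kruskal–Wallis tests:
  letter classes are the maximal cliques of the
  not-significantly-different graph, lettered in descending order of the
  best member's mean.  This guarantees two groups share a letter iff their
  pairwise test is non-significant.

## Beta structure

Bray–Curtis runs on raw counts (scipy's implementation).  PCoA
eigendecomposes the Gower-centered matrix −½·J·D²·J; negative eigenvalues
are reported but contribute no axes, and explained proportions are over the
positive part only.  No Cailliez/Lingoes correction is applied by default
because corrections change coordinates and none is standard for this kind
of survey.

PERMANOVA is the distance-based linear model: sequential (Type I) sums of
squares via hat-matrix projections of the cumulative model matrix, in the
user-given term order, with interactions encoded as cell-mean columns and
degrees of freedom taken from rank increments.  Pseudo-F uses the residual
mean square; p-values come from free permutation of sample labels with the
positively biased estimator (1 + #{F* ≥ F}) / (1 + n_perm), which can never
return zero.  Sequential SS and free permutation are the common `adonis`
defaults; a strata hook is exposed for restricted designs.  ANOSIM uses
mid-ranked distances and R = (r̄_between − r̄_within)/(M/2).

UPGMA clustering is implemented directly so that ties break by the
lowest-index pair — the library routines leave tie order unspecified, and a
deterministic rule is required for bit-reproducible runs.  Node heights are
half the merge distance, so cophenetic distances reproduce ultrametric
inputs and newick branch lengths (parent height − child height) follow the
midpoint convention.

## Environment association

Spearman correlations are mid-rank Pearson correlations with the two-sided
t-approximation p-value t = r·√((n−2)/(1−r²)); with up to 96 samples the
approximation is adequate, and exact permutation p-values would change
nothing at the thresholds used.  No multiple-testing correction is applied
across the OTU × factor grid by default (stars mark raw α levels 0.05 /
0.01 / 0.001); a Benjamini–Hochberg flag exists.  Environmental distances
are Euclidean over z-scored factors, so factor units are irrelevant.
Missing environmental values are masked and handled pairwise-complete; in
multi-factor distances a masked cell contributes zero after z-scoring (the
factor-mean imputation), the least destructive convention available.
Mantel and partial Mantel default to the rank-based correlation for
consistency with the rest of the package; the partial statistic is the
first-order formula r₁₂·₃ = (r₁₂ − r₁₃r₂₃)/√((1−r₁₃²)(1−r₂₃²)) with
permutation of the first matrix only.

## Co-occurrence networks and keystoneness

Nodes are OTUs passing two strict filters: prevalence > 50% of samples and
mean relative abundance above a floor.  The floor is deliberately a
required parameter with two documented presets: `0.005` (the 0.5% level
used for abundant-OTU heatmaps) and `0.0001`, the pipeline default —
a 0.5% floor caps a network at 200 nodes in theory and far fewer in
practice, so network analyses of this type effectively operate at a floor
one to two orders of magnitude lower.

Edges are Spearman correlations of relative abundances with |ρ| > 0.8 and
t-approximation *P* < 0.001, both strict, uncorrected (a BH flag exists but
raw thresholds are the convention this mirrors).  Rank correlations make
the counts-versus-relative-abundance choice nearly immaterial at equal
depths; relative abundances are used and the choice is recorded in run
metadata.  Isolated nodes are dropped by default so node counts mean
connected participants.

Topology: degree; betweenness normalized by (n−1)(n−2)/2; closeness
computed within each connected component as (n_c−1)/Σd and rescaled by
(n_c−1)/(n−1) (Wasserman–Faust), matching how desktop network tools score
disconnected graphs.  **Keystoneness** is the mean of min-max-scaled
degree, (1 − betweenness) and closeness; a constant vector scales to 0.5
everywhere (the unique symmetric choice, and the one that makes the
complete graph score 0.5).  Keystone taxa are selected
abundance-floor-first (> 1‰ mean relative abundance), then top-10 by
keystoneness, ties broken by degree then OTU id; the selection order is
recorded in output metadata because the two-step rule could be read either
way.

Note a structural property of this score: because (1 − betweenness) is
min-max scaled, whichever node carries the network's maximum betweenness
receives a zero component.  Pure bridge nodes are therefore penalized, and
the top keystones are nodes embedded in dense modules — central, redundant,
well-connected — not articulation points.

## The synthetic community generator

The generator emulates a two-habitat (water/sediment), four-season,
four-area, triplicate design: 96 samples, 2,000 OTUs, ~50,000 reads per
sample drawn multinomially (optional Dirichlet overdispersion).  Expected
composition per habitat is built from:

* **Dominants** — three shared OTUs at 10/7/5% (water) and 4/3/2%
  (sediment): water communities are dominated, sediment communities even.
* **Background** — lognormal weights sharing one ordering across habitats
  (tail sd 1.7 water / 1.5 sediment, independent jitter sd 0.3).  Sharing
  the ordering is deliberate: independent per-habitat tails concentrate
  zeros of near-detection-limit OTUs into one habitat, and aligned zero
  ties alone can push Spearman correlations past |0.8|, flooding the
  combined network with artifactual edges.  With a shared ordering,
  between-habitat bimodality is bounded near |ρ| ≈ 0.75 and cannot create
  edges by itself.
* **Planted blocks** — three per habitat, ten OTUs each, home share 0.2%
  per member.  Within a block, log abundance = baseline + σ·(√ρ·z_b +
  √(1−ρ)·ε) with ρ = 0.9 and σ = 0.5, so the within-block log correlation
  is ρ by construction.  Off-habitat shares are 8× lower for water taxa and
  3× lower for sediment taxa (sediment organisms resuspend into the water
  column more than water taxa persist in sediment); the asymmetry also
  keeps anti-aligned habitat profiles below the negative edge threshold.
* **A hub** — one water OTU tracking a common factor u (loading √0.98)
  from which its three blocks draw 45% of their latent variance
  (z_b = √0.45·u + √0.55·v_b).  Water seasonal OTUs load √0.35 on u and
  √0.2 on one block factor, integrating them into the module and giving the
  hub its degree margin.  The coupling strengths are the result of a
  design-time analysis: a hub over fully independent blocks is bounded at
  √(ρ·α) per member and cannot clear the 0.8 edge rule, while too strong a
  common factor merges the blocks into one clique in which the hub is no
  longer distinguishable.
* **An antagonist** — one water OTU loading +√0.5 on one water block's
  factor and −√0.5 on one sediment block's: the source of the network's
  negative inter-module edges, and structurally the betweenness maximum of
  the combined network (see the keystoneness note above — without such a
  node the hub itself is the top bridge and is penalized by its own
  centrality).
* **Seasonal effects** — eight OTUs per habitat (share 0.3%) whose expected
  abundance doubles in one flagged season.  σ = 0.5 was fixed by a power
  analysis so a doubling is detectable by Kruskal–Wallis within a habitat
  (12 vs 36 samples) with high probability at 50k reads.
* **Environment** — factors are linear combinations of block factors plus
  Gaussian noise (sd 0.5): NO₂-N, Temp and Trans track the three water
  blocks; MC, EC and OM track the sediment blocks; all other factors are
  pure noise.

Everything is deterministic given the seed.  A `SyntheticTruth` record
stores block membership, hub/antagonist links, seasonal flags and
environmental loadings; `truth_edge_set` (within-block pairs plus
hub–member pairs) is the positive set for recovery benchmarks.

**What the generator does not emulate:** phylogenetic signal, true
compositional overdispersion between biological replicates beyond the
lognormal noise, area effects (areas are pure replication by default),
copy-number variation, or community-wide seasonal turnover — seasonal
structure lives in the flagged OTUs, so whole-community seasonal tests
(PERMANOVA on season) are intentionally weak under defaults even though
per-OTU seasonal tests are well powered.  Passing recovery benchmarks shows
the pipeline recovers the structure this model plants, not that it is
robust to every pathology of real amplicon data.

## Problem sizes in the shipped benchmarks

Recovery benchmarks run the full study conditions (96 × 2,000 at 50k
reads) over 20 seeds.  Null-calibration uses 500 simulated datasets of 16
samples (12 for Mantel) with 199 permutations each — small per-dataset
sizes keep the permutation distribution exact enough while making 2,000
permutation tests affordable.  The determinism check runs the entire
pipeline twice at 400 OTUs / 10k reads / 49 permutations, a scale chosen
because bit-reproducibility is size-independent.

## Known limitations

* PERMANOVA supports sequential SS only; marginal (Type III) tests and
  restricted permutation are not implemented (a strata hook exists).
* The Spearman p-value is asymptotic; below ~10 samples an exact
  permutation p would be preferable.
* Network inference is plain thresholded correlation, inheriting its known
  compositional biases; compositionally robust estimators (SparCC-style)
  are out of scope.
* UPGMA is O(n³) in the number of items — fine for ≤ a few hundred
  samples, not for clustering thousands of OTUs.
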