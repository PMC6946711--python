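# Methods

`mycoassembly` infers which ecological processes — selection, dispersal,
or stochastic drift — structured a set of microbial communities, using
pairwise null models, and asks whether the communities share universal
ecological dynamics, using dissimilarity–overlap analysis.  Because such
inferences are easy to get subtly wrong, the package ships with a
synthetic-data generator that produces communities whose assembly
process is known by construction; every inferential component is tested
against that ground truth.

## Null-model inference

**betaMNTD / betaNTI.**  For a pair of communities, the beta mean
nearest taxon distance (betaMNTD) averages, over the taxa of each
sample, the patristic distance to the closest relative in the other
sample (abundance-weighted by default; symmetrized over both
directions).  The null model re-places taxa on the phylogeny by
shuffling tip labels — one label permutation per replicate, shared by
all pairs of that replicate — and betaNTI is the z-score of the
observed betaMNTD against 999 such replicates.  betaNTI ≤ −2 indicates
phylogenetic clustering beyond chance (homogeneous selection),
betaNTI ≥ +2 overdispersion (variable selection).  Because shuffling
moves taxa but not community membership, shared taxa contribute zero
distance in both the observed and every null replicate; the statistic
isolates phylogenetic structure.  On trees where the statistic is
invariant to relabeling (e.g. a star topology) the null standard
deviation collapses; such pairs are flagged degenerate (null sd <
1e-12), reported as undefined, and classified on the taxonomic index
alone.

**Raup–Crick (RCI).**  The default, presence-based variant draws null
communities that preserve each sample's richness, sampling taxa without
replacement with probability proportional to their occupancy frequency
across all samples (Gumbel-top-k sampling, equivalent to successive
weighted draws), and ranks the observed shared-taxon count in the null
distribution of shared counts.  The abundance variant additionally
preserves total abundance (one individual per drawn taxon, the rest
multinomial on pool-wide relative abundance) and ranks the observed
Bray–Curtis dissimilarity.  Both are scaled to
RCI = 2·((n_null_more_similar + 0.5·ties)/reps) − 1, so −1 means the
pair is more similar than every null realization.  RCI ≤ −0.95 flags
homogenizing processes, RCI ≥ +0.95 dispersal limitation.

**Classification.**  Per pair: betaNTI ≥ 2 → variable selection;
betaNTI ≤ −2 → homogeneous selection; otherwise RCI ≥ 0.95 → dispersal
limitation; RCI ≤ −0.95 → the ambiguous homogenizing class (homogeneous
selection or homogenizing dispersal — the phylogenetic index carries no
signal to separate them); |betaNTI| < 2 and |RCI| < 0.95 →
stochastic/undominated, the class attributed to drift and stochastic
colonization.  Group-level stochastic fractions are the proportion of
within-group pairs in the last class.

A structural caveat worth stating: with the occupancy-based null,
dispersal limitation is only detectable relative to a backdrop.  Random
colonization subsets of size r from a pool of S share r²/S taxa on
average — exactly what a flat-occupancy null predicts — so a table
consisting solely of dispersal-limited replicates yields RCI ≈ 0.  The
signature (RCI → +1) appears when the same table also contains
well-mixed communities whose shared core concentrates the occupancy
distribution.  The property tests construct exactly that situation.

## Dissimilarity–overlap analysis

For every pair of relative-abundance profiles, overlap is the mean
total abundance of the shared taxa, and dissimilarity is the root
Jensen–Shannon divergence (natural log; upper bound sqrt(ln 2)) of the
two profiles renormalized over the shared set.  Zero-overlap pairs are
excluded and counted.  The curve is a LOWESS fit (span 0.2, degree 1,
two robustness iterations).  Bootstraps resample samples — not pairs,
which are not independent — rebuild the pair set, refit, and record the
overlap where the terminal negative slope begins; the change point
x_min is the bootstrap median (replicates without a negative terminal
slope contribute the maximum observed overlap), Fns is the fraction of
real pairs with overlap beyond x_min, and the result is significant
when ≥ 95% of bootstrap curves end in negative slope.  p-values from a
family of guild-wise analyses can be Bonferroni-adjusted with the
provided helper.

## Supporting statistics

* **PERMANOVA** is the sequential (Type-I) trace decomposition of the
  Gower-centered squared-distance matrix; R² values for terms plus
  residual sum to one, and p-values come from free permutation of
  sample labels, reported as (b+1)/(m+1) — or from complete enumeration
  of all relabelings when requested (n ≤ 8).  Term order matters and is
  surfaced in the output.
* **Mantel** correlates lower-triangle entries (Pearson or Spearman),
  permuting rows and columns of the second matrix jointly.
* **Beta dispersion** embeds samples by principal coordinates keeping
  negative-eigenvalue axes, subtracts squared imaginary-axis
  contributions from distances to group centroids, and tests the
  one-way F on those distances by permutation.
* **PCoA** is the eigendecomposition of the Gower matrix; the Lingoes
  correction (adding the smallest constant that removes negative
  eigenvalues from the squared distances) is available for
  non-Euclidean dissimilarities.
* **The size–stochasticity model** regresses group-level stochastic
  fractions on log10 community size with a random intercept per
  compartment (statsmodels MixedLM; REML; optimizer fallbacks, and the
  OLS limit when the random variance collapses).  Marginal and
  conditional R² follow the variance-partition form
  (var_fixed [+ var_random]) / (var_fixed + var_random + var_residual).
* **Co-abundance clustering** connects taxa whose CLR profiles have
  Pearson r > 0.8 and proportionality phi = var(clr_i − clr_j)/var(clr_i)
  < 0.1 (symmetrized by the smaller direction), with correlation
  p-values Bonferroni-corrected over all taxon pairs; clusters are
  connected components ordered by size.  Constant CLR columns cannot
  form edges and remain singletons.
* **The community-age delay protocol** splits control samples 50/50
  (stratified by week), trains a 500-tree random forest of week on all
  taxa, reranks features by importance, refits a sparse forest on the
  top k features (k by 5-fold cross-validated error by default), and
  reports, per treatment and week, the mean predicted age of held-out
  controls minus that of treatment samples.  Tree-ensemble regression
  compresses predictions toward the training mean near the ends of the
  season, so a true 2-week delay is recovered as ≈ 1.8–1.9 weeks.

## Preprocessing

Counts are either rarefied (multivariate hypergeometric, i.e. without
replacement) to a fixed depth, or treated compositionally: zeros
replaced by the count-zero multiplicative method (pseudo-proportion
0.5/row_total, configurable; always below the smallest observed
proportion; nonzero proportions rescaled to stay on the simplex)
followed by the centred log-ratio transform.  Aitchison distance is
Euclidean distance between CLR rows.  Note that the CZM pseudo-count is
deliberately depth-aware: scaling a sample's counts changes the
imputation of its zeros, so exact perturbation invariance of the
Aitchison geometry holds for zero-free samples.  Hellinger and relative
transforms and functional-guild subsetting round out the module.

## The synthetic generator

The generator emulates a season-long, replicated drought trial on a
single crop host: four compartments (leaf, root, rhizosphere, soil),
17 weekly time points, three water treatments with staggered entry
(pre-flowering drought sampled from week 3, post-flowering from week
8), six replicates, plus 18 pre-planting soil cores — 1026 samples in
the full layout.  A per-week size schedule lays a community-size
gradient across the season (default: thirtyfold growth).

**Metacommunity.**  A lognormal species-abundance distribution (σ = 1
by default) over S taxa on the simplex.  Lineages are assigned by
random nested splitting with a per-rank profile — phyla split 3–4 ways,
classes and orders 2–3, families and genera 1–2 — giving family-sized
groups of close relatives, as in real fungal OTU taxonomies; the
cladogram is built from the lineages with unit branch length per rank.

**Traits.**  A single quantitative trait evolves by Brownian motion
along the cladogram with step variance decaying by half per level of
depth, concentrating divergence at deep splits.  This encodes niche
conservatism — the assumption that nearest-taxon phylogenetic inference
relies on — so that taxa sharing a phenotype band are close relatives
rather than converged strangers.  Tip values are scaled to a fixed
1.5-unit niche axis: at the reference selection strength s = 100 the
Gaussian kernel width 1/sqrt(2s) ≈ 0.07 covers about 5% of the axis,
roughly one family-level clade.  An `independent` trait model (i.i.d.
normal) is available to remove the phylogenetic signal.

**Local assembly.**  Communities of N individuals update by
Wright–Fisher resampling from (1−m)·local frequencies + m·source, with
selection entering as a Gaussian trait-matching multiplier
exp(−s·(trait − optimum)²) on the resampling weights.  Drift uses the
metacommunity as source and no selection.  Homogeneous selection shares
one optimum across replicates — by default the trait of the taxon at
the 95th trait percentile, an occupied tail phenotype; a mid-range
optimum would select phenotypes reachable from many clades and produce
no phylogenetic clustering, which is worth remembering when
interpreting betaNTI on real data as well.  Variable selection uses
per-plot optima.  Dispersal limitation seeds each replicate from a
distinct random subset of the pool (10% by default) and then closes it
(m = 0).  Homogenizing dispersal replaces the immigration source with
the current across-replicate mean (migrant exchange).  A single integer
seed drives a splittable generator; every design cell derives a child
seed, so any subset of the grid reproduces in isolation.

**Succession.**  For the age-delay protocol, a separate generator gives
each taxon a Gaussian temporal niche (peak drawn over the fixed season
support, width 2.5 weeks) and draws multinomial counts per sample, so
composition slides monotonically along the calendar.  The niche
structure derives from the seed alone; a sampling seed and a week
offset allow constructing treatment samples from the same system that
are developmentally younger than their labels.

**What the generator does not emulate** — and hence what passing tests
do not establish about field data: sequencing error, primer and copy-
number bias, compositional read-depth variation (counts are true
individual counts), spatial autocorrelation between plots, multi-trait
selection, and taxa entering from outside the fixed pool.  The process
classes are pure; field communities experience mixtures.

## Problem sizes and numerical choices

Tests and the acceptance script use pools of 200 taxa, 12-replicate
cells (66 within-group pairs), a five-level size gradient (N = 10 to
1000, 10 replicates, 20 groups), 999 null replicates for both indices,
200 DOC bootstraps (100 in the 20-seed neutral screen), and 500-tree
forests — sizes chosen so the full suite completes in a few minutes on
one core while keeping Monte-Carlo error well inside the asserted
margins.  Degenerate-null pairs use the sd < 1e-12 guard; permutation
p-values never report zero; ties in the Raup–Crick rank count half;
LOWESS duplicate-x fits are averaged before slope extraction.
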