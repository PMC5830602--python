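# Methods

`nestshore` implements the statistical machinery used to ask whether a
sandy-beach metacommunity is structured by local morphodynamics
(environmental filtering) or by spatial processes (dispersal limitation),
and whether assemblages on harsh reflective beaches are nested subsets of
those on benign dissipative beaches. This note documents the models, the
numerical choices, and what the synthetic test-bed does and does not show.

## Morphodynamic indexing

The Beach Index summarises a sector's position on the
reflective–dissipative continuum:

    BI = log10( Mz · TR / S ),   Mz = mean grain diameter (phi) + 1

with TR the maximum spring tide range (m) and S the beach slope. Two
conventions for S circulate: the angle cotangent (1/tan beta) and the
ratio (tan beta). Only the ratio — the value that environment tables in
this literature actually print in their "Slope (1/S)" column — reproduces
the published BI values of the bundled 14-sector table, so the ratio is
the operative S here. TR is rarely printed; the default TR = 2.0 m
back-solves the bundled table's BI column to within ±0.02 for 13 of 14
sectors and is exposed as a parameter. State classification (reflective
< 2.0 ≤ intermediate ≤ 2.55 < dissipative, closed-left) is configuration:
the source classifications are qualitative and these defaults reproduce
them where they are internally consistent.

## Spatial eigenfunctions (dbMEM)

Geographic distances are great-circle km (haversine); the truncation
threshold is the longest edge of the minimum spanning tree (the longest
distance joining two *neighbouring* sites). Distances beyond the threshold
are replaced by 4× the threshold; the matrix −½D*² is double-centered
(Gower) and eigendecomposed. Eigenvectors with eigenvalues above
1e−9 × the leading eigenvalue are retained, ordered large-scale → fine-
scale, sign-normalised so the first nonzero loading is positive, and each
is annotated with Moran's I under binary within-threshold connectivity.
Only positive-eigenvalue vectors (positive spatial autocorrelation) are
kept, since the spatial hypotheses of interest are about aggregation, not
repulsion.

## Variation partitioning

Community counts are Hellinger-transformed (square root of relative
abundance), making Euclidean-based RDA appropriate for sparse species
data. For predictor sets E (selected morphodynamic variables) and S
(selected dbMEMs), adjusted R² (Ezekiel) from multivariate least squares
yields the classic fractions

    a = R²adj(E+S) − R²adj(S)   (pure environment)
    c = R²adj(E+S) − R²adj(E)   (pure space)
    b = R²adj(E) + R²adj(S) − R²adj(E+S)   (shared; may be negative)
    d = 1 − R²adj(E+S)

which sum to 1 by construction (asserted to 1e−12). [a] and [c] are tested
by permuting residuals of the reduced model (Freedman–Lane), with
p = (exceedances + 1)/(n_perm + 1) so p is never zero. Forward selection
uses the double stopping criterion: a candidate enters only if its partial
permutation p ≤ alpha *and* the cumulative adjusted R² stays at or below
the global model's adjusted R². The historical description of this
procedure sometimes mentions Akaike values; the operative criteria in the
reference software are alpha and the global adjusted R², and that is what
is implemented. When the E+S union is collinear (shared structure), the
combined model's adjustment uses the effective rank rather than failing.

## Ordination and pooling

Bray–Curtis dissimilarity is computed on log(x+1) counts (down-weighting
dominants); NMDS minimises Kruskal stress-1 (reported on the 0–1 scale) by
SMACOF with isotonic regression, taking the best of 20 random starts plus
one classical-scaling start. The two sampling periods are compared by
symmetric Procrustes (centering, unit trace, optimal rotation with
reflections allowed) between the periods' PCoA configurations
(dimensionality min(n−1, 10)); PROTEST permutes rows of one configuration,
and a small p justifies pooling the periods for community-level analyses.

## Nestedness under gradient orderings

Incidence matrices are ranked: rows by an explicit morphodynamic gradient
(decreasing BI, decreasing grain phi, increasing slope, or decreasing
width — most dissipative-like first) or by decreasing richness; columns
always by decreasing species frequency (ties by species id). Empty rows
and columns are dropped and recorded.

* **NODF** averages, over ordered row and column pairs with *strictly
  decreasing* marginal totals, 100 × the fraction of the later line's
  presences shared with the earlier line. Tied pairs score 0 — which is
  why a perfectly nested matrix containing duplicated columns cannot reach
  100.
* **Matrix temperature T** measures disorder against the isocline of
  perfect nestedness for the observed fill (Rodríguez-Gironés &
  Santamaría parametrisation, Umax = 0.04145): each unexpected presence or
  absence contributes its squared normalised distance along its diagonal.
  Packing (the classic definition) iteratively re-ranks rows and columns
  eight times; ties break by current position so the result is
  deterministic. In gradient mode the supplied row order is scored as-is.
  Degenerate fills (0% or 100%) define T = 0 with a warning.

The null model is fixed-fixed (FF): every null matrix preserves all row
and column totals exactly. Sampling uses the curveball algorithm — random
row pairs trade their exclusive species — run as a single compiled chain
(burn-in 10 × fill trades, one sample per fill trades) with an internal
xorshift64* stream so results are reproducible independent of numpy RNG
internals. Uniformity of the sampler on an exhaustively enumerable
fixed-margin state space is part of the test suite; a classic swap engine
is available behind a flag. Z = (obs − null mean)/null sd; the empirical p
is one-tailed in the observed direction; positive NODF z (or negative T z)
reads as nestedness. When margins admit a single matrix the null sd is 0
and z is flagged undefined.

The minimal-site-cover diagnostic (exact branch-and-bound to 25 sites,
greedy with an inexactness flag beyond) reports the smallest number of
sites containing every species: needing more than ~40% of sites is the
classic symptom of a turnover-dominated, anti-nested dataset.

**A power caveat that the test-bed makes explicit.** The FF null
conditions on margins, and margins carry most margin-expressible
nestedness: a perfectly nested matrix is the *unique* matrix with its
margins, so any noisy nested matrix tends to score at or below the null
mean. Consequently NODF-vs-FF has essentially no power to flag nestedness
positively, and detects turnover only when species occupy several
contiguous sites along the gradient. The recovery suite documents this
honestly: the NESTED archetype yields negative z under FF (its nestedness
lives entirely in the margins), and the TURNOVER archetype yields a
negative mean z whose per-replicate sign flips under realistic sampling
sparsity. This conservatism is a known property of fixed-fixed nulls, and
mirrors the anti-nested tendencies typically reported from real sparse
beach data.

## Synthetic metacommunities

The generator emulates a study system of 14 site-sectors × 112 species
sampled in two seasons along ~60 km of coast, with defaults chosen to
match that regime: BI spanning 1.59–2.81, mean count 0.9 per
site×species×period cell (≈2800 pooled individuals — real macrobenthic
surveys are this sparse), negative-binomial counts (shape k = 0.7;
clumped), and two conditionally independent period draws from shared
intensities. Sites sit irregularly on a smooth curved coastline; grain
size, slope and width are drawn jointly and *consistently with the BI
formula* (slope is back-solved exactly), with BI targets shuffled along
the coast so environment and geography are decorrelated except in
SPACE_ONLY, where the environment is constant.

For the niche/space scenarios the log-intensity of species i at site j is

    log λ_ij = log(m·a_i) + env_effect · (g_ij − 1) + space_effect · W_ij

with g_ij a Gaussian niche response to BI (breadth σ = 0.35 by default),
W_ij zero-mean unit-variance latent fields with exponential spatial
covariance exp(−d/ρ), ρ = 20 km, independent across species (independent
species responses are exactly the premise the partitioning tests), and
a_i lognormal abundance factors; intensities are rescaled so each species'
across-site mean is m = mean_abundance, making total abundance comparable
across scenarios. Effect weights default to 2.0 (≈7-fold intensity range
across the gradient — strong but realistic filtering); scenario presets
zero the irrelevant weight. TURNOVER narrows σ to 0.10 and strengthens
filtering (weight 5) with optima equally spaced, producing species
replacement; NESTED thresholds a carrying-capacity rank along the BI
order (richest site carries everything) and flips cells with probability
ε = 0.05. The generating truth (optima, fields, expected outcomes) is
persisted as `truth.json` for recovery scoring.

What the synthetic tests show: that each engine recovers the structure it
was built to detect, at study-realistic dimensions and sparsity. What they
do not show: robustness to features real beach data add on top —
inter-species interactions, temporal autocorrelation beyond two
exchangeable seasons, observation error correlated with morphodynamics,
and taxonomic aggregation.

## Numerical choices and problem sizes

Permutation defaults are 10 000 for variation-partitioning tests
(independent seeded streams for [a] and [c]), 999 for forward selection
and PROTEST, and 1000 FF randomisations per nestedness cell; the analysis
drivers and recovery suites use 199–499 permutations and 300
randomisations with 10–20 replicates — sizes at which the recovery rates
and calibration statistics are stable. Pearson correlations of richness
against morphodynamic proxies use the site×period resolution (n = 2 ×
sites). All stages fan per-stage child seeds out of one master seed; no
stage touches global RNG state, and rerunning a pipeline with the same
seed is byte-identical.

Known limitations: two-component partitioning only (no three-set
decomposition, no CCA); presence-weighted nestedness (WNODF) and
proportional null models are out of scope; the NMDS engine reports the
lowest stress found, which for very small n can be a local optimum;
haversine distances ignore coastline topology (a connectivity-based
spatial model is a documented alternative, not implemented).
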