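# Methods

This note documents the models and procedures implemented in
`paleonet`, the parameters that matter, and the choices made where the
design was genuinely open.

## Network construction

Counts are closed to relative abundances row-wise; all-zero samples are
flagged and carried as zero rows rather than dropped.  The Hellinger
transform (element-wise square root of relative abundances) gives rows
of unit sum of squares, which makes Euclidean-type analyses appropriate
for compositional data.  Spearman's ρ between taxon columns is computed
on average ranks, with the p-value from the t-approximation
`t = ρ √((n−2)/(1−ρ²))` on n−2 degrees of freedom and p = 0 at |ρ| = 1.
Because Spearman is rank-based, the Hellinger step never changes ρ; it
is kept so the correlation stage sees exactly the matrix used by the
multivariate stages.  Zero-variance taxa have no defined correlation
and are masked; they remain in the node set with degree 0.

A group's network keeps every taxon with a nonzero count in at least
one of the group's samples (presence-based inclusion, isolated nodes
counted in S).  Edges are the unmasked pairs with p < α, stored signed
and ρ-weighted; every metric operates on the unsigned, unweighted
topology, so negative associations count as ordinary links.  Correlation
networks require at least five samples.  p-values are raw across the
taxon-pair family by design — correcting them is possible via
`fdr_adjust` but is not part of the standard workflow, which follows
the conventional threshold-on-raw-p construction for these networks.
α defaults to 0.01 for the multi-lake top-bottom design and 0.05 within
core zones, where sample sizes are much smaller and the taxon pool is
shared between the compared networks.

## Network metrics

With S nodes, L edges, degrees X_i:

- connectance `L/(S(S−1)/2)`;
- mean degree centrality `2L/S`;
- degree skewness `Σ(X_i−X̄)³ / ((S−1)σ³)` with σ the sample (ddof = 1)
  standard deviation.  The biased moment-ratio form `m₃/m₂^{3/2}` used
  by some packages is available as `method="moment"`; the two disagree
  for small S (by the factor `(S−1)σ³` vs `S·m₂^{3/2}`), and the sample
  form is the default.  Regular graphs (σ = 0) return 0 with a
  degeneracy flag;
- modularity `Q = (1/2L) Σ_ij (A_ij − γ k_i k_j/2L) δ(c_i,c_j)` with
  resolution γ (default 1, configurable).

Communities come from divisive edge-betweenness (Girvan–Newman)
search: the edge of maximal betweenness is removed, betweenness is
recomputed after every removal, and each time a component splits the
partition is recorded.  The returned partition is the recorded cut of
maximal Q.  Two determinism rules are fixed: betweenness ties are
broken by lexicographic edge order (so results are identical across
runs and platforms), and Q ties are broken toward fewer communities
(the coarser, more stable description).  An edgeless graph has
undefined modularity (flagged, reported missing); the all-singletons
partition is returned for it by the community search.

## Zonation of core records

Records are truncated to a configured earliest age (default 1750 CE)
before zonation.  Bray–Curtis dissimilarity
`d_ij = Σ|x_ik − x_jk| / Σ(x_ik + x_jk)` is computed on the
Hellinger-transformed abundances by default; a switch
(`zonation_on_hellinger=False`) uses raw relative abundances instead,
since both orderings are defensible readings of standard practice.

CONISS is agglomerative clustering in which only stratigraphically
adjacent clusters may merge.  Within-cluster dispersion of cluster C is
computed directly from the dissimilarity matrix as
`W(C) = Σ_{i<j∈C} d_ij / |C|` — exactly the within-cluster sum of
squares when d is squared Euclidean, and algebraically what the
standard Ward-type combinatorial update computes incrementally.  Each
merge minimizes the dispersion increment `W(A∪B) − W(A) − W(B)`; ties
go to the stratigraphically earlier pair (determinism).

The number of significant zones compares the dispersion fraction
explained by the k-th split (reading the dendrogram top-down) against
the broken-stick expectation `(1/(n−1)) Σ_{j=k}^{n−1} 1/j`; the zone
count is 1 plus the number of *leading* splits above expectation.
Zones need at least `min_intervals = 5` members — the minimum for a
within-zone correlation network; if a cut violates this the zone count
is decremented and retried.  Per-zone median calibrated year is
reported from the interval chronology, which is consumed as given (no
age-depth modelling is performed here).

## Null-model inference

Only one network can be observed per group, so shifts are tested
against Erdős–Rényi G(S, p) ensembles with S = the group's node count
and p = its observed connectance; n_reps = 30 by default (the order of
the group sizes in the motivating designs).  The degree sequence is
deliberately *not* preserved: the null fixes only size and density, so
a significant contrast means "the two observed (S, c) pairs generate
distinguishable random-graph metric distributions", and metric
differences partly reflect the (S, p) differences by construction.

Per metric, replicate values are compared by one-way fixed-effects
ANOVA and Tukey's HSD (via the studentized-range distribution; for two
groups the Tukey p equals the ANOVA p).  Edgeless replicates have
missing modularity and are dropped from that metric's ANOVA with a
logged count.  The Benjamini–Hochberg FDR family is the set of tests
belonging to one impact class or one lake: the four metric omnibus
p-values plus the rarefied-Shannon Mann–Whitney p.  The omnibus p (not
the pairwise Tukey p) enters the family — with two groups the two
coincide, and for more zones the omnibus is the primary test.
Mann–Whitney is two-sided, exact for small untied samples, normal
approximation with tie correction otherwise; fully degenerate data
returns p = 1 with a flag.

Rarefaction is a single seeded without-replacement draw per sample
(multivariate hypergeometric) to a common depth — by default the
minimum retained sample total; samples below depth are dropped with a
warning.  Averaging over many draws would shrink the diversity variance
and is intentionally not done, matching the single-subsample convention
of the standard tools.  Shannon diversity is in nats
(`H = −Σ p_i ln p_i`; base configurable).  For cores with very thin
recent intervals, `bins` can pool contiguous recent intervals before
rarefaction; a pooled interval takes the midpoint of member ages.

Per-run randomness derives from one root seed through
`numpy.random.SeedSequence` spawning, so every ensemble replicate has
an independent stream and reruns are byte-identical.

## Synthetic data generator

The generator emulates the study conditions so the pipeline is testable
without field data: per sample, a latent vector z ~ N(0, Σ) with Σ
block-structured by taxon modules (within-module correlation ρ_w,
default 0.7), taxon weights `w_i = exp(μ_i + s·z_i)`, composition
p = w/Σw, and counts multinomial at a total drawn uniformly from
100–600 individuals (the realistic counting effort per sample).
Because the downstream statistic is rank-based, only the latent rank
structure matters, so any monotone link would serve; the log link is
convenient.

Defaults, chosen once: 45 taxa × 100 samples (landscape mode) or
20 × 20 (core mode); 9 modules; dominance profile μ_i geometric with
ratio 0.95 (a few dominant taxa, a long rare tail, as in
*Bosmina*-dominated assemblages); latent noise scale s = 0.95; 10 % of
each module's taxa carry negated loadings, planting negative
associations while keeping Σ positive semi-definite.  Module membership
is assigned round-robin across the dominance gradient: a module made of
co-varying *dominant* taxa would swing the compositional denominator
coherently and induce spurious correlations among unrelated taxa.  Even
so, closure leaves a residual excess — the realized false-edge rate at
α = 0.01 is ≈ 0.02 rather than 0.01.  This is a property of correlating
relative abundances, shared by the analysis pipeline itself, and is
deliberately not corrected (compositionality-aware association
inference is out of scope).

Zoned cores offset μ by a per-taxon shift for intervals deposited after
the change point and attach a linear 1750–2017 CE age model.  A scalar
shift is expanded to ± that magnitude, alternating sign, on the
dominant half of the taxa — among the obvious conventions this one
produces a genuinely large compositional contrast (same-signed shifts
partially cancel under closure).  Each side of the change point must
hold at least five intervals.

What the generator does *not* emulate: temporal autocorrelation within
zones, taphonomic loss, counting-error structure, species invasions, or
environmental covariates.  Passing tests therefore show the machinery
is correct and calibrated under a controlled rank-correlation model,
not that field data meet these assumptions.

## Numerical choices and edge cases

- Exact-tie tolerances: betweenness ties at relative 1e-9; Q ties at
  1e-12; CONISS merge ties at 1e-15.
- |ρ| = 1 pairs receive p = 0 (the t-statistic diverges).
- Rows with zero totals: flagged, excluded from Shannon (error for a
  single vector), tolerated by the relative-abundance transform, and
  at most one such sample is allowed by Bray–Curtis.
- Boundary impact-index values: 0.1 classifies as low, 0.5 as high.
- Networks report S and L exactly; rounding (3 decimals for
  connectance, 2 elsewhere) happens only in report tables.

## Problem sizes used in the test suite

The acceptance checks run ensembles of 30 replicates at S ≈ 20–40,
200-seed power and calibration loops, 50 replicate synthetic datasets
for recovery rates, and 25 end-to-end landscape runs — sizes chosen to
give stable Monte-Carlo estimates (standard errors well inside the
asserted margins) while keeping the whole suite comfortably fast on a
single CPU.

## Known limitations

- Co-occurrence is not interaction: edges mix biotic association,
  shared environmental response and closure effects; the package
  measures network *structure*, not trophic links.
- The G(S, p) null inherits the observed connectance, so it cannot
  separate "fewer taxa" from "fewer links per taxon"; degree-preserving
  nulls are an extension, not implemented.
- CONISS greedy agglomeration does not guarantee globally optimal
  partitions (no dynamic-programming zonation variant is provided).
- The broken-stick rule counts only leading significant splits; deep
  hierarchical zonation patterns with an insignificant first split are
  not pursued.
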