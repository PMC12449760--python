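# paleonet

Taxon co-occurrence network analysis for paleoecological assemblage
records.

Sediment archives preserve identifiable remains of past communities —
for example subfossil cladoceran (zooplankton) assemblages in lake
cores — as sample-by-taxon count matrices, either snapshots from many
lakes (modern core-top vs pre-industrial core-bottom) or continuous
depth series from a single dated core.  `paleonet` turns such matrices
into co-occurrence networks and asks whether network structure has
shifted between time periods, impact classes, or stratigraphic zones.
It is aimed at paleolimnologists and community ecologists who want
network metrics alongside classical diversity indices.

## What it computes

**Networks.**  Counts are converted to relative abundances and
Hellinger-transformed (square root of relative abundances); every taxon
pair's Spearman rank correlation ρ is computed with a t-approximation
p-value, and pairs significant at α (0.01 for the multi-lake design,
0.05 within core zones) become edges of an undirected graph on the
taxa present in the group.  Negative associations are kept as signed
edges; all metrics use the unweighted topology.

**Metrics.**  For a network with S nodes and L edges:

- connectance `C = L / (S(S−1)/2)`,
- modularity `Q = (1/2L) Σ_ij (A_ij − γ k_i k_j / 2L) δ(c_i, c_j)` at the
  partition found by divisive edge-betweenness (Girvan–Newman) community
  detection, cut at maximal Q (γ = 1 by default),
- mean degree centrality `X̄ = 2L/S`,
- skewness of the degree distribution
  `Σ (X_i − X̄)³ / ((S−1) σ³)` with σ the sample standard deviation.

**Zonation.**  Full cores are truncated to a common start (~1750 CE),
and contiguous assemblage zones are delineated by constrained
incremental sum-of-squares clustering (CONISS) of the Bray–Curtis
dissimilarity matrix, with the number of significant zones chosen by a
broken-stick model and a minimum of five intervals per zone.

**Inference.**  Only one network exists per group, so metric shifts are
tested against Erdős–Rényi G(S, p) ensembles matched to each group's
observed node count and connectance (30 replicates by default): one-way
ANOVA plus Tukey's HSD per metric, Benjamini–Hochberg FDR within each
class or lake family, alongside a Mann–Whitney test on rarefied Shannon
diversity.

**Synthetic data.**  A Gaussian-copula-to-multinomial generator plants
known module structure, pairwise associations and compositional change
points, so every stage is testable without field data.

## Worked example

`examples/03_core_zonation.py` simulates a 20-interval core
(1750–2017 CE) with a compositional shift planted at interval 10 and
runs the full-core design:

```
planted change point: interval 10
zones found: 2 (median years {'1': 1813.2, '2': 1953.8})

per-zone network metrics:
network  median_year  S  L  connectance  modularity  mean_degree  skewness
  zone1       1813.2 20 11        0.058        0.70          1.1      0.84
  zone2       1953.8 20 20        0.105        0.52          2.0      0.11

between-zone tests:
     metric  p_raw  p_fdr stars
connectance 0.0000 0.0000  ****
 modularity 0.0001 0.0002   ***
mean_degree 0.0000 0.0000  ****
   skewness 0.3148 0.3148
    shannon 0.0006 0.0007   ***
```

The boundary found by CONISS + broken stick falls exactly at the
planted change point; the between-zone rows report the null-ensemble
ANOVA/Tukey p-values after FDR adjustment, i.e. whether each metric
differs more between zones than matched random graphs would show.  The
other example scripts build a single network, run the 101-lake-style
top-bottom comparison, and reproduce the null-ensemble contrast at
published network sizes.

A thin CLI mirrors the library:
`paleonet simulate`, `paleonet topbottom`, `paleonet fullcore`,
`paleonet metrics` (see `paleonet --help`).

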