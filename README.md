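# chorusnet

Landscape-genetic connectivity analysis for pond-breeding amphibians in
spatio-temporally variable wetland networks — built around the boreal chorus
frog (*Pseudacris maculata*) study system of montane Colorado: 18 occupied
breeding wetlands, ~110 candidate stepping-stone wetlands, strong snowpack
control on wetland hydroperiod, and microsatellite genotypes structured by
dispersal-limited gene flow.

The package is for landscape geneticists and spatial ecologists who want to
ask: *how much of the genetic distance between wetland populations is
explained by geography, terrain, moisture, and the connectivity of the
habitat network itself?*

## What it computes

**Genetic distances.** From multilocus microsatellite genotypes (GENEPOP
format), with full-sib larval clusters subsampled to the smallest cluster
per site to avoid family bias:

- D<sub>ps</sub> = 1 − proportion of shared alleles, averaged over
  inter-site individual pairs;
- Nei's G<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>,
  summed over loci before the ratio, plus a seeded permutation test.

**Habitat-graph connectivity.** Wetlands are nodes with attribute
*a<sub>i</sub>* (area, optionally discounted by the fraction of years the
wetland is hydrologically available under its snowpack category); edges
carry Euclidean distances and a negative-exponential dispersal kernel
p(d) = exp(−θd), calibrated so that 5% of dispersers exceed the observed
600 m dispersal maximum. The probability of connectivity is

> PC ∝ Σ<sub>i</sub> Σ<sub>j</sub> a<sub>i</sub> a<sub>j</sub> p\*<sub>ij</sub>,

with p\*<sub>ij</sub> the best path product of edge probabilities. Each
node's importance dPC<sub>k</sub> (percent loss of PC when node *k* is
removed) splits exactly into **Intra** (own area), **Flux** (direct
area-weighted exchange) and **Connector** (irreplaceable stepping-stone
role). Three network constructions are provided: spatial-breeding,
temporal-breeding (availability-weighted), and stepping-stone (occupied
wetlands plus all candidates larger than 400 m²; 128 nodes in the default
landscape).

**Terrain covariates.** From ESRI ASCII grids: compound topographic index
ln(a/tan β) with D8 flow accumulation, surface relief ratio, relative slope
position, precipitation ratio, meadow:forest and impervious cover — within
100 m wetland buffers and along straight between-wetland corridors at 30,
60, 120, and 240 m bandwidths — plus topographically corrected distances
and an R²/VIF collinearity screen.

**Gravity models.** Functional connectivity T<sub>ij</sub> = 1 −
D<sub>ps</sub>(i, j) is modeled as the singly-constrained gravity model

> T<sub>ij</sub> = k<sub>i</sub> · v<sub>i</sub><sup>μ</sup> ·
> w<sub>ij</sub><sup>α</sup> · c<sub>ij</sub><sup>−β</sup>,

linearized by natural logs and fit as a linear mixed model with a random
intercept per origin, by exact profile maximum likelihood (so AIC is
comparable across fixed-effect structures). Model and corridor-bandwidth
selection use AIC with a ΔAIC < 2 top set.

**Synthetic data.** Every stage is testable without field data: the
generator produces wetland layouts, snowpack series (15 of 33 years below
the 63.5 cm threshold), co-registered rasters, kernel-structured
migration–drift genotypes with full-sib larval clusters, and flow tables
with known coefficients.

## Worked example

```python
import chorusnet as cn

kernel = cn.calibrate_kernel(d_ref=600.0, p_ref=0.05)
print(f"theta = {kernel.theta:.6f} per m;  p(600 m) = {kernel.probability(600.0):.3f}")

wetlands = cn.generate_wetlands(cn.LandscapeSpec(seed=1))
net = cn.build_network(wetlands, kernel, "stepping_stone", edge_cutoff=1200.0)
print(f"stepping-stone network: {len(net.nodes)} nodes, {net.graph.number_of_edges()} edges")

result = cn.dpc_decomposition(net)
occupied = list(wetlands.loc[wetlands["occupied"], "id"])
print(cn.report(result, subset=occupied).head(4).round(4).to_string(index=False))
```

prints

```
theta = 0.004993 per m;  p(600 m) = 0.050
stepping-stone network: 128 nodes, 400 edges
 id  PC_pct  Intra_pct  Flux_pct  Connector_pct   network_kind
W01  0.1397     0.0428    0.0864         0.0105 stepping_stone
W02  0.6080     0.1351    0.4730         0.0000 stepping_stone
W03  0.0547     0.0051    0.0496         0.0000 stepping_stone
W04  0.0197     0.0043    0.0141         0.0014 stepping_stone
```

The kernel assigns a 5% dispersal probability at the 600 m reference
distance; each occupied wetland's importance (PC_pct) is the percent drop
in landscape connectivity if it were lost, and the three fractions show
whether that importance comes from its own area (Intra), its direct
exchanges (Flux), or its role as a stepping stone on other wetlands' best
dispersal routes (Connector — nonzero here because edges beyond 1200 m are
pruned, so long hops must route through intermediate wetlands).

The full pipeline (simulate → distances → networks → covariates →
connectivity → gravity) runs from the command line:

```sh
chorusnet run-all --seed 1 --outdir demo_run
```

and finishes in a few seconds, writing wetland/snow/raster inputs, the
D<sub>ps</sub> matrix and global G<sub>ST</sub>, per-network connectivity
tables, covariates at every bandwidth, and the AIC model-selection table
(`model_selection.csv`), each CSV stamped with a config-hash provenance
line. With seed 1 the selected corridor bandwidth is 30 m and the best
gravity model combines distance, between-site topographic roughness,
within-site moisture, and stepping-stone connectivity.

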