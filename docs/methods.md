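# Methods

This note documents the models implemented by `chorusnet`, the choices made
where the methodology was genuinely open, and what the synthetic data do
and do not establish.

## Genetic distances

**D_ps.** The proportion of shared alleles between two individuals is
ps(x, y) = Σ_loci Σ_alleles min(count_x, count_y) / (2 · L_xy), where
counts are per-individual allele copies (0, 1, 2) and L_xy is the number
of loci scored in both individuals; loci missing in either member of a
pair are dropped from that pair's denominator (pairwise deletion, which
keeps ps in [0, 1]). The between-site distance is 1 minus the mean ps over
all inter-site individual pairs — the individual-based convention of the
classic microsatellite tooling. Per-individual matrices are exposed
(`shared_allele_matrix`) for testing.

**G_ST.** Nei's fixation index uses the unweighted mean of per-site allele
frequencies for H_T and the unweighted mean of per-site expected
heterozygosities for H_S, with heterozygosities summed across loci before
the ratio. Monomorphic data define G_ST = 0 (H_T = 0 guard). The pairwise
version applies the same formula to each site pair. Significance is
assessed by a seeded permutation test (individuals shuffled between the
two sites, default 999 permutations, Bonferroni-corrected across pairs);
on real data with known structure most pairs are expected to reject, but
that cannot be reproduced synthetically, so the test suite only verifies
calibration on exchangeable data.

**Sibling subsampling.** Larvae arrive as full-sib clusters. For each
site, every cluster is randomly subsampled without replacement to the size
of the smallest cluster at that site; adults are never touched. This
equalizes family contributions to allele-frequency estimates. Clusters may
not span sites.

Hardy–Weinberg and linkage-disequilibrium testing is deliberately out of
scope (standard upstream QC).

## Dispersal kernel and habitat graphs

The kernel is negative exponential, p(d) = exp(−θd), with θ calibrated
from one exceedance constraint: p(d_ref) = p_ref, default d_ref = 600 m
and p_ref = 0.05 (5% of dispersers beyond the observed dispersal maximum
of the boreal chorus frog), giving θ = −ln(0.05)/600 ≈ 0.004993 m⁻¹. The
family is the standard probabilistic kernel of habitat-availability
connectivity analysis; the exceedance is interpreted as holding exactly at
d_ref.

Three graphs share this kernel. Nodes are wetland centroids (polygons are
not modeled; areas enter only as node attributes) and edges carry
Euclidean distances:

- **spatial** — occupied breeding wetlands, attribute a_i = area_i;
- **temporal** — same nodes, a_i = area_i × (available years / total
  years) for the node's snowpack category. Availability comes from
  classifying a snowpack-depth series against a 63.5 cm threshold:
  low-snowpack wetlands are productive in below-threshold years (15 of 33
  in the reference series), high wetlands in the remainder (18 of 33),
  neutral wetlands always. The multiplicative area-discount is this
  package's choice; the source methodology says availability was
  "attributed" to nodes without giving the functional form, and no simple
  area×availability rule reproduces its published temporal Intra values,
  so no attempt is made to match those columns.
- **stepping_stone** — occupied wetlands plus every unoccupied candidate
  strictly larger than min_area (default 400 m², the smallest neutral
  breeding wetland), all treated as always available; 18 + 110 = 128
  nodes in the default landscape.

**Edge cutoff.** By default the graph is complete. With a complete graph
and an exponential kernel, no multi-edge path can ever beat a direct edge
(the triangle inequality in −ln p), which forces the Connector fraction to
be identically zero. A configurable pruning cutoff (pipeline default
1200 m = 2·d_ref) removes implausibly long direct hops so stepping-stone
routing can matter — which is precisely the phenomenon the stepping-stone
network exists to measure.

## Probability of connectivity and its decomposition

p*_ij is the maximum over paths of the product of edge probabilities,
computed as a shortest path under the additive weight −ln p = θd
(Dijkstra via scipy); p*_ii = 1 and unreachable pairs get 0. The PC
numerator sums a_i a_j p*_ij over ordered pairs including i = j; the
normalized index divides by A_L², with A_L defaulting to Σa_i and
configurable to a fixed landscape attribute.

Node importance is computed by actual removal: dPC_k = 100·(PC −
PC_without_k)/PC, with

- Intra_k = 100·a_k²/PC,
- Flux_k = 100·2·a_k·Σ_{j≠k} a_j p*_kj / PC,
- Connector_k = 100·Σ_{i,j≠k} a_i a_j (p*_ij − p*′_ij)/PC,

each evaluated from its own definition, so dPC = Intra + Flux + Connector
holds to floating point rather than by subtraction. No caching shortcuts
are used (O(n·n² log n); ~1 s at n = 128), and a brute-force
path-enumeration oracle in the test suite guards all four quantities
exactly on small graphs.

## Terrain covariates

- **Slope** by Horn's 3×3 finite differences with edge replication.
- **D8 flow accumulation** counts upslope cells including self. Receivers
  are the steepest-descent neighbor with a clockwise-from-north tie-break.
  Boundary cells with no downhill in-grid neighbor drain off the grid edge
  (the usual GIS convention). Interior flat cells drain by an epsilon
  ordering: only toward an equal-elevation neighbor with a smaller linear
  cell index (a strict total order, so plateau drainage cannot cycle),
  clockwise-first among candidates; interior pits are sinks.
- **CTI** = ln(a / tan β), a = accumulation × cellsize, with tan β floored
  at tan(0.001) so flat cells stay finite.
- **SRR** = (mean − min)/(max − min) over a zone; **RSP** places a point
  between the window minimum (0) and maximum (1). Perfectly flat zones and
  windows return 0.5 — the midpoint convention avoids spurious extremes on
  synthetic flat patches.
- **Buffers** select cells whose centers fall within the radius (default
  100 m) of the wetland centroid; **corridors** select cells within
  bandwidth/2 of the straight inter-centroid segment. "Bandwidth" is the
  corridor's *total* width; the source GIS tooling does not define this,
  so the choice is explicit here and symmetric in the endpoints.
- **Meadow:forest** ratios use +1/+1 smoothing to stay finite when a class
  is absent; cases where smoothing moves the value by more than 10% are
  logged.
- **Topographic distance** samples the DEM bilinearly along the segment at
  one step per cellsize and sums 3-D segment lengths; it can never be
  shorter than the planimetric distance.
- **Collinearity screen**: greedy pairwise removal for R² > 0.7 (the
  member of the worst pair with the larger mean |r| to everything else is
  dropped), then iterative removal of the largest VIF until all ≤ 5.
  Exposed both as a function and as a fit/transform `CollinearityFilter`.

Electrical conductivity is a pass-through field measurement; no
computation is attached to it.

## Gravity model

Flow tables hold both ordered orientations of every site pair (n(n−1)
records), with response ln T_ij, T_ij = 1 − D_ps(i, j) floored at ε = 1e-6,
and ln-transformed predictors (ln(x + ε) guard). Predictors are not
standardized by default so that coefficients keep the power-law reading of
the gravity equation; a standardization flag exists for conditioning.
Site-level connectivity metrics enter as origin attributes by default,
switchable to destination or pair-mean.

The model ln T = Xβ + u_origin + ε, u ~ N(0, σ_u²) iid by origin, is fit
by exact maximum likelihood: with λ = σ_u²/σ_e² fixed, the GLS solution
and the profile log-likelihood have closed forms through the
theta-transform (x̃ = x − θ_g x̄_g, θ_g = 1 − 1/√(1 + λn_g)), leaving a
deterministic one-dimensional maximization over λ ≥ 0 (coarse log grid,
then bounded refinement). This guarantees the log-likelihood is at its
maximum to high accuracy — essential when AIC differences of fractions of
a unit decide the model ranking — and handles the σ_u = 0 boundary
exactly. General-purpose mixed-model optimizers were found to mis-converge
near that boundary by enough to corrupt ΔAIC; the test suite cross-checks
this fitter against an independent mixed-model implementation on
well-conditioned data. ML (never REML) is used throughout so fixed-effect
structures are AIC-comparable.

**AIC conventions.** `full` counts slopes + intercept + two variance
components and is the statistically defensible default. `printed_k`
counts only the named predictors, mirroring how applied gravity-model
selection tables are often typeset; it exists so published table
arithmetic can be reproduced. Published single-predictor rows of the
reference ranking are mutually inconsistent under any single convention,
so only the internally consistent multi-predictor ΔAIC values (0.70,
1.62) serve as validation targets. Candidate sets always include a
distance-only null model; ties break lexicographically by model name.
Bandwidth selection fits one predictor set per corridor bandwidth and
takes the AIC minimum, ties to the smallest bandwidth.

## Synthetic data

The generator reproduces the *statistical shape* of the study system:

- 18 breeding + 110 candidate wetlands, areas log-uniform in 200–20,000 m²
  (candidates above the 400 m² filter by default, so the default landscape
  has the reference 128-node stepping-stone network; a configurable
  fraction below the filter exercises it);
- a 33-year snow series with exactly 15 years strictly below 63.5 cm;
- DEM as filtered Gaussian noise with configurable relief and correlation
  length (smooth and differentiable, so slope/CTI/RSP behave sensibly);
  land cover as a thresholded smooth field; summer precipitation =
  annual × ratio field in (0, 1];
- genotypes from a forward migration–drift simulation on allele
  frequencies: per generation p_i ← (1 − m)p_i + Σ_j M_ij p_j followed by
  multinomial drift at the deme size (default 200 chromosomes), with the
  migration matrix proportional to the network's p* rows scaled to the
  total migration rate — tying genetic structure to the same connectivity
  model the analysis estimates. Default 12 loci with 7–26 alleles drawn
  per locus. Samples per deme: adults drawn under within-deme random
  mating plus full-sib larval clusters (two multilocus parents, Mendelian
  offspring) with truncated-geometric sizes (max 10);
- flow tables ln T = Xβ + u_origin + ε with all three components
  controllable, for parameter-recovery and selection studies.

All randomness descends from one root seed via `SeedSequence.spawn`, so
adding a consumer never shifts existing streams; every generator is
byte-identical under a fixed seed.

**What this does not show.** The simulation has no mutation, no
coalescent realism, no selection, no spatially autocorrelated sampling
noise, and only the binary snow-threshold availability scheme (no
quantitative depth–hydroperiod link is published). Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the pipeline — not that the fitted ecological coefficients of the original
system are recoverable, which would require the unpublished genotypes and
coordinates.

## Problem sizes and numerical tolerances

Default test and pipeline scales: 128-node connectivity with full node
removal; 306 ordered site pairs per gravity fit; 100-replicate recovery
studies; 200 random graphs for the decomposition identity (tolerance
1e-9); brute-force oracle agreement at 1e-12 on graphs of up to 6 nodes;
kernel calibration invariant at 1e-12. The decomposition identity, D_ps
bounds, and p* ≥ direct-edge dominance are property-tested. Degenerate
inputs have defined behavior: flat DEM zones (0.5 conventions),
monomorphic loci (G_ST = 0), coincident corridor endpoints (buffer
fallback with a warning), D_ps = 1 (ε floor with a warning), σ_u = 0
(exact boundary solution).

## Known limitations

- Wetlands are points; corridor and buffer geometry ignores wetland
  polygons and shorelines.
- Straight-line corridors stand in for least-cost paths; no resistance
  surface routing.
- The temporal attribution rule (area × availability fraction) is one
  defensible reading of an under-specified method; published temporal
  Intra values are not reproducible under it and are not targeted.
- No map projections: all coordinates are assumed planar meters.
- The permutation G_ST test is exact only under exchangeability within
  site pairs; family structure should be removed (sibling subsampling)
  before testing.
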