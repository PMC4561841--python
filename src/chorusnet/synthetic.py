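"""Synthetic wetland landscapes, rasters, snowpack, genotypes, and flows.

Every downstream stage of the pipeline (genetic distances, habitat graphs,
connectivity decomposition, raster covariates, gravity fits) is exercised
against data from this module, which emulates the statistical structure of
a montane pond-breeding amphibian study system: 18 occupied breeding
wetlands plus 110 candidate stepping-stone wetlands with areas of
200-20,000 m², a 33-year snowpack-depth series split by a 63.5 cm
availability threshold (15 low-snow years), and 12-locus microsatellite
genotypes (7-26 alleles per locus) whose spatial structure arises from a
kernel-weighted migration-drift process on the wetland network.

All randomness flows from a single integer seed per spec object; internal
streams are split with ``numpy.random.SeedSequence.spawn`` so adding a new
consumer never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .genotypes import GenotypeTable
from .networks import WetlandNetwork, SNOW_CATEGORIES
from .terrain import LANDCOVER_CODES, RasterGrid

__all__ = [
    "LandscapeSpec",
    "SnowSeriesSpec",
    "GenotypeSimSpec",
    "generate_wetlands",
    "generate_snow_series",
    "generate_rasters",
    "simulate_genotypes",
    "simulate_flow_table",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Layout of a synthetic wetland landscape.

    ``snow_category_weights`` gives the sampling proportions of the
    low/high/neutral snowpack categories for occupied wetlands; candidate
    stepping-stone wetlands are always neutral. ``frac_small`` controls how
    many candidate areas fall below the stepping-stone area filter
    (default 0: all 110 candidates pass, giving the 128-node network).
    """

    seed: int = 0
    extent: tuple = (9000.0, 9000.0)
    n_breeding: int = 18
    n_stepping: int = 110
    area_range: tuple = (200.0, 20000.0)
    snow_category_weights: tuple = (0.2, 0.55, 0.25)  # low, high, neutral
    frac_small: float = 0.0
    stepping_min_area: float = 400.0

    def __post_init__(self) -> None:
        if self.n_breeding < 2:
            raise ValueError("need at least 2 breeding wetlands")
        if self.n_stepping < 0:
            raise ValueError("n_stepping must be non-negative")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent dimensions must be positive")
        if not self.area_range[0] < self.area_range[1]:
            raise ValueError("area_range must satisfy min < max")
        if abs(sum(self.snow_category_weights) - 1.0) > 1e-9:
            raise ValueError("snow category weights must sum to 1")
        if not 0.0 <= self.frac_small <= 1.0:
            raise ValueError("frac_small must lie in [0, 1]")


@dataclass(frozen=True)
class SnowSeriesSpec:
    """A winter snowpack-depth series with a fixed count of low-snow years."""

    n_years: int = 33
    n_below_threshold: int = 15
    threshold_cm: float = 63.5
    seed: int = 0
    start_year: int = 1979

    def __post_init__(self) -> None:
        if not 0 <= self.n_below_threshold <= self.n_years:
            raise ValueError("n_below_threshold must lie in [0, n_years]")
        if self.threshold_cm <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Forward migration-drift simulation settings for microsatellite data.

    ``deme_size`` is the number of chromosomes (2N) per wetland deme;
    ``total_migration_rate`` is each deme's total per-generation immigrant
    fraction, apportioned among sources in proportion to the best-path
    dispersal probabilities of the wetland network. Larval samples are
    full-sib families: each cluster has two parents drawn from the deme and
    Mendelian offspring; cluster sizes follow a truncated geometric law.
    """

    n_loci: int = 12
    alleles_per_locus: tuple = (7, 26)
    deme_size: int = 200
    generations: int = 100
    total_migration_rate: float = 0.02
    n_adults: int = 8
    n_sib_clusters: int = 3
    sibship_geom_p: float = 0.45
    sibship_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.total_migration_rate < 1:
            raise ValueError("total_migration_rate must lie in [0, 1)")
        if self.alleles_per_locus[0] < 2:
            raise ValueError("need at least 2 alleles per locus")
        if self.deme_size < 2:
            raise ValueError("deme_size must be at least 2 chromosomes")
        if self.sibship_max < 1:
            raise ValueError("sibship_max must be at least 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Wetlands


def generate_wetlands(spec: LandscapeSpec) -> pd.DataFrame:
    """Generate the wetland node table (id, x, y, area_m2, snow_category,
    occupied).

    Occupied (breeding) wetland areas are log-uniform over the full area
    range; candidate stepping-stone areas are log-uniform above the area
    filter except for a ``frac_small`` share drawn below it.
    """
    rng_xy, rng_area, rng_cat = _streams(spec.seed, 3)
    n_total = spec.n_breeding + spec.n_stepping
    xy = rng_xy.uniform([0, 0], list(spec.extent), size=(n_total, 2))
    lo, hi = spec.area_range
    cut = min(max(spec.stepping_min_area, lo), hi)

    breeding_areas = np.exp(rng_area.uniform(np.log(lo), np.log(hi), spec.n_breeding))
    small = rng_area.random(spec.n_stepping) < spec.frac_small
    step_areas = np.where(
        small,
        np.exp(rng_area.uniform(np.log(lo), np.log(cut), spec.n_stepping)),
        np.exp(rng_area.uniform(np.log(cut), np.log(hi), spec.n_stepping)),
    )
    cats = rng_cat.choice(SNOW_CATEGORIES, size=spec.n_breeding, p=spec.snow_category_weights)

    ids = [f"W{k + 1:02d}" for k in range(spec.n_breeding)]
    ids += [f"S{k + 1:03d}" for k in range(spec.n_stepping)]
    return pd.DataFrame(
        {
            "id": ids,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "area_m2": np.concatenate([breeding_areas, step_areas]),
            "snow_category": list(cats) + ["neutral"] * spec.n_stepping,
            "occupied": [True] * spec.n_breeding + [False] * spec.n_stepping,
        }
    )


# ---------------------------------------------------------------------------
# Snow series


def generate_snow_series(spec: SnowSeriesSpec) -> pd.DataFrame:
    """Annual snowpack depths (cm) with exactly ``n_below_threshold`` years
    strictly below the threshold and the rest strictly above."""
    rng = np.random.default_rng(spec.seed)
    t = spec.threshold_cm
    below = t * rng.uniform(0.35, 0.97, spec.n_below_threshold)
    above = t * rng.uniform(1.03, 2.3, spec.n_years - spec.n_below_threshold)
    depths = np.concatenate([below, above])
    rng.shuffle(depths)
    years = spec.start_year + np.arange(spec.n_years)
    return pd.DataFrame({"year": years, "depth_cm": depths})


# ---------------------------------------------------------------------------
# Rasters


def _smooth_field(rng: np.random.Generator, shape: tuple, sigma_cells: float) -> np.ndarray:
    """Correlated Gaussian surface, standardized to zero mean, unit sd."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def generate_rasters(
    spec: LandscapeSpec,
    cellsize: float = 30.0,
    relief: float = 150.0,
    correlation_length: float = 600.0,
    base_elevation: float = 2600.0,
    landcover_fractions: dict | None = None,
) -> dict:
    """Synthesize co-registered DEM, land-cover, precipitation, and
    impervious grids for the landscape extent.

    The DEM is filtered Gaussian noise (correlation length in meters)
    scaled to ``relief``; land cover is a smooth field thresholded into
    meadow/forest/water/impervious patches; summer precipitation is the
    annual grid times a smooth ratio field in (0, 1].
    """
    w, h = spec.extent
    ncols, nrows = int(round(w / cellsize)), int(round(h / cellsize))
    if abs(ncols * cellsize - w) > 1e-6 or abs(nrows * cellsize - h) > 1e-6:
        raise ValueError("cellsize must divide the landscape extent")
    fr = landcover_fractions or {"meadow": 0.45, "forest": 0.42, "water": 0.08, "impervious": 0.05}
    rng_dem, rng_lc, rng_ppt = _streams(spec.seed + 1, 3)
    sigma = correlation_length / cellsize

    def grid(vals):
        return RasterGrid(vals, xllcorner=0.0, yllcorner=0.0, cellsize=cellsize)

    dem_field = _smooth_field(rng_dem, (nrows, ncols), sigma)
    if relief > 0:
        span = dem_field.max() - dem_field.min()
        dem = base_elevation + (dem_field - dem_field.min()) / span * relief
    else:
        dem = np.full((nrows, ncols), base_elevation)

    lc_field = _smooth_field(rng_lc, (nrows, ncols), sigma / 2)
    qs = np.cumsum([fr["meadow"], fr["forest"], fr["water"]])
    cuts = np.quantile(lc_field, qs)
    lc = np.full((nrows, ncols), LANDCOVER_CODES["impervious"], dtype=float)
    lc[lc_field <= cuts[2]] = LANDCOVER_CODES["water"]
    lc[lc_field <= cuts[1]] = LANDCOVER_CODES["forest"]
    lc[lc_field <= cuts[0]] = LANDCOVER_CODES["meadow"]

    annual = 500.0 + 120.0 * _smooth_field(rng_ppt, (nrows, ncols), sigma)
    annual = np.clip(annual, 150.0, None)
    ratio = 0.4 + 0.12 * _smooth_field(rng_ppt, (nrows, ncols), sigma)
    ratio = np.clip(ratio, 0.05, 1.0)
    summer = annual * ratio

    return {
        "dem": grid(dem),
        "landcover": grid(lc),
        "ppt_summer": grid(summer),
        "ppt_annual": grid(annual),
        "impervious": grid((lc == LANDCOVER_CODES["impervious"]).astype(float)),
    }


# ---------------------------------------------------------------------------
# Genotypes


def _migration_matrix(pstar: np.ndarray, total_rate: float) -> np.ndarray:
    """Row-stochastic immigrant apportionment scaled to the total rate.

    M_ij (i receives from j) is proportional to the best-path dispersal
    probability p*_ij, with each row scaled so off-diagonal entries sum to
    ``total_rate``.
    """
    n = pstar.shape[0]
    M = pstar.astype(float).copy()
    np.fill_diagonal(M, 0.0)
    rows = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(rows[:, None] > 0, M / rows[:, None] * total_rate, 0.0)
    if np.any(M.sum(axis=1) > 1 + 1e-9):
        raise ValueError("migration matrix row sum exceeds 1")
    return M


def _sample_diploid(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """n diploid genotypes (allele codes starting at 101) from frequencies."""
    codes = 101 + np.arange(freqs.size)
    return rng.choice(codes, size=(n, 2), p=freqs)


def simulate_genotypes(
    network: WetlandNetwork, spec: GenotypeSimSpec
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate genotypes on the wetland network by migration and drift.

    Each occupied wetland is a deme of ``deme_size`` chromosomes. Allele
    frequencies start identical across demes and evolve per generation as
    p_i <- (1 - m) p_i + sum_j M_ij p_j followed by multinomial drift, with
    M derived from the network's best-path dispersal probabilities. The
    sample per deme holds ``n_adults`` adults (random union of gametes) and
    ``n_sib_clusters`` full-sib larval families with truncated-geometric
    sizes. Returns the genotype table and the sibling-cluster frame
    (individual_id, site_id, cluster_id).
    """
    from .connectivity import pstar_matrix  # local import to avoid a cycle

    occ_mask = network.nodes["occupied"].astype(bool).to_numpy()
    if occ_mask.sum() < 2:
        raise ValueError("network needs at least 2 occupied nodes")
    pstar = pstar_matrix(network)[np.ix_(occ_mask, occ_mask)]
    deme_ids = [nid for nid, occ in zip(network.node_ids, occ_mask) if occ]
    n_demes = len(deme_ids)
    M = _migration_matrix(pstar, spec.total_migration_rate)
    m_total = M.sum(axis=1)

    rng_init, rng_evolve, rng_sample = _streams(spec.seed, 3)
    lo, hi = spec.alleles_per_locus
    n_alleles = rng_init.integers(lo, hi + 1, size=spec.n_loci)
    freqs = [
        np.tile(rng_init.dirichlet(np.ones(k)), (n_demes, 1)) for k in n_alleles
    ]

    for _ in range(spec.generations):
        for l in range(spec.n_loci):
            p = freqs[l]
            p_new = (1.0 - m_total)[:, None] * p + M @ p
            for d in range(n_demes):
                draw = rng_evolve.multinomial(spec.deme_size, p_new[d] / p_new[d].sum())
                p[d] = draw / spec.deme_size
            freqs[l] = p

    ind_ids: list = []
    site_ids: list = []
    stages: list = []
    rows: list = []
    cluster_rows: list = []
    for d, deme in enumerate(deme_ids):
        for a in range(spec.n_adults):
            geno = [_sample_diploid(rng_sample, freqs[l][d], 1)[0] for l in range(spec.n_loci)]
            ind_ids.append(f"{deme}_A{a + 1:02d}")
            site_ids.append(deme)
            stages.append("adult")
            rows.append(geno)
        for c in range(spec.n_sib_clusters):
            size = min(int(rng_sample.geometric(spec.sibship_geom_p)), spec.sibship_max)
            parents = [
                [_sample_diploid(rng_sample, freqs[l][d], 1)[0] for l in range(spec.n_loci)]
                for _ in range(2)
            ]
            for o in range(size):
                geno = [
                    np.array(
                        [
                            parents[0][l][rng_sample.integers(2)],
                            parents[1][l][rng_sample.integers(2)],
                        ]
                    )
                    for l in range(spec.n_loci)
                ]
                ind_id = f"{deme}_L{c + 1}{o + 1:02d}"
                ind_ids.append(ind_id)
                site_ids.append(deme)
                stages.append("larva")
                rows.append(geno)
                cluster_rows.append(
                    {"individual_id": ind_id, "site_id": deme, "cluster_id": f"{deme}_c{c + 1}"}
                )
    table = GenotypeTable(
        individual_ids=ind_ids,
        site_ids=site_ids,
        loci=[f"locus_{l + 1:02d}" for l in range(spec.n_loci)],
        alleles=np.array(rows, dtype=int),
        life_stages=stages,
    )
    clusters = pd.DataFrame(cluster_rows, columns=["individual_id", "site_id", "cluster_id"])
    return table, clusters


# ---------------------------------------------------------------------------
# Flow tables


def simulate_flow_table(
    design: pd.DataFrame,
    beta,
    sigma_u: float,
    sigma_e: float,
    seed: int,
    intercept: float = 0.0,
    origin_col: str = "origin",
    response_col: str = "ln_T",
) -> pd.DataFrame:
    """Simulate a gravity-model flow table from a known linear model.

    The response is ln T = intercept + X beta + u_origin + eps with
    u ~ N(0, sigma_u²) per origin and eps ~ N(0, sigma_e²) per record.
    ``design`` must contain the origin label column plus one column per
    coefficient in ``beta`` (any extra columns, e.g. ``destination``, ride
    along untouched).
    """
    if sigma_u < 0 or sigma_e < 0:
        raise ValueError("standard deviations must be non-negative")
    beta = np.asarray(beta, dtype=float)
    predictors = [c for c in design.columns if c not in (origin_col, "destination")]
    if len(predictors) != beta.size:
        raise ValueError(
            f"beta has {beta.size} entries for {len(predictors)} predictors {predictors}"
        )
    rng = np.random.default_rng(seed)
    X = design[predictors].to_numpy(dtype=float)
    origins = design[origin_col].to_numpy()
    unique_origins = pd.unique(origins)
    u = dict(zip(unique_origins, rng.normal(0.0, sigma_u, len(unique_origins))))
    eps = rng.normal(0.0, sigma_e, len(design))
    out = design.copy()
    out[response_col] = intercept + X @ beta + np.array([u[o] for o in origins]) + eps
    return out
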