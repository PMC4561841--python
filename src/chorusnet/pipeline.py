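"""Pipeline orchestration: simulate -> distances/networks/covariates ->
connectivity -> gravity.

Each stage reads its inputs from the output directory of earlier stages,
writes flat CSV artifacts (plus ESRI ASCII grids and a GENEPOP file from
the simulation stage), and stamps every CSV with a provenance comment line
carrying the configuration hash and seed. A declared dependency graph
makes out-of-order invocation fail with an actionable message naming the
stage that produces the missing artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import genotypes as geno
from . import gravity as grav
from . import networks as nets
from . import synthetic as synth
from . import terrain

log = logging.getLogger("chorusnet")

STAGES = ["simulate", "distances", "networks", "covariates", "connectivity", "gravity"]

#: artifact -> (producing stage, filename)
_ARTIFACTS = {
    "wetlands": ("simulate", "wetlands.csv"),
    "snow": ("simulate", "snow.csv"),
    "genepop": ("simulate", "genotypes.gen"),
    "clusters": ("simulate", "sibling_clusters.csv"),
    "dem": ("simulate", "dem.asc"),
    "dps": ("distances", "dps_matrix.csv"),
    "network_nodes": ("networks", "network_{kind}_nodes.csv"),
    "network_edges": ("networks", "network_{kind}_edges.csv"),
    "at_site": ("covariates", "covariates_at_site.csv"),
    "between_site": ("covariates", "covariates_between_site.csv"),
    "topo_distances": ("covariates", "topo_distances.csv"),
    "connectivity": ("connectivity", "connectivity_{kind}.csv"),
    "selection": ("gravity", "model_selection.csv"),
}


@dataclass
class PipelineConfig:
    """Run configuration; serializable to/from YAML."""

    seed: int = 1
    outdir: str = "chorusnet_run"
    kernel_d_ref: float = 600.0
    kernel_p_ref: float = 0.05
    snow_threshold_cm: float = 63.5
    min_stepping_area_m2: float = 400.0
    edge_cutoff_m: float = 1200.0
    bandwidths_m: tuple = (30.0, 60.0, 120.0, 240.0)
    cellsize_m: float = 30.0
    buffer_radius_m: float = 100.0
    aic_convention: str = "full"
    delta_aic_cut: float = 2.0
    n_breeding: int = 18
    n_stepping: int = 110
    extent_m: tuple = (9000.0, 9000.0)
    generations: int = 100
    total_migration_rate: float = 0.05
    candidate_models: dict = field(
        default_factory=lambda: {
            "dist_srr_pratio_pcstep": ["distance", "srr_bet", "pratio_at", "PC_step_at"],
            "dist_srr_pratio_both_pcstep": [
                "distance", "srr_bet", "pratio_at", "pratio_bet", "PC_step_at",
            ],
            "dist_srr_pratio_cti_pcstep": [
                "distance", "srr_bet", "pratio_at", "cti_at", "PC_step_at",
            ],
            "dist_pratio_both_pcstep": ["distance", "pratio_bet", "pratio_at", "PC_step_at"],
            "srr_only": ["srr_bet"],
            "pcstep_only": ["PC_step_at"],
        }
    )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chorusnet stage={stage} config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _require(outdir: Path, keys: list, kind: str | None = None) -> dict:
    paths = {}
    for key in keys:
        stage, fname = _ARTIFACTS[key]
        if "{kind}" in fname:
            fname = fname.format(kind=kind)
        p = outdir / fname
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {p.name!r}; run the {stage!r} stage first"
            )
        paths[key] = p
    return paths


def _kernel(config: PipelineConfig) -> nets.DispersalKernel:
    return nets.calibrate_kernel(config.kernel_d_ref, config.kernel_p_ref)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("simulate")
    lspec = synth.LandscapeSpec(
        seed=seed,
        extent=tuple(config.extent_m),
        n_breeding=config.n_breeding,
        n_stepping=config.n_stepping,
        stepping_min_area=config.min_stepping_area_m2,
    )
    wetlands = synth.generate_wetlands(lspec)
    _write_csv(wetlands, outdir / "wetlands.csv", config, "simulate")
    snow = synth.generate_snow_series(synth.SnowSeriesSpec(seed=seed + 1))
    _write_csv(snow, outdir / "snow.csv", config, "simulate")
    rasters = synth.generate_rasters(lspec, cellsize=config.cellsize_m)
    for name, grid in rasters.items():
        terrain.write_ascii_grid(grid, outdir / f"{name}.asc")
    network = nets.build_network(wetlands, _kernel(config), "spatial")
    gspec = synth.GenotypeSimSpec(
        seed=seed + 2,
        generations=config.generations,
        total_migration_rate=config.total_migration_rate,
    )
    table, clusters = synth.simulate_genotypes(network, gspec)
    geno.write_genepop(table, outdir / "genotypes.gen")
    _write_csv(clusters, outdir / "sibling_clusters.csv", config, "simulate")
    log.info("simulate: %d wetlands, %d individuals", len(wetlands), table.n_individuals)


def stage_distances(config: PipelineConfig, outdir: Path) -> None:
    paths = _require(outdir, ["genepop", "clusters"])
    table = geno.read_genepop(paths["genepop"])
    clusters = geno.read_clusters(paths["clusters"])
    seed = config.stage_seed("distances")
    table = geno.subsample_siblings(table, clusters, seed=seed)
    dps = geno.dps_matrix(table)
    with open(outdir / "dps_matrix.csv", "w") as fh:
        fh.write(f"# chorusnet stage=distances config={config.config_hash()} seed={config.seed}\n")
        dps.to_frame().to_csv(fh, index_label="site")
    global_gst, pw = geno.gst(table)
    _write_csv(
        pd.DataFrame({"statistic": ["global_gst"], "value": [global_gst]}),
        outdir / "gst_global.csv",
        config,
        "distances",
    )
    log.info("distances: %d sites, global G_ST=%.3f", len(dps.site_ids), global_gst)


def stage_networks(config: PipelineConfig, outdir: Path) -> None:
    paths = _require(outdir, ["wetlands", "snow"])
    wetlands = _read_csv(paths["wetlands"])
    snow = _read_csv(paths["snow"])
    kernel = _kernel(config)
    attribution = nets.classify_availability(snow["depth_cm"], config.snow_threshold_cm)
    for kind in ("spatial", "temporal", "stepping_stone"):
        network = nets.build_network(
            wetlands,
            kernel,
            kind,
            attribution=attribution if kind == "temporal" else None,
            min_area=config.min_stepping_area_m2,
            edge_cutoff=config.edge_cutoff_m,
        )
        network.to_csv(
            outdir / f"network_{kind}_nodes.csv", outdir / f"network_{kind}_edges.csv"
        )
        log.info("networks: %s with %d nodes", kind, len(network.nodes))


def _load_network(config: PipelineConfig, outdir: Path, kind: str) -> nets.WetlandNetwork:
    paths = _require(outdir, ["wetlands", "snow"])
    wetlands = _read_csv(paths["wetlands"])
    snow = _read_csv(paths["snow"])
    attribution = nets.classify_availability(snow["depth_cm"], config.snow_threshold_cm)
    return nets.build_network(
        wetlands,
        _kernel(config),
        kind,
        attribution=attribution if kind == "temporal" else None,
        min_area=config.min_stepping_area_m2,
        edge_cutoff=config.edge_cutoff_m,
    )


def stage_connectivity(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, ["network_nodes"], kind="spatial")
    paths = _require(outdir, ["wetlands"])
    wetlands = _read_csv(paths["wetlands"])
    occupied = list(wetlands.loc[wetlands["occupied"], "id"])
    for kind in ("spatial", "temporal", "stepping_stone"):
        network = _load_network(config, outdir, kind)
        result = conn.dpc_decomposition(network)
        table = conn.report(result, subset=occupied)
        _write_csv(table, outdir / f"connectivity_{kind}.csv", config, "connectivity")
        log.info("connectivity: %s PC numerator %.3g", kind, result.pc_num)


def stage_covariates(config: PipelineConfig, outdir: Path) -> None:
    paths = _require(outdir, ["wetlands", "dem"])
    wetlands = _read_csv(paths["wetlands"])
    occ = wetlands[wetlands["occupied"]].reset_index(drop=True)
    rasters = {
        name: terrain.read_ascii_grid(outdir / f"{name}.asc")
        for name in ("dem", "landcover", "ppt_summer", "ppt_annual", "impervious")
    }
    dem = rasters["dem"]
    rasters["cti"] = terrain.RasterGrid(
        terrain.cti(dem), dem.xllcorner, dem.yllcorner, dem.cellsize
    )
    at_rows = []
    for _, row in occ.iterrows():
        stats = terrain.buffer_stats(rasters, (row["x"], row["y"]), config.buffer_radius_m)
        for var, val in stats.items():
            at_rows.append({"site_id": row["id"], "variable": var, "value": val})
    _write_csv(pd.DataFrame(at_rows), outdir / "covariates_at_site.csv", config, "covariates")

    bet_rows = []
    dist_rows = []
    for i in range(len(occ)):
        for j in range(i + 1, len(occ)):
            pi = (occ.loc[i, "x"], occ.loc[i, "y"])
            pj = (occ.loc[j, "x"], occ.loc[j, "y"])
            dist_rows.append(
                {
                    "site_i": occ.loc[i, "id"],
                    "site_j": occ.loc[j, "id"],
                    "distance_m": terrain.topo_distance(dem, pi, pj),
                }
            )
            for bw in config.bandwidths_m:
                stats = terrain.corridor_stats(rasters, pi, pj, bandwidth=bw)
                for var, val in stats.items():
                    bet_rows.append(
                        {
                            "site_i": occ.loc[i, "id"],
                            "site_j": occ.loc[j, "id"],
                            "bandwidth_m": bw,
                            "variable": var,
                            "value": val,
                        }
                    )
    _write_csv(pd.DataFrame(bet_rows), outdir / "covariates_between_site.csv", config, "covariates")
    _write_csv(pd.DataFrame(dist_rows), outdir / "topo_distances.csv", config, "covariates")
    log.info("covariates: %d at-site rows, %d between-site rows", len(at_rows), len(bet_rows))


def _flow_table_for_bandwidth(config: PipelineConfig, outdir: Path, bandwidth: float) -> pd.DataFrame:
    paths = _require(outdir, ["dps", "at_site", "between_site", "topo_distances"])
    _require(outdir, ["connectivity"], kind="stepping_stone")
    dps = _read_csv(paths["dps"], index_col="site")
    at_long = _read_csv(paths["at_site"])
    at = at_long.pivot(index="site_id", columns="variable", values="value")
    for kind, col in (("spatial", "PC_spatial_at"), ("temporal", "PC_temporal_at"), ("stepping_stone", "PC_step_at")):
        ctab = _read_csv(outdir / f"connectivity_{kind}.csv").set_index("id")
        at[col] = ctab["PC_pct"]
    bet_long = _read_csv(paths["between_site"])
    bet = (
        bet_long[bet_long["bandwidth_m"] == bandwidth]
        .pivot(index=["site_i", "site_j"], columns="variable", values="value")
    )
    dist = _read_csv(paths["topo_distances"])
    sites = list(dps.index)
    dmat = pd.DataFrame(0.0, index=sites, columns=sites)
    for _, row in dist.iterrows():
        dmat.loc[row["site_i"], row["site_j"]] = row["distance_m"]
        dmat.loc[row["site_j"], row["site_i"]] = row["distance_m"]
    return grav.build_flow_table(dps, at, bet, dmat)


def stage_gravity(config: PipelineConfig, outdir: Path) -> None:
    screen_preds = ["distance", "srr_bet", "pratio_at", "cti_at", "pratio_bet", "PC_step_at"]
    flow_tables = {
        bw: _flow_table_for_bandwidth(config, outdir, bw) for bw in config.bandwidths_m
    }
    best_bw, bw_table = grav.bandwidth_selection(
        flow_tables, screen_preds, aic_convention=config.aic_convention
    )
    _write_csv(bw_table, outdir / "bandwidth_selection.csv", config, "gravity")
    flow = flow_tables[best_bw]
    _write_csv(flow, outdir / "flow_table.csv", config, "gravity")
    selection = grav.model_selection(
        flow,
        config.candidate_models,
        delta_cut=config.delta_aic_cut,
        aic_convention=config.aic_convention,
    )
    _write_csv(selection.table, outdir / "model_selection.csv", config, "gravity")
    log.info("gravity: best bandwidth %.0f m, best model %s", best_bw, selection.best)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "distances": stage_distances,
    "networks": stage_networks,
    "covariates": stage_covariates,
    "connectivity": stage_connectivity,
    "gravity": stage_gravity,
}


def run_stage(name: str, config: PipelineConfig, outdir=None) -> None:
    """Run one pipeline stage; raises if a dependency artifact is missing."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[name](config, out)


def run_all(config: PipelineConfig, outdir=None) -> None:
    """Run the full pipeline in dependency order."""
    for name in STAGES:
        run_stage(name, config, outdir)
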