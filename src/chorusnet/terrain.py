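"""Raster covariates for wetland landscape-genetics analyses.

Terrain and land-cover predictors are extracted from gridded surfaces
(ESRI ASCII grids) in two zonal flavours:

* **at-site** — summaries within a radial buffer around each wetland
  centroid (default 100 m), describing conditions that control the
  production of dispersers (larval recruitment, hydroperiod);
* **between-site** — summaries over a straight-line corridor of a given
  total bandwidth joining two wetlands, describing matrix resistance to
  dispersal.

The topographic indices follow standard terrain-analysis definitions:
compound topographic index CTI = ln(a / tan beta) with a the specific
catchment area from D8 flow accumulation, surface relief ratio
SRR = (mean - min)/(max - min), and relative slope position RSP placing a
point between valley floor (0) and ridge top (1) inside a circular window.
Wetlands are treated as points (centroids); polygon outlines are not
modelled, so buffers and corridors are purely geometric cell selections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RasterGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "slope_and_flowacc",
    "cti",
    "srr",
    "rsp",
    "buffer_stats",
    "corridor_stats",
    "topo_distance",
    "collinearity_screen",
    "CollinearityFilter",
    "LANDCOVER_CODES",
]

#: Integer codes used by land-cover grids throughout the package.
LANDCOVER_CODES = {"meadow": 1, "forest": 2, "water": 3, "impervious": 4}

# D8 neighbour offsets in clockwise order starting at north; row axis points
# south (row 0 is the northernmost row).
_D8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class RasterGrid:
    """A single-band raster with ESRI ASCII grid georeferencing.

    ``values`` is an (nrows, ncols) array whose row 0 is the northernmost
    row; the origin (``xllcorner``, ``yllcorner``) is the lower-left corner
    of the lower-left cell.
    """

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 30.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shaped like values."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing point (x, y)."""
        j = int(np.floor((x - self.xllcorner) / self.cellsize))
        i = self.nrows - 1 - int(np.floor((y - self.yllcorner) / self.cellsize))
        if not (0 <= i < self.nrows and 0 <= j < self.ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the raster extent")
        return i, j

    def interpolate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at arbitrary points (clamped to the extent)."""
        gx = (np.asarray(x, dtype=float) - self.xllcorner) / self.cellsize - 0.5
        gy = (self.nrows - 0.5) - (np.asarray(y, dtype=float) - self.yllcorner) / self.cellsize
        gx = np.clip(gx, 0, self.ncols - 1)
        gy = np.clip(gy, 0, self.nrows - 1)
        j0 = np.clip(np.floor(gx).astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros_like(gx, int)
        i0 = np.clip(np.floor(gy).astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros_like(gy, int)
        fx = gx - j0
        fy = gy - i0
        v = self.values
        if self.ncols == 1:
            fx = np.zeros_like(fx)
        if self.nrows == 1:
            fy = np.zeros_like(fy)
        j1 = np.minimum(j0 + 1, self.ncols - 1)
        i1 = np.minimum(i0 + 1, self.nrows - 1)
        return (
            v[i0, j0] * (1 - fx) * (1 - fy)
            + v[i0, j1] * fx * (1 - fy)
            + v[i1, j0] * (1 - fx) * fy
            + v[i1, j1] * fx * fy
        )


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid: missing {key}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return RasterGrid(
        values=values,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.6f}\n")
        fh.write(f"yllcorner {grid.yllcorner:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Topographic primitives


def _horn_slope(z: np.ndarray, cellsize: float) -> np.ndarray:
    """Slope in radians by Horn's 3x3 finite differences (edge-replicated)."""
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                      f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cellsize)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cellsize)
    return np.arctan(np.hypot(dzdx, dzdy))


def _d8_directions(z: np.ndarray) -> np.ndarray:
    """D8 receiver index for each cell (flattened index; -1 = sink).

    Steepest descent with a clockwise-from-north tie-break. A boundary cell
    with no strictly lower in-grid neighbour drains off the grid edge
    (sink). Interior flat cells drain by epsilon ordering: such a cell may
    only drain to an equal-elevation neighbour of strictly smaller linear
    index (a strict total order, which rules out cycles on plateaus),
    preferring the clockwise-first such neighbour. Interior pits are sinks.
    """
    nrows, ncols = z.shape
    recv = np.full(z.shape, -1, dtype=int)
    for i in range(nrows):
        for j in range(ncols):
            zc = z[i, j]
            best_drop = 0.0
            best = -1
            for di, dj in _D8:
                ni, nj = i + di, j + dj
                if not (0 <= ni < nrows and 0 <= nj < ncols):
                    continue
                drop = (zc - z[ni, nj]) / np.hypot(di, dj)
                if drop > best_drop:  # strict >: clockwise-first wins ties
                    best_drop = drop
                    best = ni * ncols + nj
            if best >= 0:
                recv[i, j] = best
                continue
            if i in (0, nrows - 1) or j in (0, ncols - 1):
                continue  # boundary cell with no downhill route drains off-grid
            # interior flat: epsilon drainage across the plateau, restricted
            # to smaller linear index so the flat graph stays acyclic
            for di, dj in _D8:
                ni, nj = i + di, j + dj
                if not (0 <= ni < nrows and 0 <= nj < ncols):
                    continue
                if z[ni, nj] == zc and (ni * ncols + nj) < (i * ncols + j):
                    recv[i, j] = ni * ncols + nj
                    break
    return recv


def slope_and_flowacc(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (radians) and D8 flow accumulation (upslope cell count, incl. self).

    Flow routing is single-direction (D8) toward the steepest downslope
    neighbour, ties broken clockwise from north; flats drain deterministically
    by an epsilon ordering (see :func:`_d8_directions`).
    """
    z = dem.values
    if not np.isfinite(z).any():
        raise ValueError("DEM contains no finite cells")
    slope = _horn_slope(z, dem.cellsize)
    recv = _d8_directions(z)
    acc = np.ones(z.size, dtype=float)
    flat = z.ravel()
    # process in strictly decreasing effective elevation: descending z, and
    # within flats descending index (flat edges point to smaller indices)
    order = np.lexsort((np.arange(z.size), flat))[::-1]
    recv_flat = recv.ravel()
    for idx in order:
        r = recv_flat[idx]
        if r >= 0:
            acc[r] += acc[idx]
    return slope, acc.reshape(z.shape)


_MIN_TANB = np.tan(0.001)


def cti(dem: RasterGrid) -> np.ndarray:
    """Compound topographic index ln(a / tan beta).

    ``a`` is the specific catchment area (flow accumulation x cellsize);
    tan(beta) is floored at tan(0.001 rad) so flat cells stay finite.
    """
    slope, acc = slope_and_flowacc(dem)
    a = acc * dem.cellsize
    tanb = np.maximum(np.tan(slope), _MIN_TANB)
    return np.log(a / tanb)


def srr(dem: RasterGrid, zone: np.ndarray) -> float:
    """Surface relief ratio (mean - min)/(max - min) over a zone mask.

    A perfectly flat zone returns 0.5 (midpoint convention).
    """
    zone = np.asarray(zone, dtype=bool)
    if not zone.any():
        raise ValueError("srr zone is empty")
    vals = dem.values[zone]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return 0.5
    return float((vals.mean() - lo) / (hi - lo))


def rsp(dem: RasterGrid, center: tuple[float, float], radius: float) -> float:
    """Relative slope position of a point within a circular window.

    0 at the window minimum (valley), 1 at the maximum (ridge); flat
    windows return 0.5.
    """
    x0, y0 = center
    i, j = dem.rowcol(x0, y0)  # raises off-grid
    X, Y = dem.cell_centers()
    mask = (X - x0) ** 2 + (Y - y0) ** 2 <= radius**2
    if not mask.any():
        mask = np.zeros(dem.values.shape, bool)
        mask[i, j] = True
    vals = dem.values[mask]
    lo, hi = vals.min(), vals.max()
    zc = dem.values[i, j]
    if hi == lo:
        return 0.5
    return float(np.clip((zc - lo) / (hi - lo), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Zonal summaries


def _require_grids(rasters: dict) -> None:
    missing = {"dem", "landcover", "ppt_summer", "ppt_annual"} - set(rasters)
    if missing:
        raise KeyError(f"missing rasters: {sorted(missing)}")


def _meadow_forest_ratio(landcover_vals: np.ndarray) -> float:
    # +1 smoothing keeps the ratio finite when either class is absent
    n_meadow = int(np.sum(landcover_vals == LANDCOVER_CODES["meadow"]))
    n_forest = int(np.sum(landcover_vals == LANDCOVER_CODES["forest"]))
    raw = n_meadow / n_forest if n_forest else np.inf
    smoothed = (n_meadow + 1) / (n_forest + 1)
    if np.isfinite(raw) and raw > 0 and abs(smoothed - raw) / raw > 0.10:
        log.debug(
            "meadow:forest smoothing changed the ratio by >10%% (%.3g -> %.3g)", raw, smoothed
        )
    return smoothed


def buffer_stats(rasters: dict, wetland_xy: tuple[float, float], radius: float = 100.0) -> dict:
    """At-site covariates within a radial buffer of the wetland centroid.

    Returns meadow:forest ratio (+1 smoothed), impervious cell count, mean
    CTI, mean precipitation ratio, and relative slope position at the
    centroid (same radius window).
    """
    _require_grids(rasters)
    dem = rasters["dem"]
    x0, y0 = wetland_xy
    X, Y = dem.cell_centers()
    mask = (X - x0) ** 2 + (Y - y0) ** 2 <= radius**2
    if not mask.any():
        raise ValueError(f"buffer around ({x0}, {y0}) does not intersect the raster")
    cti_grid = rasters.get("cti")
    if cti_grid is None:
        cti_grid = RasterGrid(cti(dem), dem.xllcorner, dem.yllcorner, dem.cellsize)
    pr = rasters["ppt_summer"].values / np.maximum(rasters["ppt_annual"].values, 1e-12)
    return {
        "mf_at": _meadow_forest_ratio(rasters["landcover"].values[mask]),
        "imperv_at": float(np.sum(rasters["landcover"].values[mask] == LANDCOVER_CODES["impervious"])),
        "cti_at": float(cti_grid.values[mask].mean()),
        "pratio_at": float(pr[mask].mean()),
        "rsp_at": rsp(dem, wetland_xy, radius),
    }


def _segment_mask(grid: RasterGrid, p: tuple[float, float], q: tuple[float, float], half_width: float) -> np.ndarray:
    """Cells whose centers lie within half_width of segment p-q."""
    X, Y = grid.cell_centers()
    px, py = p
    qx, qy = q
    dx, dy = qx - px, qy - py
    L2 = dx * dx + dy * dy
    if L2 == 0:
        d2 = (X - px) ** 2 + (Y - py) ** 2
    else:
        t = np.clip(((X - px) * dx + (Y - py) * dy) / L2, 0.0, 1.0)
        d2 = (X - (px + t * dx)) ** 2 + (Y - (py + t * dy)) ** 2
    return d2 <= half_width**2


def corridor_stats(
    rasters: dict,
    site_i: tuple[float, float],
    site_j: tuple[float, float],
    bandwidth: float = 30.0,
) -> dict:
    """Between-site covariates over a straight corridor of total width ``bandwidth``.

    The corridor is the set of cells whose centers lie within bandwidth/2 of
    the segment joining the two wetland centroids; results are symmetric in
    the endpoints. A zero-length segment degrades to a radial buffer of the
    same half-width (with a warning).
    """
    _require_grids(rasters)
    dem = rasters["dem"]
    dem.rowcol(*site_i)
    dem.rowcol(*site_j)
    if site_i == site_j:
        warnings.warn("zero-length corridor; using at-site buffer statistics", stacklevel=2)
    mask = _segment_mask(dem, site_i, site_j, bandwidth / 2.0)
    if not mask.any():
        raise ValueError("corridor does not intersect the raster")
    cti_grid = rasters.get("cti")
    if cti_grid is None:
        cti_grid = RasterGrid(cti(dem), dem.xllcorner, dem.yllcorner, dem.cellsize)
    pr = rasters["ppt_summer"].values / np.maximum(rasters["ppt_annual"].values, 1e-12)
    lc = rasters["landcover"].values[mask]
    return {
        "mf_bet": _meadow_forest_ratio(lc),
        "imperv_bet": float(np.mean(lc == LANDCOVER_CODES["impervious"])),
        "cti_bet": float(cti_grid.values[mask].mean()),
        "pratio_bet": float(pr[mask].mean()),
        "srr_bet": srr(dem, mask),
    }


def topo_distance(
    dem: RasterGrid,
    site_i: tuple[float, float],
    site_j: tuple[float, float],
    step: float | None = None,
) -> float:
    """Topographically corrected length of the straight segment i-j (meters).

    The DEM is sampled (bilinearly) along the segment at ``step`` spacing
    (default: one cellsize) and 3-D segment lengths sqrt(dxy^2 + dz^2) are
    summed; the result is never shorter than the planimetric distance.
    """
    if step is None:
        step = dem.cellsize
    xi, yi = site_i
    xj, yj = site_j
    d = float(np.hypot(xj - xi, yj - yi))
    if d == 0:
        return 0.0
    dem.rowcol(xi, yi)
    dem.rowcol(xj, yj)
    n = max(int(np.ceil(d / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    xs = xi + t * (xj - xi)
    ys = yi + t * (yj - yi)
    zs = dem.interpolate(xs, ys)
    seg_xy = d / n
    return float(np.sum(np.hypot(seg_xy, np.diff(zs))))


# ---------------------------------------------------------------------------
# Collinearity screening


class CollinearityFilter:
    """Drop collinear covariates by pairwise R² and then by VIF.

    Screening is greedy: while any pair of variables has squared Pearson
    correlation above ``r2_cut`` (default 0.7), the member of the worst pair
    with the larger mean absolute correlation to all other variables is
    dropped; afterwards variables are removed one at a time by largest
    variance inflation factor until all VIFs are at most ``vif_cut``
    (default 5). Constant columns are dropped up front with a warning.

    Follows the scikit-learn transformer protocol: :meth:`fit` learns the
    retained column set (``retained_``, ``dropped_``), :meth:`transform`
    subsets a DataFrame to it.
    """

    def __init__(self, r2_cut: float = 0.7, vif_cut: float = 5.0):
        self.r2_cut = r2_cut
        self.vif_cut = vif_cut

    def get_params(self, deep: bool = True) -> dict:
        return {"r2_cut": self.r2_cut, "vif_cut": self.vif_cut}

    def set_params(self, **params) -> "CollinearityFilter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _vifs(df: pd.DataFrame) -> pd.Series:
        X = df.to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(X)), X])
        out = {}
        for k, name in enumerate(df.columns, start=1):
            others = np.delete(X, k, axis=1)
            y = X[:, k]
            beta, *_ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ beta
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
            out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    def fit(self, X: pd.DataFrame, y=None) -> "CollinearityFilter":
        X = pd.DataFrame(X)
        if X.shape[1] < 2 or X.shape[0] < 3:
            raise ValueError("collinearity screening needs >= 2 variables and >= 3 records")
        dropped: list[tuple[str, str]] = []
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        for c in constant:
            warnings.warn(f"dropping constant covariate {c!r} before screening", stacklevel=2)
            dropped.append((c, "constant"))
        work = X.drop(columns=constant)
        # stage 1: pairwise R^2
        while work.shape[1] >= 2:
            corr = work.corr().to_numpy()
            np.fill_diagonal(corr, 0.0)
            r2 = corr**2
            if np.nanmax(r2) <= self.r2_cut:
                break
            i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
            mean_abs = np.nanmean(np.abs(corr), axis=1)
            loser = int(i) if mean_abs[i] >= mean_abs[j] else int(j)
            name = work.columns[loser]
            dropped.append((name, "pairwise_r2"))
            work = work.drop(columns=[name])
        # stage 2: VIF
        while work.shape[1] >= 2:
            vifs = self._vifs(work)
            if vifs.max() <= self.vif_cut:
                break
            name = vifs.idxmax()
            dropped.append((name, "vif"))
            work = work.drop(columns=[name])
        self.retained_ = list(work.columns)
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_"):
            raise RuntimeError("CollinearityFilter is not fitted")
        return pd.DataFrame(X)[self.retained_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def collinearity_screen(table: pd.DataFrame, r2_cut: float = 0.7, vif_cut: float = 5.0) -> list[str]:
    """Retained variable names after pairwise-R² and VIF screening."""
    return CollinearityFilter(r2_cut=r2_cut, vif_cut=vif_cut).fit(table).retained_
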