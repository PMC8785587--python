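"""Kriging prediction of the spatial residual field on a regular grid.

Per retained MCMC draw the structured field is interpolated to grid-cell
centroids by the Gaussian-process conditional mean (simple kriging, no
nugget): weights Lambda = Sigma_oi Sigma_jj^-1 make the predictor exact at
cluster locations.  Because both covariance blocks share the factor
sigma_s^2, the weights depend only on the decay parameter phi of each draw.
Cells are treated independently (marginal prediction; no joint conditional
covariance across cells), matching the per-cell map products.  The surface
is summarized on the odds-ratio scale: mean and SD over draws of exp(s0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import pearsonr

from .model import EARTH_RADIUS_KM, ClusterSet, haversine_km

__all__ = [
    "PredictionGrid",
    "make_grid",
    "kriging_weights",
    "predict_residual_surface",
    "sample_surface_at_points",
    "correlate_with_classes",
]

_KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class PredictionGrid:
    """Regular lattice of cell centroids with per-cell OR summaries.

    ``x_km``/``y_km`` are planar offsets from the region's lower-left corner;
    for lon/lat regions each centroid also carries lon/lat via a local
    equirectangular projection about the region centre.
    """

    x_km: np.ndarray
    y_km: np.ndarray
    cell_km: float
    inside: np.ndarray
    crs: str = "lonlat"
    lon: Optional[np.ndarray] = None
    lat: Optional[np.ndarray] = None
    or_mean: Optional[np.ndarray] = None
    or_sd: Optional[np.ndarray] = None
    s_sd: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.x_km)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(len(self))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "x_km": self.x_km, "y_km": self.y_km})
        df["lon"] = self.lon if self.lon is not None else np.nan
        df["lat"] = self.lat if self.lat is not None else np.nan
        df["or_mean"] = self.or_mean if self.or_mean is not None else np.nan
        df["or_sd"] = self.or_sd if self.or_sd is not None else np.nan
        df["inside"] = self.inside
        return df


def make_grid(bbox: Optional[Tuple[float, float, float, float]] = None,
              boundary=None, cell_km: float = 5.0, crs: str = "lonlat") -> PredictionGrid:
    """Axis-aligned lattice of cell centroids covering a bbox or polygon.

    ``bbox`` is (lon_min, lat_min, lon_max, lat_max) for ``crs="lonlat"`` or
    (x_min, y_min, x_max, y_max) km for ``crs="km"``.  When a shapely
    ``boundary`` polygon is given (same crs), cells whose centroid falls
    outside it are flagged ``inside=False`` and excluded from prediction.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be > 0")
    if bbox is None:
        if boundary is None:
            raise ValueError("provide a bbox or a boundary polygon")
        bbox = boundary.bounds
    x0, y0, x1, y1 = (float(v) for v in bbox)
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region")

    if crs == "lonlat":
        lat_mid = 0.5 * (y0 + y1)
        kx = _KM_PER_DEG_LAT * math.cos(math.radians(lat_mid))
        ky = _KM_PER_DEG_LAT
        width, height = (x1 - x0) * kx, (y1 - y0) * ky
    elif crs == "km":
        width, height = x1 - x0, y1 - y0
    else:
        raise ValueError(f"unknown crs {crs!r}")

    nx = max(int(math.ceil(width / cell_km - 1e-9)), 1)
    ny = max(int(math.ceil(height / cell_km - 1e-9)), 1)
    cx = (np.arange(nx) + 0.5) * cell_km
    cy = (np.arange(ny) + 0.5) * cell_km
    gx, gy = np.meshgrid(cx, cy, indexing="xy")
    x_km, y_km = gx.ravel(), gy.ravel()

    lon = lat = None
    if crs == "lonlat":
        lon = x0 + x_km / kx
        lat = y0 + y_km / ky
    inside = np.ones(len(x_km), dtype=bool)
    if boundary is not None:
        from shapely import points as _shp_points
        pts = np.column_stack([lon, lat]) if crs == "lonlat" else np.column_stack(
            [x0 + x_km, y0 + y_km])
        inside = np.asarray(boundary.contains(_shp_points(pts)))
    return PredictionGrid(x_km=x_km, y_km=y_km, cell_km=float(cell_km), inside=inside,
                          crs=crs, lon=lon, lat=lat)


def _cross_distances(grid: PredictionGrid, clusters: ClusterSet) -> np.ndarray:
    """Cell-to-cluster distance matrix (C x J) in km."""
    if grid.crs == "lonlat":
        if clusters.crs != "lonlat":
            raise ValueError("grid and clusters must share a crs")
        return haversine_km(grid.lon[:, None], grid.lat[:, None],
                            clusters.coords[None, :, 0], clusters.coords[None, :, 1])
    if clusters.crs != "km":
        raise ValueError("grid and clusters must share a crs")
    diff_x = grid.x_km[:, None] - clusters.coords[None, :, 0]
    diff_y = grid.y_km[:, None] - clusters.coords[None, :, 1]
    return np.sqrt(diff_x ** 2 + diff_y ** 2)


def kriging_weights(grid: PredictionGrid, clusters: ClusterSet,
                    sigma_s: float, phi: float, jitter: float = 1e-10) -> np.ndarray:
    """Simple-kriging weight matrix Lambda (cells x J).

    Lambda = Sigma_oi Sigma_jj^-1; the sigma_s^2 factor cancels, so the
    weights are a function of phi alone.  A cell coincident with a cluster
    gets the corresponding unit weight vector (interpolation exactness).
    """
    if sigma_s < 0 or phi <= 0:
        raise ValueError("require sigma_s >= 0 and phi > 0")
    R = np.exp(-phi * clusters.distances)
    R[np.diag_indices_from(R)] += jitter
    d_cross = _cross_distances(grid, clusters)
    R_oi = np.exp(-phi * d_cross)
    try:
        cf = cho_factor(R, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("observation covariance singular after jitter") from exc
    return cho_solve(cf, R_oi.T).T


def predict_residual_surface(samples, grid: PredictionGrid, clusters: ClusterSet,
                             thin: int = 10, conditional_noise: bool = False,
                             seed: int = 0) -> PredictionGrid:
    """Fill the grid with posterior summaries of the residual odds ratio.

    Per retained draw t (every ``thin``-th): s0^(t) = Lambda(phi^(t)) s^(t)
    at the inside-boundary cells.  Summaries are the mean and SD over draws
    of exp(s0) — the residual OR surface and its uncertainty.  ``thin=1``
    reproduces the per-iteration scheme at full cost.  With
    ``conditional_noise=True`` each draw adds independent N(0, conditional
    variance) noise per cell (off by default: the map products summarize the
    conditional mean).
    """
    if getattr(samples, "model", 2) != 2 or "s" not in samples.draws:
        raise ValueError("spatial residual prediction needs Model 2 samples "
                         "(no spatial field in Model 1)")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    s_draws = samples.draws["s"][::thin]
    phi_draws = samples.draws["phi"][::thin]
    sig_draws = samples.draws["sigma_s"][::thin]
    rng = np.random.default_rng(seed)

    sel = np.flatnonzero(grid.inside)
    sub = PredictionGrid(x_km=grid.x_km[sel], y_km=grid.y_km[sel], cell_km=grid.cell_km,
                         inside=np.ones(len(sel), dtype=bool), crs=grid.crs,
                         lon=None if grid.lon is None else grid.lon[sel],
                         lat=None if grid.lat is None else grid.lat[sel])
    d_cross = _cross_distances(sub, clusters)
    D = clusters.distances

    exp_sum = np.zeros(len(sel))
    exp_sq = np.zeros(len(sel))
    s0_sum = np.zeros(len(sel))
    s0_sq = np.zeros(len(sel))
    T = len(s_draws)
    for t in range(T):
        phi = float(phi_draws[t])
        R = np.exp(-phi * D)
        R[np.diag_indices_from(R)] += 1e-10
        cf = cho_factor(R, lower=True)
        R_oi = np.exp(-phi * d_cross)
        w = cho_solve(cf, s_draws[t])
        s0 = R_oi @ w
        if conditional_noise:
            lam = cho_solve(cf, R_oi.T)
            cond_var = np.clip(1.0 - np.einsum("ij,ji->i", R_oi, lam), 0.0, None)
            s0 = s0 + rng.standard_normal(len(s0)) * sig_draws[t] * np.sqrt(cond_var)
        e = np.exp(s0)
        exp_sum += e
        exp_sq += e * e
        s0_sum += s0
        s0_sq += s0 * s0

    mean_e = exp_sum / T
    var_e = np.clip(exp_sq / T - mean_e ** 2, 0.0, None)
    var_s = np.clip(s0_sq / T - (s0_sum / T) ** 2, 0.0, None)

    out = PredictionGrid(x_km=grid.x_km, y_km=grid.y_km, cell_km=grid.cell_km,
                         inside=grid.inside, crs=grid.crs, lon=grid.lon, lat=grid.lat,
                         or_mean=np.full(len(grid), np.nan),
                         or_sd=np.full(len(grid), np.nan),
                         s_sd=np.full(len(grid), np.nan))
    out.or_mean[sel] = mean_e
    out.or_sd[sel] = np.sqrt(var_e)
    out.s_sd[sel] = np.sqrt(var_s)
    return out


def sample_surface_at_points(grid: PredictionGrid, points: np.ndarray) -> np.ndarray:
    """Nearest-centroid lookup of the OR surface at query points.

    ``points`` is (m, 2) in the grid's crs (lon/lat degrees or km).  Points
    farther than half a cell diagonal outside the lattice return NaN with a
    warning.
    """
    if grid.or_mean is None:
        raise ValueError("grid has no predicted surface yet")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if grid.crs == "lonlat":
        # lon/lat -> planar km offsets using the grid's own projection constants
        kx = (grid.x_km.max() - grid.x_km.min()) / max(grid.lon.max() - grid.lon.min(), 1e-12)
        ky = (grid.y_km.max() - grid.y_km.min()) / max(grid.lat.max() - grid.lat.min(), 1e-12)
        px = grid.x_km.min() + (pts[:, 0] - grid.lon.min()) * kx
        py = grid.y_km.min() + (pts[:, 1] - grid.lat.min()) * ky
    else:
        px, py = pts[:, 0], pts[:, 1]
    half = grid.cell_km * 0.5 + 1e-9
    out = np.empty(len(pts))
    for m in range(len(pts)):
        d2 = (grid.x_km - px[m]) ** 2 + (grid.y_km - py[m]) ** 2
        k = int(np.argmin(d2))
        if abs(grid.x_km[k] - px[m]) > half + grid.cell_km or \
           abs(grid.y_km[k] - py[m]) > half + grid.cell_km:
            warnings.warn(f"point {m} lies outside the grid extent; returning NaN")
            out[m] = np.nan
        else:
            out[m] = grid.or_mean[k]
    return out


def correlate_with_classes(values: np.ndarray, classes) -> Tuple[float, float]:
    """Pearson correlation of surface values against ordinal class labels.

    Classes are integer-coded in their given (ordinal) order; the p-value is
    the two-sided t approximation.  Constant values raise (r undefined).
    """
    values = np.asarray(values, dtype=float)
    codes = pd.Categorical(classes).codes.astype(float)
    keep = np.isfinite(values) & (codes >= 0)
    values, codes = values[keep], codes[keep]
    if len(values) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(codes)) < 2:
        raise ValueError("need at least 2 classes present")
    if np.ptp(values) == 0:
        raise ValueError("constant surface values: correlation undefined")
    r, p = pearsonr(values, codes)
    return float(r), float(p)
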