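"""File contracts and the end-to-end pipeline.

All tabular artifacts are CSV with a single leading ``#`` header comment
carrying the software version and a config hash; the boundary (optional) is
GeoJSON.  Floats survive write -> read round trips exactly (shortest-repr
serialisation).  ``run_pipeline`` chains the stages in the study's order:
simulate -> describe -> fit both models -> validate both -> compare ->
predict, and writes a manifest with seeds and artifact hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .descriptive import table_one
from .krige import PredictionGrid, make_grid, predict_residual_surface
from .mcmc import McmcConfig, PosteriorSamples, fit, summarize_fixed_effects
from .model import ClusterSet, CovariateSchema
from .synthetic import SyntheticConfig, simulate
from .validate import validation_report

__all__ = [
    "RunConfig",
    "read_child_table",
    "write_child_table",
    "read_clusters",
    "write_clusters",
    "write_grid",
    "read_grid",
    "write_samples",
    "read_samples",
    "run_pipeline",
]

log = logging.getLogger("geoprev")


def _header(config_hash: str = "") -> str:
    return f"# geoprev {__version__} config={config_hash}\n"


def _write_csv(df: pd.DataFrame, path, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kw)


def config_hash(obj) -> str:
    """Stable short hash of a jsonable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# child table / clusters
# ---------------------------------------------------------------------------

def write_child_table(table: pd.DataFrame, path, config_hash: str = "") -> None:
    _write_csv(table, path, config_hash)


def read_child_table(path, schema: Optional[CovariateSchema] = None) -> pd.DataFrame:
    """Load a child table; empty cells become missing values.

    Requires ``child_id``, ``cluster_id`` and ``y`` columns; the outcome must
    be 0/1 with no gaps.  Categorical labels are validated against the schema
    when one is given.
    """
    df = _read_csv(path)
    for col in ("child_id", "cluster_id", "y"):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    if df["y"].isna().any():
        row = int(df.index[df["y"].isna()][0])
        raise ValueError(f"missing outcome at row {row}; children without valid "
                         "anthropometry must be dropped before analysis")
    bad = ~df["y"].isin((0, 1))
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"outcome must be 0/1; offending row {row}")
    if schema is not None:
        for cov in schema.categorical:
            vals = df[cov.name].dropna()
            unknown = set(vals) - set(cov.categories)
            if unknown:
                raise ValueError(f"unknown categories {sorted(unknown)!r} in column {cov.name!r}")
        for cov in schema.continuous:
            df[cov.name] = pd.to_numeric(df[cov.name], errors="raise")
    n_missing = int(df.drop(columns=["child_id", "cluster_id", "y"]).isna().sum().sum())
    log.info("read %d children, %d missing covariate cells from %s", len(df), n_missing, path)
    return df


def write_clusters(clusters: ClusterSet, path, config_hash: str = "") -> None:
    _write_csv(clusters.to_frame(), path, config_hash)


def read_clusters(path) -> ClusterSet:
    df = _read_csv(path)
    if "lon" in df.columns and "lat" in df.columns:
        coords, crs = df[["lon", "lat"]].to_numpy(dtype=float), "lonlat"
    elif "x_km" in df.columns and "y_km" in df.columns:
        coords, crs = df[["x_km", "y_km"]].to_numpy(dtype=float), "km"
    else:
        raise ValueError(f"{path}: expected lon/lat or x_km/y_km columns")
    return ClusterSet(ids=df["cluster_id"].to_numpy(), coords=coords, crs=crs)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def write_grid(grid: PredictionGrid, path, config_hash: str = "") -> None:
    df = grid.to_frame()
    df["cell_km"] = grid.cell_km
    df["crs"] = grid.crs
    _write_csv(df, path, config_hash)


def read_grid(path) -> PredictionGrid:
    df = _read_csv(path)
    crs = str(df["crs"].iloc[0])
    lon = df["lon"].to_numpy(dtype=float) if df["lon"].notna().any() else None
    lat = df["lat"].to_numpy(dtype=float) if df["lat"].notna().any() else None
    or_mean = df["or_mean"].to_numpy(dtype=float)
    or_sd = df["or_sd"].to_numpy(dtype=float)
    return PredictionGrid(x_km=df["x_km"].to_numpy(dtype=float),
                          y_km=df["y_km"].to_numpy(dtype=float),
                          cell_km=float(df["cell_km"].iloc[0]),
                          inside=df["inside"].to_numpy(dtype=bool), crs=crs,
                          lon=lon, lat=lat,
                          or_mean=None if np.isnan(or_mean).all() else or_mean,
                          or_sd=None if np.isnan(or_sd).all() else or_sd)


# ---------------------------------------------------------------------------
# posterior samples
# ---------------------------------------------------------------------------

def write_samples(samples: PosteriorSamples, path, config_hash: str = "") -> None:
    """Columnar CSV (one row per retained draw) plus a JSON metadata sidecar."""
    path = Path(path)
    cols = {}
    for j, nm in enumerate(samples.coef_names):
        cols[f"coef:{nm}"] = samples.draws["coef"][:, j]
    for key, arr in samples.draws.items():
        if key == "coef":
            continue
        if arr.ndim == 1:
            cols[key] = arr
        else:
            for j in range(arr.shape[1]):
                cols[f"{key}:{j}"] = arr[:, j]
    if samples.loglik_obs is not None:
        for j in range(samples.loglik_obs.shape[1]):
            cols[f"ll:{j}"] = samples.loglik_obs[:, j].astype(float)
    for name, arr in samples.imputed.items():
        for j in range(arr.shape[1]):
            cols[f"imp:{name}:{j}"] = arr[:, j].astype(float)
    _write_csv(pd.DataFrame(cols), path, config_hash)
    meta = {
        "model": samples.model,
        "coef_names": samples.coef_names,
        "cluster_ids": [str(c) for c in samples.cluster_ids],
        "schema": samples.schema.to_dict(),
        "acceptance": {k: float(v) for k, v in samples.acceptance.items()},
        "imputed_dtypes": {k: str(v.dtype) for k, v in samples.imputed.items()},
        "vector_keys": {k: int(v.shape[1]) for k, v in samples.draws.items() if v.ndim > 1},
        "n_obs": None if samples.loglik_obs is None else int(samples.loglik_obs.shape[1]),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_samples(path) -> PosteriorSamples:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    df = _read_csv(path)
    coef = df[[f"coef:{nm}" for nm in meta["coef_names"]]].to_numpy()
    draws = {"coef": coef}
    for key, width in meta["vector_keys"].items():
        if key == "coef":
            continue
        draws[key] = df[[f"{key}:{j}" for j in range(width)]].to_numpy()
    for key in df.columns:
        if ":" not in key:
            draws[key] = df[key].to_numpy()
        elif key.startswith(("mu_x:", "sigma_x:", "sigma_z:")):
            draws[key] = df[key].to_numpy()
    loglik = None
    if meta["n_obs"]:
        loglik = df[[f"ll:{j}" for j in range(meta["n_obs"])]].to_numpy(dtype=np.float32)
    imputed = {}
    for name, dt in meta["imputed_dtypes"].items():
        sub = [c for c in df.columns if c.startswith(f"imp:{name}:")]
        sub.sort(key=lambda c: int(c.rsplit(":", 1)[1]))
        imputed[name] = df[sub].to_numpy().astype(dt)
    return PosteriorSamples(model=meta["model"], coef_names=meta["coef_names"], draws=draws,
                            loglik_obs=loglik, imputed=imputed,
                            cluster_ids=np.asarray(meta["cluster_ids"]),
                            schema=CovariateSchema.from_dict(meta["schema"]),
                            acceptance=meta["acceptance"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run: simulation, chain, and grid settings plus output dir."""

    out_dir: str
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    cell_km: float = 5.0
    predict_thin: int = 10
    seed: int = 0


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> describe -> fit x2 -> validate x2 -> compare -> predict.

    Returns the manifest (also written as ``manifest.json``): artifact paths,
    sha256 hashes, seeds and the comparison verdict.  Any stage failure
    raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash({"synthetic": config.synthetic.to_dict(),
                         "mcmc": vars(config.mcmc), "cell_km": config.cell_km,
                         "seed": config.seed})
    stage = "simulate"
    artifacts = {}
    try:
        config.synthetic.seed = config.seed
        table, clusters, truth = simulate(config.synthetic)
        write_child_table(table, out / "children.csv", chash)
        write_clusters(clusters, out / "clusters.csv", chash)
        truth.to_yaml(out / "truth.yaml")
        inputs = {"children": out / "children.csv", "clusters": out / "clusters.csv",
                  "truth": out / "truth.yaml"}

        stage = "describe"
        desc = table_one(table, config.synthetic.covariate_schema)
        _write_csv(desc, out / "descriptive.csv", chash)
        artifacts["descriptive"] = out / "descriptive.csv"

        stage = "fit"
        schema = config.synthetic.covariate_schema
        reports = {}
        psml_by_model = {}
        for model, spatial in ((1, False), (2, True)):
            cfg = McmcConfig(n_iterations=config.mcmc.n_iterations, burn_in=config.mcmc.burn_in,
                             thinning=config.mcmc.thinning, seed=config.seed + model,
                             adapt=config.mcmc.adapt)
            samples = fit(table, clusters, schema, mcmc=cfg, spatial=spatial)
            write_samples(samples, out / f"samples_model{model}.csv", chash)
            artifacts[f"samples_model{model}"] = out / f"samples_model{model}.csv"
            stage = "validate"
            rep = validation_report(samples)
            _write_csv(rep.table, out / f"validation_model{model}.csv", chash)
            artifacts[f"validation_model{model}"] = out / f"validation_model{model}.csv"
            reports[model] = rep
            psml_by_model[model] = rep.psml
            if spatial:
                stage = "predict"
                grid = make_grid(bbox=config.synthetic.bbox, cell_km=config.cell_km,
                                 crs=config.synthetic.crs)
                grid = predict_residual_surface(samples, grid, clusters,
                                                thin=config.predict_thin, seed=config.seed)
                write_grid(grid, out / "residual_grid.csv", chash)
                artifacts["residual_grid"] = out / "residual_grid.csv"
            stage = "fit"
        stage = "compare"
        verdict = 2 if psml_by_model[2] > psml_by_model[1] else 1
        comparison = {"psml": {str(k): v for k, v in psml_by_model.items()},
                      "preferred_model": verdict}
        (out / "comparison.json").write_text(json.dumps(comparison, indent=1))
        artifacts["comparison"] = out / "comparison.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "psml": {str(k): v for k, v in psml_by_model.items()},
        "preferred_model": verdict,
        "fixed_effects": summarize_fixed_effects(samples).to_dict(orient="records"),
        "inputs": {k: {"path": str(p), "sha256": _sha(p)} for k, p in inputs.items()},
        "artifacts": {k: {"path": str(p), "sha256": _sha(p)} for k, p in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
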