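"""Readers, writers and the end-to-end pipeline.

The pipeline chains the full analysis: descriptive statistics, the global
OLS baseline with VIFs, the multiscale fit, the Monte Carlo
non-stationarity test, and the three-dimension disparity report.  Every
artifact is a headed CSV keyed by ``unit_id`` (or variable name), plus a
MANIFEST recording completion state and a plain-text echo of the
configuration and seeds, so a run is reproducible and diagnosable from its
output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baseline import fit_ols, vif
from .dataset import SpatialDataset
from .dimensions import dimension_report
from .exceptions import DataError, DegenerateVariableError, MgwrlabError
from .indices import IndexSpec, build_index
from .mgwr import MGWROptions, fit_mgwr, monte_carlo_test
from .synth import SyntheticConfig, TruthBundle, default_config, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` / ``simulate`` is set.  ``columns`` maps
    the roles (id, x, y, population, outcome) to CSV column names;
    ``covariates`` lists covariate columns in model order.
    """

    input_path: str | None = None
    simulate: SyntheticConfig | None = None
    columns: dict = field(
        default_factory=lambda: {
            "id": "unit_id", "x": "x", "y": "y",
            "population": "population", "outcome": "y_outcome",
        }
    )
    covariates: list[str] = field(default_factory=list)
    index_specs: list[IndexSpec] = field(default_factory=list)
    metric: str = "euclidean"
    mgwr: MGWROptions = field(default_factory=MGWROptions)
    alpha_policy: str = "corrected"
    n_perm: int = 99
    seed: int = 0
    out_dir: str = "mgwrlab_out"

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise DataError("set exactly one of input_path / simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        mg = raw.pop("mgwr", None)
        idx = raw.pop("index_specs", None)
        cfg = cls(**raw)
        if idx is not None:
            cfg.index_specs = [IndexSpec(**spec) for spec in idx]
        if sim is not None:
            if sim == "default":
                cfg.simulate = default_config()
            else:
                from .synth import SurfaceSpec

                surfaces = {
                    k: SurfaceSpec(v["kind"], {a: b for a, b in v.items() if a != "kind"})
                    for k, v in sim.pop("surfaces", {}).items()
                }
                cfg.simulate = SyntheticConfig(surfaces=surfaces, **sim)
        if mg is not None:
            cfg.mgwr = MGWROptions(**mg)
        cfg.validate()
        return cfg


def read_dataset(path: str | Path, config: PipelineConfig) -> SpatialDataset:
    """Load a unit table from CSV or GeoJSON points and standardize it.

    Composite indices declared in ``config.index_specs`` are constructed
    from their raw input columns first and become available as covariates
    under their index names.  Outcome and covariates are then z-scored with
    the means/SDs recorded on the returned dataset.  Missing mapped
    columns, missing values, duplicate ids and constant covariates are
    reported as errors.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        frame, metric = _read_geojson_points(path, config)
    else:
        frame = pd.read_csv(path)
        metric = config.metric
    for spec in config.index_specs:
        missing = [v for v in spec.variables if v not in frame.columns]
        if missing:
            raise DataError(f"index {spec.name!r} is missing inputs: {missing}")
        frame[spec.name] = build_index(frame, spec).scores
    cols = config.columns
    mapped = [cols[r] for r in ("id", "x", "y", "population", "outcome")] + list(
        config.covariates
    )
    missing = [c for c in mapped if c not in frame.columns]
    if missing:
        raise DataError(f"input is missing mapped columns: {missing}")
    sub = frame[mapped]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise DataError(f"missing values in mapped columns at rows {bad[:10]}")
    renames = {cols["id"]: "unit_id", cols["x"]: "x", cols["y"]: "y",
               cols["population"]: "population", cols["outcome"]: "y_outcome"}
    tidy = sub.rename(columns=renames)
    for c in config.covariates:
        if tidy[c].nunique() < 2:
            raise DegenerateVariableError(f"covariate {c!r} is constant")
    data = SpatialDataset.from_frame(tidy, config.covariates, metric=metric)
    return data.standardized()


def _read_geojson_points(path: Path, config: PipelineConfig):
    gj = json.loads(path.read_text())
    rows = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise DataError("GeoJSON input must contain Point features")
        props = dict(feat.get("properties") or {})
        props[config.columns["x"]], props[config.columns["y"]] = geom["coordinates"][:2]
        rows.append(props)
    logger.info("GeoJSON input: coordinates read as lon/lat, metric set to haversine")
    return pd.DataFrame(rows), "haversine"


def write_dataset(data: SpatialDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_geojson_points(
    data: SpatialDataset, path: str | Path, extra: pd.DataFrame | None = None
) -> None:
    """Point-feature export (one feature per unit) for downstream mapping."""
    frame = data.to_frame()
    if extra is not None:
        frame = frame.merge(extra, on="unit_id", how="left")
    feats = []
    for _, row in frame.iterrows():
        props = {k: (v.item() if hasattr(v, "item") else v) for k, v in row.items()
                 if k not in ("x", "y")}
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                "properties": props,
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_truth(truth: TruthBundle, names: list[str], unit_ids, path: str | Path) -> None:
    truth.to_frame(names, unit_ids).to_csv(path, index=False)


def descriptive_stats(data: SpatialDataset) -> pd.DataFrame:
    """Mean/SD/min/max of the outcome and covariates on their input scale."""
    frame = data.to_frame()
    cols = ["y_outcome"] + [nm for nm in data.names if nm != "intercept"]
    rows = []
    for c in cols:
        v = frame[c].to_numpy(dtype=float)
        rows.append(
            {"variable": c, "mean": v.mean(), "sd": v.std(ddof=1),
             "min": v.min(), "max": v.max()}
        )
    return pd.DataFrame(rows)


def quantile_bins(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Quantile bin labels (1..n_bins) with ties going to the lower bin."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return 1 + np.searchsorted(qs, values, side="left")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write artifacts; returns the output dir.

    On a stage failure the partial artifacts are preserved and the MANIFEST
    records which stages completed before the error is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _note(stage: str) -> None:
        manifest.append(stage)
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")

    try:
        if config.simulate is not None:
            data, truth = simulate_dataset(config.simulate)
            write_dataset(data, out / "dataset.csv")
            write_truth(truth, data.names, data.units["unit_id"], out / "truth.csv")
            data = data.standardized()
        else:
            data = read_dataset(config.input_path, config)
        _note("load")

        descriptive_stats(data).to_csv(out / "descriptives.csv", index=False)
        _note("descriptives")

        ols = fit_ols(data)
        vrep = vif(data.X[:, 1:], data.names[1:])
        ols_tab = pd.DataFrame(
            {
                "variable": ols.names,
                "estimate": ols.coefficients,
                "se": ols.se,
                "t": ols.tvalues,
                "p": ols.pvalues,
                "vif": [np.nan] + list(vrep.vif),
            }
        )
        ols_tab.attrs["aicc"] = ols.aicc
        ols_tab.to_csv(out / "ols.csv", index=False)
        _note("ols")

        logger.info("fitting MGWR (n=%d, %d terms)", data.n, len(data.names))
        res = fit_mgwr(data, config.mgwr)
        for s, soc in enumerate(res.soc_history):
            logger.info("  sweep %d: SOC-f %.3e", s + 1, soc)
        unit_ids = data.units["unit_id"].to_numpy()
        local = pd.DataFrame({"unit_id": unit_ids})
        sig = res.significant(config.alpha_policy)
        for j, nm in enumerate(res.names):
            local[f"{nm}_est"] = res.params[:, j]
            local[f"{nm}_se"] = res.se[:, j]
            local[f"{nm}_t"] = res.tvalues[:, j]
            local[f"{nm}_sig"] = sig[:, j].astype(int)
        local.to_csv(out / "mgwr_local.csv", index=False)
        pd.DataFrame(
            {"unit_id": unit_ids, "local_r2": res.local_r2}
        ).to_csv(out / "local_r2.csv", index=False)
        _note("mgwr")

        mc = monte_carlo_test(data, res, n_perm=config.n_perm, seed=config.seed)
        summary = pd.DataFrame(
            {
                "variable": res.names,
                "bandwidth": res.bandwidths,
                "enp": res.enp,
                "mean": res.params.mean(axis=0),
                "sd": res.params.std(axis=0, ddof=1),
                "min": res.params.min(axis=0),
                "median": np.median(res.params, axis=0),
                "max": res.params.max(axis=0),
                "monte_carlo_p": mc.pvalues,
            }
        )
        summary.to_csv(out / "mgwr_summary.csv", index=False)
        pd.DataFrame(
            {"model": ["ols", "mgwr"], "aicc": [ols.aicc, res.aicc],
             "adjusted_r2": [ols.adjusted_r2, res.adjusted_r2]}
        ).to_csv(out / "model_comparison.csv", index=False)
        _note("montecarlo")

        report = dimension_report(res, data, config.alpha_policy)
        report.table.to_csv(out / "dimensions.csv", index=False)
        report.dominant.rename_axis("unit_id").reset_index().to_csv(
            out / "dominant_variable.csv", index=False
        )
        _note("dimensions")

        echo = {
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha_policy": config.alpha_policy,
            "metric": data.metric,
            "mgwr": vars(config.mgwr),
            "converged": res.converged,
        }
        (out / "run_config.txt").write_text(yaml.safe_dump(echo))
        _note("done")
    except MgwrlabError:
        _note("FAILED")
        raise
    return out
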