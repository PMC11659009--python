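"""AGB map rendering and end-to-end pipeline orchestration.

The default map is plot-level (choropleth): every pixel of a plot carries
the plot's predicted AGB in kg/ha, non-plot pixels hold the nodata
sentinel.  A per-pixel mode exists for visual inspection but the features
driving the models are plot-zonal, so the choropleth is the faithful
rendering of what was estimated.

:func:`run_pipeline` runs simulate -> features -> screen/fit -> evaluate
-> map from a single config and writes every artifact (feature CSVs,
evaluation report, importances, maps, manifest, log) into one output
directory.  Re-running with the same config and seed reproduces the CSVs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canopyagb._version import __version__ as _pkg_version
from canopyagb.geo import (
    PlotROI,
    RasterGrid,
    STAGES,
    plots_to_geojson,
    rasterize_roi,
    read_observations,
    read_plots,
    read_raster,
    write_raster,
)
from canopyagb.modeling import (
    FEATURE_SETS,
    ModelConfig,
    build_feature_table,
    evaluate_grid,
    fit,
    rf_importance,
    split_by_replicate,
)
from canopyagb.scene import SceneConfig, generate_multistage
from canopyagb.spectral import vi_table
from canopyagb.structure import chm, sf_table
from canopyagb.texture import TextureConfig, tf_table

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "predict_plot_map", "run_pipeline"]

NODATA = -9999.0


def predict_plot_map(model, feature_table: pd.DataFrame, plots: list[PlotROI],
                     template: RasterGrid) -> RasterGrid:
    """Choropleth raster of per-plot predicted AGB on the template grid."""
    missing = [f for f in model.feature_names if f not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table lacks model features {missing}")
    out = np.full(template.shape, NODATA, dtype=float)
    table = feature_table.set_index("plot_id")
    for roi in plots:
        if roi.plot_id not in table.index:
            continue
        row = table.loc[[roi.plot_id]]
        pred = float(model.predict(row[list(model.feature_names)])[0])
        out[rasterize_roi(roi, template)] = pred
    return RasterGrid(values=out, transform=template.transform,
                      nodata=NODATA, crs_id=template.crs_id)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    mode: str = "synthetic"                  # "synthetic" or "real"
    scene: dict = field(default_factory=dict)  # SceneConfig overrides
    paths: dict = field(default_factory=dict)  # real mode: per-stage raster paths
    stages: tuple[str, ...] = STAGES
    texture: dict = field(default_factory=dict)  # TextureConfig overrides
    screening_threshold: float = 0.6
    algorithms: tuple[str, ...] = ("DNN", "RF", "SVR")
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
    cv_folds: int = 10
    map_algorithm: str = "DNN"
    map_feature_set: str = "VI+TF+SF"
    seed: int = 0
    output_dir: str = "canopyagb_run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        bad = [s for s in self.feature_sets if s not in FEATURE_SETS]
        if bad:
            raise ValueError(f"unknown feature sets {bad}")
        if self.mode == "real":
            for stage in self.stages:
                p = self.paths.get(stage, {})
                for key in ("cube", "rgb", "dsm", "dem"):
                    if key not in p:
                        raise ValueError(f"paths.{stage}.{key} is required in real mode")
            for key in ("plots", "observations"):
                if key not in self.paths:
                    raise ValueError(f"paths.{key} is required in real mode")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self) -> str:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            return x

        return yaml.safe_dump(plain(dataclasses.asdict(self)), sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_stage_inputs(cfg: PipelineConfig):
    """Per-stage (cube, rgb, dsm, dem, plots) plus the observation table."""
    stages = {}
    hashes = {}
    if cfg.mode == "synthetic":
        scene_cfg = SceneConfig(**{**cfg.scene, "seed": cfg.seed})
        scenes = generate_multistage(scene_cfg, stages=cfg.stages)
        obs = pd.concat([s.observations for s in scenes.values()],
                        ignore_index=True)
        for stage, sc in scenes.items():
            stages[stage] = dict(cube=sc.cube, rgb=sc.rgb, dsm=sc.dsm,
                                 dem=sc.dem, plots=sc.plots, truth=sc.truth)
        hashes["scene_config"] = hashlib.sha256(
            json.dumps(cfg.scene, sort_keys=True).encode()).hexdigest()
    else:
        plots_all = read_plots(cfg.paths["plots"])
        obs = read_observations(cfg.paths["observations"])
        hashes["plots"] = _sha256(Path(cfg.paths["plots"]))
        hashes["observations"] = _sha256(Path(cfg.paths["observations"]))
        for stage in cfg.stages:
            p = cfg.paths[stage]
            entry = {}
            for key in ("cube", "rgb", "dsm", "dem"):
                entry[key] = read_raster(p[key])
                hashes[f"{stage}/{key}"] = _sha256(Path(p[key]))
            entry["plots"] = [dataclasses.replace(r, stage=stage) for r in plots_all]
            entry["truth"] = None
            stages[stage] = entry
    return stages, obs, hashes


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full image-to-biomass analysis; returns the output directory."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("canopyagb")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        (out / "config.yaml").write_text(cfg.to_yaml())
        stage_inputs, obs, hashes = _load_stage_inputs(cfg)
        tex_cfg = TextureConfig(**cfg.texture)

        vi_parts, tf_parts, sf_parts = [], [], []
        for stage, inp in stage_inputs.items():
            log.info("stage %s: extracting features for %d plots",
                     stage, len(inp["plots"]))
            try:
                vi_parts.append(vi_table(inp["cube"], inp["plots"], rgb=inp["rgb"]))
                tf_parts.append(tf_table(inp["rgb"], inp["plots"], tex_cfg))
                chm_model = chm(inp["dsm"], inp["dem"])
                log.info("stage %s: %d negative CHM pixels clamped",
                         stage, chm_model.clamped_negative_count)
                sf_parts.append(sf_table(chm_model, inp["rgb"], inp["plots"]))
            except Exception as exc:
                raise RuntimeError(f"feature extraction failed at stage {stage}: {exc}"
                                   ) from exc
        vi_df = pd.concat(vi_parts, ignore_index=True)
        tf_df = pd.concat(tf_parts, ignore_index=True)
        sf_df = pd.concat(sf_parts, ignore_index=True)
        vi_df.to_csv(out / "features_vi.csv", index=False)
        tf_df.to_csv(out / "features_tf.csv", index=False)
        sf_df.to_csv(out / "features_sf.csv", index=False)

        plots_all = [r for inp in stage_inputs.values() for r in inp["plots"]]
        table = build_feature_table(obs, plots_all, vi_df, tf_df, sf_df)
        table.to_csv(out / "feature_table.csv", index=False)

        eval_stages = ["pooled", *[s for s in cfg.stages if len(cfg.stages) > 1]]
        report = evaluate_grid(
            table, {k: FEATURE_SETS[k] for k in cfg.feature_sets},
            algorithms=cfg.algorithms, stages=eval_stages,
            threshold=cfg.screening_threshold, seed=cfg.seed,
            cv_folds=cfg.cv_folds)
        report.table.to_csv(out / "evaluation.csv", index=False)
        report.table.to_json(out / "evaluation.json", orient="records", indent=2)
        report.predictions.to_csv(out / "predictions.csv", index=False)

        # RF variable importance per stage on the screened combined set
        imp_parts = []
        for stage in eval_stages:
            names = list(report.selected[(stage, cfg.map_feature_set)])
            sub = table if stage == "pooled" else table[table["stage"] == stage]
            cal, _ = split_by_replicate(sub)
            cal = cal.dropna(subset=names + ["agb_kg_ha"])
            rf = fit(ModelConfig(algorithm="RF", seed=cfg.seed), cal[names],
                     cal["agb_kg_ha"].to_numpy())
            imp = rf_importance(rf)
            imp.insert(0, "stage", stage)
            imp_parts.append(imp)
        pd.concat(imp_parts, ignore_index=True).to_csv(
            out / "importance.csv", index=False)

        # AGB maps from the configured model, one per stage
        for stage, inp in stage_inputs.items():
            names = list(report.selected[("pooled", cfg.map_feature_set)])
            cal, _ = split_by_replicate(table)
            cal = cal.dropna(subset=names + ["agb_kg_ha"])
            model = fit(ModelConfig(algorithm=cfg.map_algorithm, seed=cfg.seed),
                        cal[names], cal["agb_kg_ha"].to_numpy())
            stage_rows = table[table["stage"] == stage].dropna(subset=names)
            amap = predict_plot_map(model, stage_rows, inp["plots"],
                                    inp["rgb"] if inp["rgb"].values.ndim == 2
                                    else RasterGrid(values=inp["rgb"].values[0],
                                                    transform=inp["rgb"].transform,
                                                    crs_id=inp["rgb"].crs_id))
            write_raster(amap, out / f"agb_map_{stage}.tif")
            plots_to_geojson(inp["plots"], out / f"plots_{stage}.geojson")

        manifest = {
            "package_version": _pkg_version,
            "seed": cfg.seed,
            "inputs": hashes,
            "n_rows": int(len(table)),
            "stages": list(cfg.stages),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        log.info("pipeline complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
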