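"""End-to-end pipeline: BPI -> delineate -> describe -> join/cover -> model.

Driven by a YAML config; every stage writes its artefacts into the output
directory and a run manifest records versions, seeds, the parameters
actually applied, per-stage counts and output checksums, so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bpi import compute_bpi
from .delineation import DelineationConfig, delineate
from .description import cover_class, describe_features, join_current
from .grid import AnnulusSpec, Grid, read_raster, rugosity, write_raster
from .habitat import ModelConfig, predict_map, select_predictors, train_rf
from .io_vector import write_attributes_csv, write_features
from .synthetic import (
    SyntheticSceneConfig,
    generate_current,
    generate_dem,
    generate_labels,
    reference_scene_config,
)

log = logging.getLogger("reefmounds")

__all__ = ["run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """A pipeline config failed validation; message names the field."""


def _require(cfg: dict, key: str, context: str):
    if key not in cfg:
        raise ConfigError(f"config field {context}.{key} is required")
    return cfg[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ConfigError("config field inputs.dem is required (or a synthetic: section)")
    if "inputs" in cfg and "dem" not in cfg["inputs"] and "synthetic" not in cfg:
        raise ConfigError("config field inputs.dem is required")
    return cfg


def run_pipeline(config_path, output_dir=None) -> dict:
    """Execute the full chain described by a YAML config; returns the manifest."""
    config_path = Path(config_path)
    cfg = _load_config(config_path)
    out_dir = Path(output_dir or cfg.get("output_dir", config_path.parent / "run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "config": str(config_path),
        "seed": seed,
        "parameters": {},
        "counts": {},
        "outputs": {},
    }

    # ------------------------------------------------------------------ inputs
    backscatter = current = None
    coral_polys = None
    labels_df = None
    if "synthetic" in cfg:
        syn = cfg["synthetic"] or {}
        scene = reference_scene_config(
            n_mounds=int(syn.get("n_mounds", 120)),
            noise_sd=float(syn.get("noise_sd", 0.0)),
            seed=int(syn.get("seed", seed)),
            grid_shape=tuple(syn.get("grid_shape", (700, 1000))),
        )
        dem, registry = generate_dem(scene)
        current = generate_current(scene)
        manifest["counts"]["planted_mounds"] = len(registry)
        write_raster(dem, out_dir / "dem.tif")
        manifest["parameters"]["synthetic"] = {
            "n_mounds": len(scene.mounds),
            "noise_sd": scene.noise_sd,
            "seed": scene.seed,
        }
    else:
        inp = cfg["inputs"]
        dem = read_raster(
            _require(inp, "dem", "inputs"),
            depth_positive=bool(inp.get("depth_positive", False)),
        )
        if inp.get("backscatter"):
            backscatter = read_raster(inp["backscatter"])
        if inp.get("current"):
            current = read_raster(inp["current"])
        if inp.get("coral"):
            from .io_vector import read_features

            coral_feats, _ = read_features(inp["coral"])
            coral_polys = [f.ring for f in coral_feats]
        if inp.get("labels"):
            labels_df = pd.read_csv(inp["labels"])
        scene = None

    # ------------------------------------------------------------------ bpi
    bpi_cfg = cfg.get("bpi", {})
    annulus = AnnulusSpec(int(bpi_cfg.get("inner", 8)), int(bpi_cfg.get("outer", 24)))
    log.info("computing BPI (i%d x o%d)", annulus.inner_radius_cells, annulus.outer_radius_cells)
    bpi = compute_bpi(dem, annulus)
    write_raster(bpi, out_dir / "bpi.tif")
    manifest["parameters"]["bpi"] = {
        "inner": annulus.inner_radius_cells,
        "outer": annulus.outer_radius_cells,
    }

    # ------------------------------------------------------------ delineation
    dcfg = DelineationConfig(**(cfg.get("delineation", {}) or {}))
    log.info(
        "delineating: cutline %.2f, min BPI %.2f, min area %.0f m2, min W/L %.2f, buffer %.1f m",
        dcfg.cutline_bpi, dcfg.min_bpi, dcfg.min_area, dcfg.min_wl_ratio, dcfg.buffer_distance,
    )
    features = delineate(bpi, dcfg)
    manifest["parameters"]["delineation"] = dcfg.__dict__
    manifest["counts"]["features"] = len(features)

    # ------------------------------------------------------------ description
    desc_cfg = cfg.get("description", {}) or {}
    rug = rugosity(dem, method=desc_cfg.get("rugosity_method", "sd_of_slope"))
    attrs = describe_features(
        dem,
        bpi,
        features,
        rug,
        backscatter=backscatter,
        contour_interval=float(desc_cfg.get("contour_interval", 0.5)),
    )
    if current is not None:
        attrs = join_current(attrs, features, current)

    # ----------------------------------------------------- labels / coral cover
    if scene is not None and features:
        from .description import attributes_table

        table = attributes_table(attrs)
        labelled, coral_polys = generate_labels(table, scene, features)
        labels_df = labelled[["FeatureID", "Presence"]].rename(
            columns={"FeatureID": "feature_id", "Presence": "presence"}
        )
    if coral_polys is not None:
        attrs = cover_class(attrs, features, coral_polys)
    if labels_df is not None:
        by_id = {r.feature_id: r for r in attrs}
        for _, row in labels_df.iterrows():
            rec = by_id.get(int(row["feature_id"]))
            if rec is not None:
                rec.presence = bool(row["presence"])
    write_attributes_csv(attrs, out_dir / "attributes.csv")
    write_features(features, out_dir / "features.geojson", attributes=attrs,
                  crs_tag=dem.crs_tag)
    manifest["counts"]["attributed_features"] = len(attrs)

    # ------------------------------------------------------------------ model
    from .description import attributes_table

    table = attributes_table(attrs)
    have_labels = table.get("Presence") is not None and table["Presence"].notna().any()
    if have_labels and table["Presence"].nunique() > 1:
        mcfg_dict = dict(cfg.get("model", {}) or {})
        mcfg_dict.setdefault("seed", seed)
        mcfg = ModelConfig(**mcfg_dict)
        predictors = select_predictors(table, table["Presence"], mcfg)
        model, training, holdout = train_rf(table, mcfg, predictors, compute_curves=True)
        manifest["parameters"]["model"] = {
            "n_trees": mcfg.n_trees,
            "vars_per_split": mcfg.vars_per_split,
            "test_fraction": mcfg.test_fraction,
            "target": mcfg.target,
            "predictors": predictors,
            "seed": mcfg.seed,
        }
        (out_dir / "training_report.json").write_text(training.to_json())
        (out_dir / "holdout_report.json").write_text(holdout.to_json())
        holdout.importance.to_csv(out_dir / "importance.csv", header=["mean_decrease_accuracy"])
        proba = predict_map(model, table)
        pred = pd.DataFrame({"FeatureID": table["FeatureID"], "PresenceProb": proba})
        pred.to_csv(out_dir / "predictions.csv", index=False)
        write_features(
            features,
            out_dir / "prediction_map.geojson",
            attributes=attrs,
            extra={int(fid): {"presence_prob": float(p)}
                   for fid, p in zip(table["FeatureID"], proba)},
            crs_tag=dem.crs_tag,
        )
        manifest["counts"]["predicted_features"] = len(pred)
        manifest["model_summary"] = {
            "oob_error": training.oob_error,
            "holdout_sensitivity": holdout.sensitivity,
            "holdout_specificity": holdout.specificity,
            "holdout_auc": holdout.auc,
        }
    else:
        log.info("no (or single-class) labels: model stage skipped")
        manifest["counts"]["predicted_features"] = 0

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out_dir.iterdir()) if p.name != "manifest.json"
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
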