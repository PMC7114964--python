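"""GeoJSON read/write for delineated features and their attribute records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .delineation import FeaturePolygon
from .description import FeatureAttributes, attributes_table

__all__ = ["write_features", "read_features", "write_attributes_csv"]


def _clean(value):
    if isinstance(value, (np.floating, float)):
        return None if not np.isfinite(value) else float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def write_features(
    features: list[FeaturePolygon],
    path,
    attributes: list[FeatureAttributes] | None = None,
    extra: dict[int, dict] | None = None,
    crs_tag: str | None = None,
) -> None:
    """Write features (buffered outlines) as a GeoJSON FeatureCollection.

    Attribute records, when given, are flattened into each feature's
    properties; ``extra`` maps feature_id -> additional properties (e.g. the
    predicted presence probability).
    """
    table = None
    if attributes is not None:
        table = attributes_table(attributes).set_index("FeatureID")
    out = {"type": "FeatureCollection", "features": []}
    if crs_tag:
        out["crs_tag"] = crs_tag
    for feat in features:
        props = {"feature_id": feat.feature_id, "merged_flag": feat.merged_flag,
                 "edited_flag": feat.edited_flag}
        if table is not None and feat.feature_id in table.index:
            props.update({k: _clean(v) for k, v in table.loc[feat.feature_id].items()})
        if extra and feat.feature_id in extra:
            props.update({k: _clean(v) for k, v in extra[feat.feature_id].items()})
        out["features"].append(
            {"type": "Feature", "geometry": mapping(feat.ring), "properties": props}
        )
    Path(path).write_text(json.dumps(out))


def read_features(path) -> tuple[list[FeaturePolygon], pd.DataFrame]:
    """Read a feature GeoJSON back into outlines + a properties table."""
    doc = json.loads(Path(path).read_text())
    features, rows = [], []
    for f in doc["features"]:
        props = f.get("properties", {})
        fid = int(props.get("feature_id", len(features) + 1))
        geom = shape(f["geometry"])
        features.append(
            FeaturePolygon(
                feature_id=fid,
                ring=geom,
                raw_ring=geom,
                merged_flag=bool(props.get("merged_flag", False)),
                edited_flag=bool(props.get("edited_flag", False)),
            )
        )
        rows.append(props)
    return features, pd.DataFrame(rows)


def write_attributes_csv(attributes: list[FeatureAttributes], path) -> None:
    attributes_table(attributes).to_csv(path, index=False)
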