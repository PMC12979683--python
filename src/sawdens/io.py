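"""Readers and writers for the pipeline's open interchange formats.

Survey tables travel as CSV with ISO-8601 dates; scenes as TIFF rasters
(with JSON georeference sidecars) plus GeoJSON grid polygons and
shoreline; configuration as YAML; fitted models and reports as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping

#: canonical survey CSV column order
SURVEY_COLUMNS = [
    "set_id", "date", "x", "y", "microgrid_id", "effort_yard_min",
    "depth_min_m", "avg_temp", "avg_do", "avg_salin", "avg_ph",
    "sum_mnn", "min_mdts", "river", "dist_to_rm_m", "developed_sl",
    "year", "season", "n_caught", "n_fish", "lengths_stl_m", "sexes",
]


def write_survey_csv(survey: pd.DataFrame, path) -> None:
    cols = [c for c in SURVEY_COLUMNS if c in survey.columns]
    survey[cols].to_csv(path, index=False, date_format="%Y-%m-%d")


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    for col in ("lengths_stl_m", "sexes"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_geojson(geometries, path, properties=None) -> None:
    feats = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties else {}
        feats.append({"type": "Feature", "geometry": mapping(geom),
                      "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path):
    with open(path) as fh:
        gj = json.load(fh)
    return [shapely.geometry.shape(f["geometry"]) for f in gj["features"]]


def config_to_yaml(config, path) -> None:
    """Serialize a (possibly nested) dataclass config to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=True)


def config_hash(config) -> str:
    """Short stable hash of a config, stamped into every output file name."""
    blob = json.dumps(_plain(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if not callable(getattr(obj, f.name))}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()
                if not callable(v)}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_plain(obj), fh, indent=2, default=str)
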