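"""GeoJSON read/write for polygons (candidate areas) and polylines (rivers)."""

from __future__ import annotations

import json

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def write_geojson(features: dict[str, BaseGeometry] | list, path, properties=None) -> None:
    """Write named geometries (or (geometry, properties) pairs) as a FeatureCollection."""
    feats = []
    if isinstance(features, dict):
        items = [(k, g, {"name": k}) for k, g in features.items()]
    else:
        items = [(None, g, p or {}) for g, p in features]
    if properties is not None and isinstance(features, dict):
        items = [(k, g, {**p, **properties.get(k, {})}) for k, g, p in items]
    for _, geom, props in items:
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path) -> dict[str, BaseGeometry]:
    """Read a FeatureCollection into {name: geometry}; unnamed features get indices."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for i, feat in enumerate(gj["features"]):
        name = str((feat.get("properties") or {}).get("name", i))
        out[name] = shape(feat["geometry"])
    return out
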