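"""File formats and schema validation.

All tabular artifacts are plain CSV with fixed, documented column sets;
geography travels as GeoJSON (a FeatureCollection of Point features with
``division_id`` and ``province_id`` properties, or polygons whose
centroid is taken as the division centroid).  Spatial weights use the
sparse edge-list text format of
:meth:`vapegeo.spatial.SpatialWeights.to_edgelist`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

#: required columns per table kind (extra columns are allowed and kept)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "respondents": (
        "respondent_id", "division_id", "age_group", "sex",
        "source", "weight",
    ),
    "covariates": ("division_id",),
    "estimates": (
        "division_id", "n_j", "prevalence", "ci_low", "ci_high",
        "suppressed", "merged_into",
    ),
    "truth": ("division_id", "u_true", "p_true_ends", "p_true_smoke"),
}


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    required = SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table is missing required column(s) {missing}; "
            f"expected at least {list(required)}"
        )
    if df["division_id"].isna().any():
        raise SchemaError(f"{kind} table has missing division_id values")
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} file not found: {path}")
    return validate_table(pd.read_csv(path), kind)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# -- geography / GeoJSON ----------------------------------------------------

def write_geojson(geography: pd.DataFrame, path, estimates: pd.DataFrame | None = None) -> None:
    """Write division centroids (optionally joined with estimates) as GeoJSON."""
    props_extra: dict[str, dict] = {}
    if estimates is not None:
        keep = [c for c in ("n_j", "prevalence", "ci_low", "ci_high", "suppressed", "merged_into") if c in estimates.columns]
        for _, row in estimates.iterrows():
            rec = {}
            for c in keep:
                v = row[c]
                if pd.isna(v):
                    rec[c] = None
                elif isinstance(v, (bool,)):
                    rec[c] = bool(v)
                elif isinstance(v, (int, float)):
                    rec[c] = float(v) if c != "n_j" else int(v)
                else:
                    rec[c] = v
            props_extra[row["division_id"]] = rec
    features = []
    for _, row in geography.iterrows():
        props = {
            "division_id": row["division_id"],
            "province_id": row["province_id"],
        }
        props.update(props_extra.get(row["division_id"], {}))
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": features},
            fh, sort_keys=True, separators=(",", ":"),
        )


def _polygon_centroid(coords) -> tuple[float, float]:
    """Area-weighted centroid of a GeoJSON polygon's outer ring."""
    ring = coords[0]
    a = cx = cy = 0.0
    for (x0, y0), (x1, y1) in zip(ring, ring[1:]):
        cross = x0 * y1 - x1 * y0
        a += cross
        cx += (x0 + x1) * cross
        cy += (y0 + y1) * cross
    if a == 0:
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        return sum(xs) / len(xs), sum(ys) / len(ys)
    return cx / (3 * a), cy / (3 * a)


def read_geojson(path) -> pd.DataFrame:
    """Read division geography from GeoJSON into the centroid frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geography file not found: {path}")
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        geom = feat["geometry"]
        if geom["type"] == "Point":
            x, y = geom["coordinates"]
        elif geom["type"] == "Polygon":
            x, y = _polygon_centroid(geom["coordinates"])
        elif geom["type"] == "MultiPolygon":
            x, y = _polygon_centroid(geom["coordinates"][0])
        else:
            raise SchemaError(f"unsupported geometry type {geom['type']!r}")
        props = feat.get("properties", {})
        if "division_id" not in props:
            raise SchemaError("GeoJSON feature lacks a division_id property")
        rows.append(
            {
                "division_id": props["division_id"],
                "province_id": props.get("province_id", "P1"),
                "x": x,
                "y": y,
            }
        )
    df = pd.DataFrame(rows)
    if df["division_id"].duplicated().any():
        raise SchemaError("duplicate division_id in geography")
    return df


# -- checksums ---------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
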