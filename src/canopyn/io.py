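"""File formats: CSV tables, multiband TIFF rasters, GeoJSON layouts, model
JSON and YAML configs.

Every output embeds the seed and a config hash (as ``# key: value`` header
comments for CSV, properties for GeoJSON, a JSON field otherwise), so any run
is reproducible from its artifacts.  Tables are CSV with '.' decimal
separator and UTF-8; write -> read round-trips are lossless (floats are
serialized via repr).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import tifffile
import yaml

from .core import BandStack, LayoutItem, Rect
from .models import FitSummary, NitrogenModelI, NitrogenModelII
from .synthetic import SynthConfig, config_from_dict, config_to_dict

PathLike = Union[str, Path]


def config_hash(config: SynthConfig) -> str:
    """Short stable digest of the full configuration."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _meta_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items() if v is not None)


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path: PathLike, **meta) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, index=False)


def read_table(path: PathLike) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, meta


def require_columns(df: pd.DataFrame, expected: Sequence[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{name}: header mismatch; expected columns {list(expected)}, "
            f"found {list(df.columns)} (missing {missing})"
        )


# ---------------------------------------------------------------------------
# rasters

def write_band_stack(stack: BandStack, path: PathLike, **meta) -> None:
    """Multiband TIFF, one page per band; wavelengths and provenance in the
    ImageDescription JSON."""
    desc = json.dumps(
        {
            "band_centers": list(stack.band_centers),
            "value_kind": stack.value_kind,
            **{k: v for k, v in meta.items() if v is not None},
        }
    )
    tifffile.imwrite(Path(path), stack.values, description=desc,
                     photometric="minisblack")


def read_band_stack(path: PathLike) -> tuple[BandStack, dict]:
    with tifffile.TiffFile(Path(path)) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    stack = BandStack(
        values=values,
        band_centers=tuple(meta.pop("band_centers")),
        value_kind=meta.pop("value_kind"),
    )
    return stack, meta


# ---------------------------------------------------------------------------
# layouts

def write_layout(items: Sequence[LayoutItem], path: PathLike, **meta) -> None:
    """GeoJSON FeatureCollection of rectangle polygons in pixel coordinates.

    Polygon exteriors trace the half-open bounds (x = col, y = row); the
    exact integer bounds are repeated in the properties so the round-trip is
    lossless.
    """
    features = []
    for item in items:
        r = item.rect
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[
                        [r.col0, r.row0], [r.col1, r.row0],
                        [r.col1, r.row1], [r.col0, r.row1],
                        [r.col0, r.row0],
                    ]],
                },
                "properties": {
                    "role": item.role,
                    "id": item.item_id,
                    "variety": item.variety,
                    "stage": item.stage,
                    "reflectance": item.reflectance,
                    "row0": r.row0, "row1": r.row1,
                    "col0": r.col0, "col1": r.col1,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {k: v for k, v in meta.items() if v is not None},
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_layout(path: PathLike) -> tuple[list[LayoutItem], dict]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    items = []
    for feat in doc["features"]:
        p = feat["properties"]
        items.append(
            LayoutItem(
                role=p["role"],
                item_id=p["id"],
                rect=Rect(p["row0"], p["row1"], p["col0"], p["col1"]),
                variety=p.get("variety"),
                stage=p.get("stage"),
                reflectance=p.get("reflectance"),
            )
        )
    return items, doc.get("properties", {})


# ---------------------------------------------------------------------------
# fitted models

def model_to_dict(model: Union[NitrogenModelI, NitrogenModelII]) -> dict:
    s = model.summary
    summary = {
        "n": s.n,
        "r_squared": s.r_squared,
        "adj_r_squared": s.adj_r_squared,
        "pearson_r": s.pearson_r,
        "p_value": s.p_value,
    }
    if isinstance(model, NitrogenModelI):
        return {"model": "quadratic", "coefficients": {"a": model.a, "b": model.b, "c": model.c},
                "summary": summary}
    return {"model": "exponential",
            "coefficients": {"alpha": model.alpha, "beta": model.beta},
            "summary": summary}


def write_model(model, path: PathLike, **meta) -> None:
    doc = model_to_dict(model)
    doc.update({k: v for k, v in meta.items() if v is not None})
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_model(path: PathLike) -> Union[NitrogenModelI, NitrogenModelII]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    s = doc["summary"]
    summary = FitSummary(
        n=s["n"], r_squared=s["r_squared"], adj_r_squared=s["adj_r_squared"],
        pearson_r=s["pearson_r"], p_value=s["p_value"],
    )
    coef = doc["coefficients"]
    if doc["model"] == "quadratic":
        return NitrogenModelI(a=coef["a"], b=coef["b"], c=coef["c"], summary=summary)
    if doc["model"] == "exponential":
        return NitrogenModelII(alpha=coef["alpha"], beta=coef["beta"], summary=summary)
    raise ValueError(f"unknown model kind {doc['model']!r}")


# ---------------------------------------------------------------------------
# configuration

def write_config(config: SynthConfig, path: PathLike) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


def read_config(path: PathLike) -> SynthConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        return config_from_dict(data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
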