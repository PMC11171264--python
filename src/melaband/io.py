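"""Readers and writers for the pipeline's on-disk artifacts.

Cell tables, clinical tables and feature tables are CSV and travel as
:class:`pandas.DataFrame`; slide annotations are GeoJSON backed by shapely
polygons; fitted gates and models are JSON. All readers validate and
reject rather than silently coerce; writers round-trip losslessly at
documented precision (coordinates to 0.01 µm, intensities to 6
significant digits).

Coordinates are in µm with y increasing downward (image convention), so
tumor depth increases with y on a superficial-at-top slide. Breslow
thickness is stored in mm; geometry stays in µm throughout and the
mm conversion happens only at feature assembly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "ki67", "s100")
COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")

#: intensity columns of the detection-table dialect
INTENSITY_COLUMNS = tuple(
    f"{ch}_{cp}_mean" for ch in CHANNELS for cp in COMPARTMENTS
)

#: required columns of a cell table
CELL_COLUMNS = (
    "cell_id",
    "centroid_x_um",
    "centroid_y_um",
    "nucleus_area_um2",
) + INTENSITY_COLUMNS

#: common alternative headers seen in detection-software exports
DEFAULT_COLUMN_MAP = {
    "Object ID": "cell_id",
    "Centroid X µm": "centroid_x_um",
    "Centroid Y µm": "centroid_y_um",
    "Nucleus: Area µm^2": "nucleus_area_um2",
    **{
        f"{ch.upper() if ch != 'dapi' else 'DAPI'}: {cp.capitalize()}: Mean": f"{ch}_{cp}_mean"
        for ch in CHANNELS
        for cp in COMPARTMENTS
    },
}


class FormatError(ValueError):
    """The file does not have the expected structure (e.g. missing column)."""


class ValidationError(ValueError):
    """The file parses but violates a schema invariant."""


@dataclass(frozen=True)
class SlideAnnotation:
    """Manual tumor and epidermis annotation for one slide, in µm."""

    slide_id: str
    tumor: Polygon
    epidermis: Polygon
    pixel_size_um: float = 0.5  # provenance of the upstream scan

    def __post_init__(self) -> None:
        for name, poly in (("tumor", self.tumor), ("epidermis", self.epidermis)):
            if not isinstance(poly, Polygon) or poly.is_empty:
                raise ValidationError(f"{name} polygon is empty or not a polygon")
            if not poly.is_valid:
                raise ValidationError(f"{name} polygon is invalid (self-intersecting?)")
            if poly.area <= 0:
                raise ValidationError(f"{name} polygon has zero area")
        if self.tumor.equals(self.epidermis):
            raise ValidationError("tumor and epidermis polygons coincide")


@dataclass
class CellTable:
    """Validated cell table plus the rows that failed validation."""

    cells: pd.DataFrame
    rejected: pd.DataFrame  # original row, plus a 'reason' column

    def __len__(self) -> int:  # number of valid cells
        return len(self.cells)


def read_cell_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    slide_id: str | None = None,
) -> CellTable:
    """Read a per-cell detection CSV into a validated DataFrame.

    ``column_map`` maps dialect headers onto the canonical names in
    :data:`CELL_COLUMNS`; the common detection-export dialect in
    :data:`DEFAULT_COLUMN_MAP` is always accepted. Rows with negative
    area or intensity are not silently dropped: they are collected into
    ``rejected`` with a reason, and the valid rows are returned.

    Raises
    ------
    FormatError
        If a required column is absent (the message names the column).
    """
    df = pd.read_csv(path)
    rename = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        rename.update(column_map)
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})

    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cell table {path} is missing required column {col!r}")

    numeric = ["centroid_x_um", "centroid_y_um", "nucleus_area_um2", *INTENSITY_COLUMNS]
    df[numeric] = df[numeric].apply(pd.to_numeric, errors="coerce")

    reasons = pd.Series("", index=df.index)
    bad_nan = df[numeric].isna().any(axis=1)
    reasons[bad_nan] = "non-numeric or missing value"
    bad_area = ~bad_nan & (df["nucleus_area_um2"] <= 0)
    reasons[bad_area] = "non-positive nucleus area"
    bad_int = ~bad_nan & ~bad_area & (df[list(INTENSITY_COLUMNS)] < 0).any(axis=1)
    reasons[bad_int] = "negative intensity"

    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    if bad.any():
        logger.warning("%s: rejected %d of %d rows", path, int(bad.sum()), len(df))

    cells = df[~bad].copy()
    cells["cell_id"] = cells["cell_id"].astype(str)
    if slide_id is not None:
        cells["slide_id"] = slide_id
    return CellTable(cells=cells.reset_index(drop=True), rejected=rejected)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table CSV (coordinates at 0.01 µm, intensities 6 s.f.)."""
    out = cells.copy()
    for col in ("centroid_x_um", "centroid_y_um"):
        out[col] = out[col].round(2)
    for col in INTENSITY_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(lambda v: float(f"{v:.6g}"))
    out.to_csv(path, index=False)


def _classification_name(properties: dict) -> str | None:
    cls = properties.get("classification")
    if isinstance(cls, dict):
        return cls.get("name")
    return cls


def read_annotation(path: str | Path, slide_id: str | None = None) -> SlideAnnotation:
    """Read a GeoJSON FeatureCollection with one tumor and one epidermis polygon."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    found: dict[str, Polygon] = {}
    pixel_size = 0.5
    for feat in gj.get("features", []):
        name = (_classification_name(feat.get("properties", {})) or "").lower()
        if name in ("tumor", "epidermis"):
            if name in found:
                raise FormatError(f"{path}: multiple {name!r} features")
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise FormatError(f"{path}: {name!r} feature is not a Polygon")
            found[name] = geom
            pixel_size = feat.get("properties", {}).get("pixel_size_um", pixel_size)
    for name in ("tumor", "epidermis"):
        if name not in found:
            raise FormatError(f"{path}: no feature classified {name!r}")
    sid = slide_id if slide_id is not None else gj.get("slide_id", Path(path).stem)
    return SlideAnnotation(
        slide_id=sid,
        tumor=found["tumor"],
        epidermis=found["epidermis"],
        pixel_size_um=pixel_size,
    )


def write_annotation(annotation: SlideAnnotation, path: str | Path) -> None:
    """Write a slide annotation as GeoJSON (coordinates rounded to 0.01 µm)."""
    features = []
    for name, poly in (("tumor", annotation.tumor), ("epidermis", annotation.epidermis)):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(shapely.set_precision(poly, 0.01)),
                "properties": {
                    "classification": {"name": name},
                    "pixel_size_um": annotation.pixel_size_um,
                },
            }
        )
    gj = {
        "type": "FeatureCollection",
        "slide_id": annotation.slide_id,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


CLINICAL_COLUMNS = ("patient_id", "age", "mitosis", "thickness_mm", "time_months", "event")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the patient clinical table.

    Required columns: patient_id, age (years), mitosis (count per HPF),
    thickness_mm (Breslow), time_months, event (0/1). Optional: endpoint
    (OS | PFS), sex.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: clinical table is empty", stacklevel=2)
        return df
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"clinical table {path} is missing required column {col!r}")
    key = ["patient_id", "endpoint"] if "endpoint" in df.columns else ["patient_id"]
    if df.duplicated(subset=key).any():
        dupes = df.loc[df.duplicated(subset=key), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s): {dupes}")
    if (df["time_months"] < 0).any():
        raise ValidationError("negative survival time")
    if (df["age"] <= 0).any():
        raise ValidationError("non-positive age")
    if (df["thickness_mm"] <= 0).any():
        raise ValidationError("non-positive Breslow thickness")
    df["patient_id"] = df["patient_id"].astype(str)
    df["event"] = df["event"].astype(bool)
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON result artifacts with a provenance block


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, (shapely.Geometry,)):
        return mapping(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_result_json(obj, path: str | Path, *, config=None, seed=None) -> None:
    """Serialize a result object to JSON with a provenance block."""
    from melaband import __version__

    payload = {
        "provenance": {
            "package": "melaband",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "result": _jsonable(obj),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_result_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
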