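"""Reading, validating and writing annotation measurement tables.

Annotation measurements are exported from whole-slide annotation software in
tabular form, lengths in µm and areas in µm².  This module validates such
tables against a closed annotation-class vocabulary (unknown classes are
rejected rather than silently mis-grouped), and can re-derive lengths and
areas from GeoJSON annotation geometry given a µm-per-pixel scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

logger = logging.getLogger(__name__)

#: Closed vocabulary: six outgrowth morphologies, the slice perimeter and the
#: two within-slice tumor-area classes.
ANNOTATION_CLASSES = frozenset(
    {
        "flat",
        "cubic",
        "cylindrical",
        "clear",
        "swollen",
        "necro_apoptotic",
        "perimeter",
        "tumor_viable_area",
        "tumor_damaged_area",
    }
)

REQUIRED_COLUMNS = (
    "culture_id",
    "slice_id",
    "condition",
    "annotation_class",
    "measure_kind",
    "value",
)

_KIND_UNITS = {"length": "um", "perimeter": "um", "area": "um2"}


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class AnnotationValidationError(ValueError):
    """A row violates the annotation contract (class vocabulary, sign, unit)."""


@dataclass(frozen=True)
class ScaleSpec:
    """Conversion from planar coordinate units (pixels) to micrometres."""

    microns_per_unit: float

    def __post_init__(self):
        if not (self.microns_per_unit > 0):
            raise ValueError("microns_per_unit must be strictly positive")


def read_annotation_table(
    path: str | Path,
    *,
    sep: str | None = None,
    drop_missing_values: bool = True,
) -> pd.DataFrame:
    """Read and validate a CSV/TSV annotation measurement table.

    The delimiter is sniffed from the header line unless ``sep`` is given.
    Rows with a missing ``value`` are dropped with a logged count; unknown
    annotation classes or negative values raise.

    Returns the validated table with a ``replicate`` column defaulting to 1
    and a ``unit`` column filled from the measure kind when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    table = pd.read_csv(path, sep=sep)
    return validate_annotation_table(table, drop_missing_values=drop_missing_values)


def validate_annotation_table(
    table: pd.DataFrame, *, drop_missing_values: bool = True
) -> pd.DataFrame:
    """Validate an in-memory annotation table (schema, vocabulary, signs)."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column: {col!r}")
    table = table.copy()
    if "replicate" not in table.columns:
        table["replicate"] = 1

    n_missing = int(table["value"].isna().sum())
    if n_missing:
        if not drop_missing_values:
            raise AnnotationValidationError(f"{n_missing} rows with missing value")
        logger.warning("dropping %d rows with missing value", n_missing)
        table = table[table["value"].notna()]

    unknown = set(table["annotation_class"]) - ANNOTATION_CLASSES
    if unknown:
        raise AnnotationValidationError(
            f"unknown annotation_class values: {sorted(unknown)}"
        )
    bad_kind = set(table["measure_kind"]) - set(_KIND_UNITS)
    if bad_kind:
        raise AnnotationValidationError(f"unknown measure_kind values: {sorted(bad_kind)}")

    negative = table.index[table["value"] < 0]
    if len(negative):
        raise AnnotationValidationError(
            f"negative value at row index {int(negative[0])}"
        )

    expected_unit = table["measure_kind"].map(_KIND_UNITS)
    if "unit" in table.columns:
        mismatch = table.index[table["unit"].notna() & (table["unit"] != expected_unit)]
        if len(mismatch):
            raise AnnotationValidationError(
                f"unit inconsistent with measure_kind at row index {int(mismatch[0])}"
            )
    table["unit"] = expected_unit
    return table.reset_index(drop=True)


def write_readout_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy readout table as CSV with full float precision (17 s.d.)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_readout_table(path: str | Path) -> pd.DataFrame:
    """Read back a tidy readout table with round-trip float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def polyline_length(
    coordinates: Sequence[tuple[float, float]], scale: ScaleSpec
) -> float:
    """Length in µm of an open polyline given in planar coordinate units.

    A single point has length 0.  Raises on an empty coordinate list or
    non-finite coordinates.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.size == 0:
        raise ValueError("polyline needs at least one point")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if len(coords) < 2:
        return 0.0
    return float(LineString(coords).length * scale.microns_per_unit)


def polygon_perimeter_area(
    ring: Sequence[tuple[float, float]], scale: ScaleSpec
) -> tuple[float, float]:
    """Perimeter (µm) and area (µm²) of a polygon ring in planar units.

    The ring is closed implicitly; orientation does not matter.  Needs at
    least three distinct points.
    """
    coords = np.asarray(ring, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    distinct = {tuple(p) for p in coords}
    if len(distinct) < 3:
        raise ValueError("polygon needs at least 3 distinct points")
    poly = Polygon(coords)
    s = scale.microns_per_unit
    return float(poly.exterior.length * s), float(poly.area * s * s)


def read_geojson_annotations(
    path: str | Path,
    scale: ScaleSpec,
    *,
    classification_key: str = "classification",
) -> pd.DataFrame:
    """Derive µm-scale measurements from a GeoJSON FeatureCollection.

    Each feature must carry a classification property (either a bare string
    or a QuPath-style ``{"name": ...}`` object) naming an annotation class.
    LineString geometry yields a length record; Polygon geometry yields a
    perimeter record for the ``perimeter`` class and an area record for area
    classes.  Coordinates are treated as planar pixel units and converted via
    ``scale``.
    """
    path = Path(path)
    fc = json.loads(path.read_text())
    if fc.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    rows = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {}) or {}
        cls = props.get(classification_key)
        if isinstance(cls, dict):
            cls = cls.get("name")
        if cls is None:
            raise AnnotationValidationError(
                f"feature missing classification property {classification_key!r}"
            )
        if cls not in ANNOTATION_CLASSES:
            raise AnnotationValidationError(f"unknown annotation_class: {cls!r}")
        geom = feat.get("geometry", {})
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "LineString":
            value, kind = polyline_length(coords, scale), "length"
        elif gtype == "Polygon":
            perim, area = polygon_perimeter_area(coords[0], scale)
            if cls == "perimeter":
                value, kind = perim, "perimeter"
            else:
                value, kind = area, "area"
        else:
            raise AnnotationValidationError(f"unsupported geometry type: {gtype!r}")
        rows.append(
            {
                "culture_id": props.get("culture_id", ""),
                "slice_id": props.get("slice_id", ""),
                "replicate": props.get("replicate", 1),
                "condition": props.get("condition", ""),
                "annotation_class": cls,
                "measure_kind": kind,
                "value": value,
                "unit": _KIND_UNITS[kind],
            }
        )
    return pd.DataFrame(rows)
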