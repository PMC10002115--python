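"""Raster and vector I/O.

Rasters travel as single-band GeoTIFFs: continuous layers as float32 with NaN
nodata, categorical layers as unsigned integers with a reserved nodata code.
Grid geometry goes into the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint), the nodata value into the GDAL_NODATA tag, and the CRS tag and
categorical legend into GDAL_METADATA.  Files written here are readable by any
GDAL-based tool; reading requires the geometry tags and a CRS entry to be
present.

Vector data (disaster inventories, river/fault polylines) travel as GeoJSON;
inventories may alternatively be CSV with columns ``x, y[, type]``.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LineString, Point, mapping, shape

from .grid import CategoricalRaster, GridSpec, Raster

__all__ = [
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "read_polylines",
    "write_polylines",
]

# TIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_METADATA = 42112
_GDAL_NODATA = 42113

_CAT_NODATA = 255  # reserved code for masked cells in categorical files


def _gdal_metadata_xml(items: dict[str, str]) -> str:
    root = ET.Element("GDALMetadata")
    for name, value in items.items():
        item = ET.SubElement(root, "Item", name=name)
        item.text = value
    return ET.tostring(root, encoding="unicode")


def _parse_gdal_metadata(text: str) -> dict[str, str]:
    try:
        root = ET.fromstring(text)
    except ET.ParseError:
        return {}
    return {item.get("name", ""): (item.text or "") for item in root.iter("Item")}


def write_raster(raster: Raster | CategoricalRaster, path: str | Path) -> Path:
    """Write a raster to a single-band GeoTIFF.

    Continuous rasters are stored as float32 with NaN at masked cells;
    categorical rasters as uint8 with code 255 at masked cells.
    """
    path = Path(path)
    g = raster.grid
    meta: dict[str, str] = {"crs_tag": g.crs_tag}
    if isinstance(raster, CategoricalRaster):
        if any(int(c) >= _CAT_NODATA or int(c) < 0 for c in raster.legend):
            raise ValueError(f"categorical codes must lie in [0, {_CAT_NODATA})")
        data = raster.codes.astype(np.uint8).copy()
        data[raster.nodata_mask] = _CAT_NODATA
        nodata = str(_CAT_NODATA)
        meta["legend"] = json.dumps({str(k): v for k, v in raster.legend.items()})
    else:
        data = raster.values.astype(np.float32).copy()
        data[raster.nodata_mask] = np.nan
        nodata = "nan"

    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(g.cell_size), float(g.cell_size), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(g.origin_x), float(g.origin_y), 0.0)),
        # minimal GeoKeyDirectory declaring a projected model type
        (_GEO_KEY_DIRECTORY, "H", 8, (1, 1, 0, 1, 1024, 0, 1, 1)),
        (_GDAL_METADATA, "s", 0, _gdal_metadata_xml(meta)),
        (_GDAL_NODATA, "s", 0, nodata),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    return path


def read_raster(path: str | Path) -> Raster | CategoricalRaster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or compatible).

    Returns a :class:`CategoricalRaster` when the file carries a legend,
    otherwise a :class:`Raster`.  Raises if the file lacks geometry tags or a
    CRS entry.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}

    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF geometry tags (not georeferenced)")
    meta = _parse_gdal_metadata(tags.get(_GDAL_METADATA, ""))
    if "crs_tag" not in meta or not meta["crs_tag"]:
        raise ValueError(f"{path}: no CRS recorded in the file")

    scale = tags[_MODEL_PIXEL_SCALE]
    tiepoint = tags[_MODEL_TIEPOINT]
    grid = GridSpec(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size=float(scale[0]),
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        crs_tag=meta["crs_tag"],
    )

    nodata_text = tags.get(_GDAL_NODATA, "nan")
    if "legend" in meta:
        legend = {int(k): v for k, v in json.loads(meta["legend"]).items()}
        nodata_code = int(float(nodata_text))
        mask = data == nodata_code
        codes = data.astype(np.int64)
        codes[mask] = min(legend) if legend else 0
        return CategoricalRaster(grid, codes, legend, mask)

    values = data.astype(np.float64)
    if nodata_text.strip().lower() == "nan":
        mask = np.isnan(values)
    else:
        nodata_val = float(nodata_text)
        mask = values == nodata_val
    values = values.copy()
    values[mask] = np.nan
    return Raster(grid, values, mask)


# ---------------------------------------------------------------------------
# vector I/O


def write_points(
    points: Sequence[tuple[float, float]] | np.ndarray,
    path: str | Path,
    types: Sequence[str] | None = None,
    properties: dict | None = None,
) -> Path:
    """Write point features to GeoJSON (or CSV when the suffix is .csv)."""
    path = Path(path)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
        if types is not None:
            df["type"] = list(types)
        df.to_csv(path, index=False)
        return path
    features = []
    for i, (x, y) in enumerate(pts):
        props = {} if types is None else {"type": types[i]}
        features.append(
            {"type": "Feature", "geometry": mapping(Point(x, y)), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    if properties:
        doc["properties"] = properties
    path.write_text(json.dumps(doc))
    return path


def read_points(path: str | Path) -> tuple[np.ndarray, list[str | None]]:
    """Read an inventory of points from GeoJSON or CSV.

    Returns (coords n x 2, type labels) with ``None`` where no label exists.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            raise ValueError(f"{path}: CSV inventory needs columns x, y")
        types = list(df["type"]) if "type" in df.columns else [None] * len(df)
        return df[["x", "y"]].to_numpy(float), types
    doc = json.loads(path.read_text())
    coords, types = [], []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Point":
            raise ValueError(f"{path}: inventory features must be Points, got {geom.geom_type}")
        coords.append((geom.x, geom.y))
        types.append((feat.get("properties") or {}).get("type"))
    return np.asarray(coords, float).reshape(-1, 2), types


def write_polylines(lines: Iterable[LineString], path: str | Path) -> Path:
    features = [
        {"type": "Feature", "geometry": mapping(line), "properties": {}} for line in lines
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return Path(path)


def read_polylines(path: str | Path) -> list[LineString]:
    doc = json.loads(Path(path).read_text())
    lines = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(geom.geoms)
        else:
            raise ValueError(f"{path}: expected LineString features, got {geom.geom_type}")
    return lines
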