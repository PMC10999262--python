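"""Readers and writers for the five input formats and all indicator outputs.

Input tables are delimited text with Darwin Core–style headers (GRIIS
checklist exports, first-record tables, GBIF-style occurrence downloads,
EICAT assessment tables); regions are GeoJSON; per-species climatic
suitability surfaces are single-band georeferenced TIFFs.

Design rules applied throughout:

* **Collect-and-report.** Rows violating a row-level invariant are rejected
  into an error report (``errors`` DataFrame with columns ``row``, ``code``,
  ``detail``) rather than aborting the run or being silently dropped.
  Structural problems (missing mapped column, unparseable file, unknown
  controlled-vocabulary token in EICAT) raise typed errors instead.
* **Fixed CRS.** Everything is WGS84 longitude/latitude; no reprojection.
* ``row`` in error reports is the 1-based line number in the source file
  (the header is line 1), so reports can be matched to the raw file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.validation import make_valid

from .errors import (
    AlignmentError,
    FormatError,
    RegionError,
    SchemaError,
    ValidationError,
    VocabularyError,
)
from .grid import GridTransform

__all__ = [
    "MAGNITUDES",
    "MAGNITUDE_RANK",
    "MECHANISMS",
    "Dialect",
    "ReadResult",
    "RegionSet",
    "SuitabilitySurface",
    "read_checklist",
    "read_eicat",
    "read_first_records",
    "read_occurrences",
    "read_regions",
    "write_regions",
    "read_grid",
    "write_grid",
    "read_surface",
    "write_surface",
    "read_table",
    "write_table",
]

#: EICAT impact magnitude categories, minimal concern -> massive.
MAGNITUDES = ("MC", "MN", "MO", "MR", "MV")
MAGNITUDE_RANK = {m: i for i, m in enumerate(MAGNITUDES)}

#: Canonical impact-mechanism vocabulary. The mechanism set is open in
#: principle (EICAT defines twelve); these are the ones exercised by the
#: amphibian-style synthetic world. Unknown mechanism tokens are accepted
#: by the reader (the vocabulary constrains magnitudes, not mechanisms).
MECHANISMS = (
    "predation",
    "disease_transmission",
    "competition",
    "hybridization",
    "parasitism",
    "poisoning",
    "interaction_with_other_invasive_species",
)

# GeoTIFF tag codes used for georeferencing single-band surfaces.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from a file's header to canonical field names.

    Defaults follow Darwin Core terms as used by GRIIS and GBIF exports.
    ``occurrence_status`` and ``record_id`` columns are optional in the
    source file; every other mapped column must exist.
    """

    taxon: str = "scientificName"
    region: str = "locationID"
    establishment_means: str = "establishmentMeans"
    is_invasive: str = "isInvasive"
    occurrence_status: str = "occurrenceStatus"
    latitude: str = "decimalLatitude"
    longitude: str = "decimalLongitude"
    event_date: str = "eventDate"
    year: str = "year"
    record_id: str = "occurrenceID"
    mechanism: str = "mechanism"
    magnitude: str = "magnitude"
    delimiter: str = ","

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str] | None) -> "Dialect":
        return cls(**dict(mapping)) if mapping else cls()


@dataclass
class ReadResult:
    """Validated records plus the report of rejected/flagged rows."""

    records: pd.DataFrame
    errors: pd.DataFrame

    def __iter__(self):  # allow tuple unpacking
        yield self.records
        yield self.errors


def _empty_errors() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "code", "detail"]).astype(
        {"row": "int64", "code": "string", "detail": "string"}
    )


def _errors_frame(entries: list[tuple[int, str, str]]) -> pd.DataFrame:
    if not entries:
        return _empty_errors()
    return pd.DataFrame(entries, columns=["row", "code", "detail"]).astype(
        {"row": "int64", "code": "string", "detail": "string"}
    )


def _read_delimited(path, delimiter: str) -> pd.DataFrame:
    """Total CSV read: structural failures become :class:`FormatError`."""
    try:
        df = pd.read_csv(
            path, sep=delimiter, dtype=str, keep_default_na=False, engine="python"
        )
    except (OSError, UnicodeError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse {path!s}: {e}") from e
    df.index = df.index + 2  # 1-based file line numbers; header is line 1
    return df


def _require_columns(df: pd.DataFrame, required: dict[str, str], path) -> None:
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{path!s}: missing mapped column(s) {missing}; header has {list(df.columns)}"
        )


_TRUE_TOKENS = {"true", "1", "yes", "invasive", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f", "null", "none", ""}


def _parse_invasive(token: str) -> bool | None:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    return None


def read_checklist(path, dialect: Dialect | Mapping[str, str] | None = None) -> ReadResult:
    """Read a GRIIS-style regional checklist.

    Returns one validated entry per (taxon, region) with columns
    ``taxon, region_id, occurrence_status, establishment_means, is_invasive``.

    Row-level rejections (collected in the error report, never silent):

    ``empty_field``
        taxon or region id blank.
    ``occurrence_status``
        status other than "present" (absent/doubtful listings are reported,
        not counted — only present listings enter the indicators).
    ``establishment_means``
        value outside {introduced, uncertain}; native listings land here.
    ``invasive_flag``
        unparseable impact-evidence flag, or is_invasive=true on a listing
        whose establishment means is not "introduced".
    ``duplicate_row``
        exact repeat of an earlier (taxon, region) listing.
    ``conflict``
        same (taxon, region) listed with contradictory invasive flags; all
        rows of the conflicting key are rejected and the report names them.
    """
    dialect = dialect if isinstance(dialect, Dialect) else Dialect.from_mapping(dialect)
    df = _read_delimited(path, dialect.delimiter)
    _require_columns(
        df,
        {
            "taxon": dialect.taxon,
            "region": dialect.region,
            "establishment_means": dialect.establishment_means,
            "is_invasive": dialect.is_invasive,
        },
        path,
    )

    errors: list[tuple[int, str, str]] = []
    rows = []
    for line, raw in df.iterrows():
        taxon = raw[dialect.taxon].strip()
        region = raw[dialect.region].strip()
        if not taxon or not region:
            errors.append((line, "empty_field", "blank taxon or region id"))
            continue
        status = (
            raw[dialect.occurrence_status].strip().lower()
            if dialect.occurrence_status in df.columns
            else "present"
        ) or "present"
        if status != "present":
            errors.append((line, "occurrence_status", f"status {status!r} not 'present'"))
            continue
        means = raw[dialect.establishment_means].strip().lower()
        if means not in ("introduced", "uncertain"):
            errors.append((line, "establishment_means", f"unsupported value {means!r}"))
            continue
        inv = _parse_invasive(raw[dialect.is_invasive])
        if inv is None:
            errors.append(
                (line, "invasive_flag", f"unparseable flag {raw[dialect.is_invasive]!r}")
            )
            continue
        if inv and means != "introduced":
            errors.append(
                (line, "invasive_flag", "is_invasive=true requires establishmentMeans=introduced")
            )
            continue
        rows.append((line, taxon, region, status, means, inv))

    rec = pd.DataFrame(
        rows,
        columns=["_line", "taxon", "region_id", "occurrence_status", "establishment_means", "is_invasive"],
    )

    # Enforce (taxon, region) uniqueness: identical repeats keep the first,
    # contradictory invasive flags reject the whole key.
    keep = np.ones(len(rec), dtype=bool)
    if len(rec):
        for (_, _), grp in rec.groupby(["taxon", "region_id"], sort=False):
            if len(grp) == 1:
                continue
            lines = grp["_line"].tolist()
            if grp["is_invasive"].nunique() > 1:
                keep[rec.index.isin(grp.index)] = False
                for line in lines:
                    errors.append(
                        (line, "conflict", f"conflicting is_invasive flags on lines {lines}")
                    )
            else:
                for idx, line in zip(grp.index[1:], lines[1:]):
                    keep[rec.index.get_loc(idx)] = False
                    errors.append((line, "duplicate_row", f"repeat of line {lines[0]}"))

    rec = rec.loc[keep].drop(columns="_line").reset_index(drop=True)
    return ReadResult(rec, _errors_frame(sorted(errors)))


def read_eicat(path, dialect: Dialect | Mapping[str, str] | None = None) -> ReadResult:
    """Read global EICAT assessments (taxon, mechanism, magnitude).

    Duplicate (taxon, mechanism) pairs are collapsed to the **maximum**
    magnitude under the EICAT order MC < MN < MO < MR < MV; collapsed rows
    are noted in the report (code ``collapsed``). A magnitude token outside
    the five-level vocabulary raises :class:`VocabularyError` — it signals
    a mis-mapped file rather than one messy row.
    """
    dialect = dialect if isinstance(dialect, Dialect) else Dialect.from_mapping(dialect)
    df = _read_delimited(path, dialect.delimiter)
    _require_columns(
        df,
        {"taxon": dialect.taxon, "mechanism": dialect.mechanism, "magnitude": dialect.magnitude},
        path,
    )

    errors: list[tuple[int, str, str]] = []
    rows = []
    for line, raw in df.iterrows():
        taxon = raw[dialect.taxon].strip()
        mech = raw[dialect.mechanism].strip().lower().replace(" ", "_")
        mag = raw[dialect.magnitude].strip().upper()
        if not taxon or not mech:
            errors.append((line, "empty_field", "blank taxon or mechanism"))
            continue
        if mag not in MAGNITUDE_RANK:
            raise VocabularyError(
                f"{path!s} line {line}: unknown EICAT magnitude {mag!r}; expected one of {MAGNITUDES}"
            )
        rows.append((line, taxon, mech, mag))

    rec = pd.DataFrame(rows, columns=["_line", "taxon", "mechanism", "magnitude"])
    if len(rec):
        rec["_rank"] = rec["magnitude"].map(MAGNITUDE_RANK)
        rec = rec.sort_values(["_rank", "_line"], ascending=[False, True], kind="stable")
        dup = rec.duplicated(subset=["taxon", "mechanism"], keep="first")
        for line in rec.loc[dup, "_line"]:
            errors.append((line, "collapsed", "duplicate (taxon, mechanism); kept max magnitude"))
        rec = (
            rec.loc[~dup]
            .sort_values("_line")
            .drop(columns=["_line", "_rank"])
            .reset_index(drop=True)
        )
    else:
        rec = rec.drop(columns="_line")
    return ReadResult(rec, _errors_frame(sorted(errors)))


def read_first_records(
    path,
    dialect: Dialect | Mapping[str, str] | None = None,
    year_window: tuple[int, int] = (1500, 2030),
) -> ReadResult:
    """Read first-introduction records (taxon, region, single year).

    Years outside the plausibility window are rejected (code ``year``);
    duplicate (taxon, region) keys keep the earliest year (code
    ``duplicate_row`` on later ones) so the table satisfies the one-year-
    per-key invariant downstream trend code relies on.
    """
    dialect = dialect if isinstance(dialect, Dialect) else Dialect.from_mapping(dialect)
    df = _read_delimited(path, dialect.delimiter)
    _require_columns(
        df, {"taxon": dialect.taxon, "region": dialect.region, "year": dialect.year}, path
    )

    lo, hi = year_window
    errors: list[tuple[int, str, str]] = []
    rows = []
    for line, raw in df.iterrows():
        taxon = raw[dialect.taxon].strip()
        region = raw[dialect.region].strip()
        if not taxon or not region:
            errors.append((line, "empty_field", "blank taxon or region id"))
            continue
        try:
            year = int(float(raw[dialect.year]))
        except (TypeError, ValueError):
            errors.append((line, "year", f"unparseable year {raw[dialect.year]!r}"))
            continue
        if not lo <= year <= hi:
            errors.append((line, "year", f"year {year} outside window [{lo}, {hi}]"))
            continue
        rows.append((line, taxon, region, year))

    rec = pd.DataFrame(rows, columns=["_line", "taxon", "region_id", "year"])
    if len(rec):
        rec = rec.sort_values(["year", "_line"], kind="stable")
        dup = rec.duplicated(subset=["taxon", "region_id"], keep="first")
        for line in rec.loc[dup, "_line"]:
            errors.append((line, "duplicate_row", "duplicate (taxon, region); kept earliest year"))
        rec = (
            rec.loc[~dup].sort_values("_line").drop(columns="_line").reset_index(drop=True)
        )
    else:
        rec = rec.drop(columns="_line")
    rec["year"] = rec.get("year", pd.Series(dtype="int64")).astype("int64")
    return ReadResult(rec, _errors_frame(sorted(errors)))


def read_occurrences(path, dialect: Dialect | Mapping[str, str] | None = None) -> ReadResult:
    """Read Darwin Core–style occurrence records.

    Coordinates are parsed as decimal degrees. Records with unparseable or
    out-of-bounds coordinates, or a blank taxon, are kept in the table but
    flagged ``usable=False`` with a reason (and mirrored into the error
    report); the run continues. The verbatim event date is retained for the
    harmonization step, which reduces it to a single year.
    """
    dialect = dialect if isinstance(dialect, Dialect) else Dialect.from_mapping(dialect)
    df = _read_delimited(path, dialect.delimiter)
    _require_columns(
        df,
        {
            "taxon": dialect.taxon,
            "latitude": dialect.latitude,
            "longitude": dialect.longitude,
            "event_date": dialect.event_date,
        },
        path,
    )

    errors: list[tuple[int, str, str]] = []
    rows = []
    has_id = dialect.record_id in df.columns
    for line, raw in df.iterrows():
        rid = raw[dialect.record_id].strip() if has_id else ""
        rid = rid or f"r{line}"
        taxon = raw[dialect.taxon].strip()
        lat_s, lon_s = raw[dialect.latitude].strip(), raw[dialect.longitude].strip()
        date = raw[dialect.event_date].strip()
        reason = ""
        lat = lon = math.nan
        if not taxon:
            reason = "blank taxon"
        else:
            try:
                lat, lon = float(lat_s), float(lon_s)
            except ValueError:
                reason = f"unparseable coordinates ({lat_s!r}, {lon_s!r})"
            else:
                if not (math.isfinite(lat) and math.isfinite(lon)):
                    reason = "non-finite coordinates"
                elif not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                    reason = f"coordinates out of bounds ({lat}, {lon})"
        usable = reason == ""
        if not usable:
            errors.append((line, "unusable", reason))
        rows.append((rid, taxon, lat, lon, date, usable, reason))

    rec = pd.DataFrame(
        rows,
        columns=["record_id", "taxon", "lat", "lon", "event_date", "usable", "reason"],
    )
    return ReadResult(rec, _errors_frame(sorted(errors)))


# ---------------------------------------------------------------------------
# Regions (GeoJSON)
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Mapping of region id -> shapely (multi)polygon, WGS84 lon/lat."""

    geometries: dict[str, shapely.Geometry] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.geometries)

    def __len__(self) -> int:
        return len(self.geometries)

    def __getitem__(self, region_id: str) -> shapely.Geometry:
        return self.geometries[region_id]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.geometries

    def items(self):
        return self.geometries.items()


def read_regions(path, id_property: str = "region_id") -> tuple[RegionSet, pd.DataFrame]:
    """Read region polygons from a GeoJSON FeatureCollection.

    Each feature must carry an ``id_property`` property. Invalid geometries
    are repaired structurally (preserving the full vertex span, e.g. both
    lobes of a self-intersecting "bowtie"); a geometry that stays invalid
    (or repairs to an empty set) is rejected into the report. Duplicate
    region ids raise :class:`RegionError` listing the offending features.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
    except (OSError, UnicodeError, json.JSONDecodeError) as e:
        raise FormatError(f"cannot parse {path!s} as GeoJSON: {e}") from e
    if not isinstance(gj, dict) or gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path!s}: expected a GeoJSON FeatureCollection")

    errors: list[tuple[int, str, str]] = []
    geoms: dict[str, shapely.Geometry] = {}
    seen_at: dict[str, int] = {}
    dups: dict[str, list[int]] = {}
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        rid = props.get(id_property)
        if rid is None or str(rid).strip() == "":
            errors.append((i, "missing_id", f"feature {i} lacks property {id_property!r}"))
            continue
        rid = str(rid)
        if rid in seen_at:
            dups.setdefault(rid, [seen_at[rid]]).append(i)
            continue
        try:
            geom = geom_shape(feat["geometry"])
        except (KeyError, TypeError, ValueError, AttributeError) as e:
            errors.append((i, "bad_geometry", f"feature {i}: {e}"))
            continue
        if not geom.is_valid:
            # make_valid keeps every lobe of self-intersecting figures,
            # where zero-width buffering can drop half the area
            geom = make_valid(geom)
            if geom.geom_type == "GeometryCollection":
                polys = [g for g in geom.geoms
                         if g.geom_type in ("Polygon", "MultiPolygon")]
                geom = shapely.union_all(polys) if polys else geom
        if not geom.is_valid or geom.is_empty:
            errors.append((i, "bad_geometry", f"feature {i}: irreparable geometry"))
            continue
        seen_at[rid] = i
        geoms[rid] = geom
    if dups:
        raise RegionError(
            "duplicate region ids: "
            + "; ".join(f"{rid!r} in features {ix}" for rid, ix in sorted(dups.items()))
        )
    return RegionSet(geoms), _errors_frame(errors)


def write_regions(regions: RegionSet, path, id_property: str = "region_id") -> None:
    """Write a RegionSet as a GeoJSON FeatureCollection (RFC 7946)."""
    features = [
        {
            "type": "Feature",
            "properties": {id_property: rid},
            "geometry": geom_mapping(geom),
        }
        for rid, geom in regions.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Suitability surfaces (single-band georeferenced TIFF)
# ---------------------------------------------------------------------------


@dataclass
class SuitabilitySurface:
    """Per-species relative likelihood of occurrence on a lon/lat grid.

    Values are in [0, 1]; ``nodata`` cells (sentinel -1) mark areas with no
    prediction. Being *relative* likelihoods (max-rescaled per species),
    magnitudes are not comparable across species beyond the [0, 1] scale.
    """

    taxon: str
    grid: np.ndarray
    transform: GridTransform
    nodata: float = -1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValidationError("surface grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def data_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def validate(self, tol: float = 1e-6) -> None:
        """Raise :class:`ValidationError` if any data value leaves [0, 1]
        by more than ``tol``. Values are never silently clamped."""
        vals = self.grid[self.data_mask()]
        if vals.size and (vals.min() < -tol or vals.max() > 1 + tol):
            raise ValidationError(
                f"surface {self.taxon!r}: values outside [0, 1] "
                f"(min {vals.min():.6g}, max {vals.max():.6g})"
            )

    def copy_with(self, grid: np.ndarray) -> "SuitabilitySurface":
        return replace(self, grid=np.asarray(grid, dtype=np.float64))


def write_grid(grid: np.ndarray, transform: GridTransform, path,
               meta: dict | None = None, nodata: float = -1.0) -> None:
    """Write any 2-D grid as a single-band float64 TIFF with GeoTIFF
    georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL nodata) and
    ``meta`` embedded as a JSON ImageDescription tag."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise ValidationError(f"expected a 2-D grid, got shape {grid.shape}")
    payload = {"nodata": nodata}
    payload.update(meta or {})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (transform.xres, transform.yres, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.west, transform.north, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, grid, extratags=extratags, description=json.dumps(payload))


def read_grid(path) -> tuple[np.ndarray, GridTransform, dict]:
    """Read a single-band georeferenced TIFF; returns (grid, transform,
    metadata dict). Works for files from :func:`write_grid` or any tool
    emitting ModelPixelScale/ModelTiepoint tags."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            grid = page.asarray()
            tags = page.tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
            nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else -1.0
            desc = {}
            if page.description:
                try:
                    desc = json.loads(page.description)
                except json.JSONDecodeError:
                    desc = {}
    except (OSError, KeyError, IndexError, tifffile.TiffFileError) as e:
        raise FormatError(f"cannot read {path!s} as a georeferenced TIFF: {e}") from e
    if grid.ndim != 2:
        raise FormatError(f"{path!s}: expected a single-band raster, got shape {grid.shape}")
    transform = GridTransform(
        west=float(tiepoint[3]), north=float(tiepoint[4]),
        xres=float(scale[0]), yres=float(scale[1]),
    )
    desc.setdefault("nodata", nodata)
    return np.asarray(grid, dtype=np.float64), transform, desc


def write_surface(surface: SuitabilitySurface, path, description: dict | None = None) -> None:
    """Write a suitability surface (validated to [0, 1]) as a georeferenced
    TIFF; the taxon (plus any extra ``description`` entries, e.g. a subset
    descriptor) rides along in the JSON ImageDescription tag."""
    surface.validate()
    meta = {"taxon": surface.taxon}
    if description:
        meta.update(description)
    write_grid(surface.grid, surface.transform, path, meta=meta, nodata=surface.nodata)


def read_surface(path) -> SuitabilitySurface:
    """Read a suitability surface written by :func:`write_surface` (or any
    single-band georeferenced TIFF with values in [0, 1])."""
    grid, transform, desc = read_grid(path)
    surface = SuitabilitySurface(
        taxon=str(desc.get("taxon", "")),
        grid=grid,
        transform=transform,
        nodata=float(desc.get("nodata", -1.0)),
    )
    surface.validate()
    return surface


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

#: Fixed output schemas (documented in the README).
TABLE_SCHEMAS = {
    "trend": ["subset", "mode", "year", "cumulative_count"],
    "region_counts": ["region_id", "mode", "count"],
    "info_status": ["region_id", "In", "Im", "Rd", "composite", "burden", "flags"],
    "change_log": ["verbatim", "canonical", "count", "status"],
}


def write_table(df: pd.DataFrame, path, schema: str | None = None, delimiter: str = ",") -> None:
    """Write an output table; if ``schema`` is given, enforce and order its
    fixed header so outputs are stable across runs."""
    if schema is not None:
        cols = TABLE_SCHEMAS[schema]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"table missing columns {missing} for schema {schema!r}")
        df = df[cols]
    df.to_csv(path, sep=delimiter, index=False)


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read back an output table (round-trip counterpart of write_table)."""
    try:
        return pd.read_csv(path, sep=delimiter)
    except (OSError, UnicodeError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse {path!s}: {e}") from e


def check_aligned(transforms: Iterable[GridTransform], shapes: Iterable[tuple[int, int]],
                  names: Iterable[str] = ()) -> None:
    """Raise :class:`AlignmentError` unless all transforms/shapes agree."""
    transforms, shapes = list(transforms), list(shapes)
    names = list(names) or [str(i) for i in range(len(transforms))]
    if not transforms:
        return
    ref_t, ref_s = transforms[0], shapes[0]
    for t, s, n in zip(transforms, shapes, names):
        if s != ref_s or not t.approx_equal(ref_t):
            raise AlignmentError(
                f"grid {n!r} misaligned: shape {s} vs {ref_s}, transform {t} vs {ref_t}"
            )
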