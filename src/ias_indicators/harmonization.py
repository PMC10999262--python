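"""Data-integration steps applied before any indicator is computed.

Aggregated invasion data arrive under divergent taxonomies, date formats
and duplicated sampling events. Four operations bring them onto one
footing: taxon names are mapped to canonical forms through a synonym
table (a stand-in for full backbone-taxonomy matching, which is out of
scope), event dates are reduced to single calendar years, exact duplicate
occurrence records are removed, and occurrence points are assigned to
regions by cell-free point-in-polygon tests.

All operations are deterministic and idempotent where the contract says
so; boundary points are tie-broken by lexicographic region id so repeated
runs produce byte-identical outputs.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .errors import ValidationError
from .formats_io import RegionSet

__all__ = [
    "SynonymTable",
    "load_synonyms",
    "canonicalize_names",
    "extract_year",
    "add_event_years",
    "dedup_occurrences",
    "assign_region",
]


class SynonymTable:
    """Verbatim -> canonical name mapping with fixed-point canonicals.

    Canonical names map to themselves (explicitly or implicitly); chains
    and cycles are rejected at construction, so applying the table twice
    equals applying it once.
    """

    def __init__(self, mapping: Mapping[str, str]):
        mapping = {str(k).strip(): str(v).strip() for k, v in mapping.items()}
        for verbatim, canonical in mapping.items():
            target = mapping.get(canonical, canonical)
            if target != canonical:
                raise ValidationError(
                    f"synonym table is not fixed-point: {verbatim!r} -> {canonical!r} -> {target!r}"
                )
        self._map = mapping

    def canonical(self, name: str) -> str:
        return self._map.get(name, name)

    def __contains__(self, name: str) -> bool:
        return name in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def load_synonyms(path, delimiter: str = ",") -> SynonymTable:
    """Load a two-column (verbatim, canonical) delimited file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"{path!s}: synonym table needs two columns")
    return SynonymTable(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def canonicalize_names(
    records: pd.DataFrame, synonyms: SynonymTable, taxon_col: str = "taxon"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substitute canonical taxon names in any taxon-bearing table.

    Returns the substituted table (a copy) and a change log with columns
    ``verbatim, canonical, count, status`` where status is ``mapped`` for a
    substitution, ``fixed_point`` for names the table maps to themselves,
    and ``unmatched`` for names absent from the table (passed through
    unchanged, preserving auditability).
    """
    out = records.copy()
    names = out[taxon_col].astype(str)
    canonical = names.map(synonyms.canonical)
    out[taxon_col] = canonical

    log_rows = []
    for verbatim, grp in names.groupby(names, sort=True):
        canon = synonyms.canonical(verbatim)
        if verbatim not in synonyms:
            status = "unmatched"
        elif canon == verbatim:
            status = "fixed_point"
        else:
            status = "mapped"
        log_rows.append((verbatim, canon, len(grp), status))
    log = pd.DataFrame(log_rows, columns=["verbatim", "canonical", "count", "status"])
    return out, log


_ISO_DATE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")
_BARE_YEAR = re.compile(r"^(\d{4})$")


def _parse_single(token: str, window: tuple[int, int]) -> int | None:
    token = token.strip()
    m = _ISO_DATE.match(token)
    if not m:
        # ISO datetime like 1987-05-03T12:00:00Z
        m = _ISO_DATE.match(token.split("T")[0]) if "T" in token else None
    if not m:
        return None
    year = int(m.group(1))
    month, day = m.group(2), m.group(3)
    if month is not None and not 1 <= int(month) <= 12:
        return None
    if day is not None and not 1 <= int(day) <= 31:
        return None
    lo, hi = window
    return year if lo <= year <= hi else None


def extract_year(event_date, window: tuple[int, int] = (1500, 2030)) -> int | None:
    """Reduce a verbatim event date to a single calendar year.

    Accepts ISO 8601 dates and datetimes (``1987-05-03``, ``1987-05``,
    ``1987-05-03T10:00Z``), bare years (``1987``), and ranges joined by
    ``/`` (``1970/1975``, ``1970-01-01/1975-12-31``) from which the
    **earliest** year is taken. Anything else — including years outside the
    plausibility window — returns ``None`` (unusable). Total function:
    never raises, whatever the input.
    """
    if event_date is None:
        return None
    try:
        text = str(event_date).strip()
    except Exception:
        return None
    if not text:
        return None
    # A 4-digit-slash-4-digit or ISO/ISO range: earliest valid side wins.
    if "/" in text:
        years = [
            y for part in text.split("/") if (y := _parse_single(part, window)) is not None
        ]
        return min(years) if years else None
    return _parse_single(text, window)


def add_event_years(
    occurrences: pd.DataFrame, window: tuple[int, int] = (1500, 2030)
) -> pd.DataFrame:
    """Attach ``event_year`` (nullable int) to an occurrence table and
    flag records without an extractable year as unusable."""
    out = occurrences.copy()
    years = out["event_date"].map(lambda d: extract_year(d, window))
    out["event_year"] = pd.array(years, dtype="Int64")
    no_year = out["event_year"].isna() & out["usable"]
    out.loc[no_year, "usable"] = False
    out.loc[no_year, "reason"] = "no extractable event year"
    return out


def dedup_occurrences(
    occurrences: pd.DataFrame, date_granularity: str = "year"
) -> tuple[pd.DataFrame, int]:
    """Drop exact duplicate occurrence records.

    One record is kept (first in current order) per key
    ``(taxon, lat, lon, date)`` where *date* is the extracted year
    (``date_granularity="year"``, default) or the verbatim date string
    (``"date"``). Coordinates compare by exact float equality — no
    rounding. Unusable records pass through untouched and never collide
    with usable ones. Returns the deduplicated table and the removed count.
    Idempotent: a second pass removes nothing.
    """
    if date_granularity == "year":
        if "event_year" not in occurrences.columns:
            raise ValidationError("run add_event_years before dedup (year granularity)")
        key_date = occurrences["event_year"]
    elif date_granularity == "date":
        key_date = occurrences["event_date"]
    else:
        raise ValidationError(f"unknown date_granularity {date_granularity!r}")

    usable = occurrences["usable"].to_numpy(dtype=bool)
    key = pd.DataFrame(
        {
            "taxon": occurrences["taxon"],
            "lat": occurrences["lat"],
            "lon": occurrences["lon"],
            "date": key_date,
        }
    )
    dup = key.duplicated(keep="first").to_numpy() & usable
    out = occurrences.loc[~dup].reset_index(drop=True)
    return out, int(dup.sum())


def assign_region(occurrences: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Fill ``region_id`` by point-in-polygon containment (boundary
    inclusive).

    A point on a shared boundary is assigned to the region with the
    lexicographically smallest id — the tie-break that makes assignment
    deterministic and permutation-invariant. Points inside no region get
    a null id (they are excluded from the range-dynamics sub-indicator).
    Unusable records keep a null id.
    """
    out = occurrences.copy()
    region_ids = np.array(sorted(regions.ids))
    out["region_id"] = pd.array([None] * len(out), dtype="string")
    if not len(out) or not len(region_ids):
        return out

    usable = out["usable"].to_numpy(dtype=bool)
    idx = np.flatnonzero(usable)
    if not idx.size:
        return out
    pts = [Point(lon, lat) for lon, lat in zip(out["lon"].iloc[idx], out["lat"].iloc[idx])]
    geoms = [regions[rid] for rid in region_ids]
    tree = STRtree(geoms)
    # 'covered_by' includes boundary points, unlike 'within'.
    pt_i, geom_i = tree.query(np.array(pts, dtype=object), predicate="covered_by")
    assigned: dict[int, str] = {}
    for p, g in zip(pt_i, geom_i):
        rid = region_ids[g]
        if p not in assigned or rid < assigned[p]:
            assigned[p] = rid
    col = out.columns.get_loc("region_id")
    for p, rid in assigned.items():
        out.iat[idx[p], col] = rid
    return out
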