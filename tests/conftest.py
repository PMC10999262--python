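"""Shared fixtures and brute-force oracle helpers.

The oracles here are deliberately naive — plain Python loops over rows
and cells — so they stay independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from ias_indicators.harmonization import add_event_years, assign_region, dedup_occurrences
from ias_indicators.information_status import RdParams
from ias_indicators.synthetic_world import ScenarioConfig, Scenario, generate_scenario


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """A 12-region, 20-species world shared by read-only tests."""
    return generate_scenario(
        ScenarioConfig(seed=42, n_regions=12, n_species=20, n_invasive=6)
    )


@pytest.fixture(scope="session")
def harmonized_occurrences(small_scenario) -> pd.DataFrame:
    """Occurrences of the small world: years extracted, deduplicated,
    region-assigned."""
    occ = add_event_years(small_scenario.occurrences)
    occ, _ = dedup_occurrences(occ)
    return assign_region(occ, small_scenario.world.regions)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory, small_scenario):
    """The small world written to disk in its external file formats."""
    from ias_indicators.synthetic_world import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_scenario, out)
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def oracle_subset(checklist: pd.DataFrame, eicat: pd.DataFrame, scope: str,
                  mode: str, region_filter=None) -> set:
    """Set-comprehension re-derivation of a priority subset."""
    rows = checklist.to_dict("records")
    if region_filter is not None:
        rows = [r for r in rows if r["region_id"] == region_filter]
    if scope == "realized":
        assert mode == "total"
        return {r["taxon"] for r in rows if r["is_invasive"]}
    present = {r["taxon"] for r in rows}
    ev = eicat.to_dict("records")
    if mode == "total":
        assessed = {e["taxon"] for e in ev}
    elif mode.startswith("mechanism:"):
        mech = mode.split(":", 1)[1]
        assessed = {e["taxon"] for e in ev if e["mechanism"] == mech}
    elif mode == "worst":
        best: dict[str, int] = {}
        order = {"MC": 0, "MN": 1, "MO": 2, "MR": 3, "MV": 4}
        for e in ev:
            best[e["taxon"]] = max(best.get(e["taxon"], -1), order[e["magnitude"]])
        assessed = {t for t, r in best.items() if r >= 3}
    else:
        raise AssertionError(mode)
    return present & assessed


def oracle_trend_value(first_year_by_species: dict, year: int) -> int:
    return sum(1 for y in first_year_by_species.values() if y <= year)


def oracle_rd(checklist, occurrences, region_id, params: RdParams) -> float | None:
    """Triple loop over species x slices x records."""
    listed = sorted({r["taxon"] for r in checklist.to_dict("records")
                     if r["region_id"] == region_id})
    if not listed:
        return None
    occ = occurrences.to_dict("records")
    hits = 0
    for sp in listed:
        for s in range(params.n_slices):
            y0 = params.window_start + s * params.slice_years
            y1 = y0 + params.slice_years - 1
            n = 0
            for r in occ:
                if (r.get("usable", True) and r["taxon"] == sp
                        and r.get("region_id") == region_id
                        and r.get("event_year") is not None
                        and not pd.isna(r.get("event_year"))
                        and y0 <= int(r["event_year"]) <= y1):
                    n += 1
            if n >= params.min_records:
                hits += 1
    return 100.0 * hits / (len(listed) * params.n_slices)


def oracle_in(checklist, first_records, region_id) -> float | None:
    listed = {r["taxon"] for r in checklist.to_dict("records")
              if r["region_id"] == region_id}
    if not listed:
        return None
    dated = {r["taxon"] for r in first_records.to_dict("records")
             if r["region_id"] == region_id}
    return 100.0 * len(listed & dated) / len(listed)


def oracle_im(checklist, region_id) -> float | None:
    rows = [r for r in checklist.to_dict("records") if r["region_id"] == region_id]
    listed = {r["taxon"] for r in rows}
    if not listed:
        return None
    assessed = {r["taxon"] for r in rows if r["is_invasive"]}
    return 100.0 * len(assessed) / len(listed)


def oracle_point_region(lon: float, lat: float, regions) -> str | None:
    """Per-point containment scan with lexicographic tie-break."""
    hits = [rid for rid in sorted(regions.ids)
            if regions[rid].covers(Point(lon, lat))]
    return hits[0] if hits else None


def oracle_masked_sum(surface_grid, transform, geoms, nodata=-1.0) -> float:
    """Cell-by-cell containment sum over a list of shapely geometries."""
    nrows, ncols = surface_grid.shape
    lons, lats = transform.cell_centers((nrows, ncols))
    total = 0.0
    for i in range(nrows):
        for j in range(ncols):
            v = surface_grid[i, j]
            if v == nodata:
                continue
            p = Point(lons[j], lats[i])
            if any(g.covers(p) for g in geoms):
                total += v
    return total
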