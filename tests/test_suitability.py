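"""Envelope model, region masking and the spatial index of potential impact."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from conftest import oracle_masked_sum
from ias_indicators.errors import AlignmentError, ValidationError
from ias_indicators.formats_io import RegionSet, SuitabilitySurface
from ias_indicators.grid import GridTransform
from ias_indicators.impact_indicators import PrioritySubset
from ias_indicators.suitability_spatial import (
    ClimateStack,
    fit_envelope_suitability,
    mask_to_regions,
    spatial_index,
)

T = GridTransform(west=0.0, north=10.0, xres=1.0, yres=1.0)


def _coordinate_climate(shape, transform=T):
    """Layers equal to the cell-center coordinates: the climate envelope
    then coincides with a geographic rectangle, giving an exact oracle."""
    lons, lats = transform.cell_centers(shape)
    xx, yy = np.meshgrid(lons, lats)
    return ClimateStack(layers={"x": xx, "y": yy}, transform=transform)


def _occ(points, taxon="SpA"):
    return pd.DataFrame(
        [(taxon, lat, lon) for lon, lat in points], columns=["taxon", "lat", "lon"]
    )


class TestEnvelopeModel:
    def test_single_layer_full_range_presences(self):
        climate = ClimateStack(
            layers={"x": _coordinate_climate((10, 10)).layers["x"]}, transform=T
        )
        pts = [(0.5, 9.5), (9.5, 0.5)]  # span the full x range
        occ = _occ(pts * 5)  # 10 presences to clear the minimum
        surf = fit_envelope_suitability(occ, climate, quantile_clip=0.0)
        assert np.allclose(surf.grid, 1.0)  # every cell inside the 1-layer envelope

    def test_quantile_zero_scores_all_presence_cells_one(self):
        climate = _coordinate_climate((10, 10))
        rng = np.random.default_rng(7)
        pts = [(float(rng.uniform(2, 8)), float(rng.uniform(2, 8))) for _ in range(30)]
        pts += [(0.5, 0.5), (9.5, 9.5)]  # grid extremes
        surf = fit_envelope_suitability(_occ(pts), climate, quantile_clip=0.0)
        row, col = T.rowcol([p[0] for p in pts], [p[1] for p in pts])
        assert np.allclose(surf.grid[row, col], 1.0)

    def test_too_few_presences_refused_with_count(self):
        climate = _coordinate_climate((10, 10))
        with pytest.raises(ValidationError, match="only 3"):
            fit_envelope_suitability(_occ([(1, 1), (2, 2), (3, 3)]), climate)

    def test_misaligned_layers_rejected(self):
        with pytest.raises(AlignmentError):
            ClimateStack(layers={"a": np.zeros((5, 5)), "b": np.zeros((6, 5))},
                         transform=T)

    def test_known_rectangular_niche_recovered(self):
        # 200 presences uniform in a known rectangle; envelope bounds must
        # land within order-statistic distance of the true bounds and
        # >=95% of within-niche cells must score above 0.5
        t = GridTransform(west=0.0, north=50.0, xres=0.5, yres=0.5)
        shape = (100, 100)
        climate = _coordinate_climate(shape, t)
        niche = (10.0, 15.0, 35.0, 40.0)  # west, south, east, north
        rng = np.random.default_rng(123)
        n = 200
        pts = [(float(rng.uniform(niche[0], niche[2])),
                float(rng.uniform(niche[1], niche[3]))) for _ in range(n)]
        surf = fit_envelope_suitability(_occ(pts), climate, quantile_clip=0.0)

        lons, lats = t.cell_centers(shape)
        xx, yy = np.meshgrid(lons, lats)
        inside = ((xx >= niche[0]) & (xx <= niche[2])
                  & (yy >= niche[1]) & (yy <= niche[3]))
        frac_high = (surf.grid[inside] > 0.5).mean()
        assert frac_high >= 0.95

        # support of the fitted envelope vs the true rectangle: the gap at
        # each edge is the sample-minimum offset, expected span/(n+1),
        # allowed up to one cell plus 5 expected gaps
        full = surf.grid == 1.0
        rows, cols = np.where(full)
        tol = 0.5 + 5 * 25.0 / n
        assert abs(lons[cols.min()] - niche[0]) <= tol
        assert abs(lons[cols.max()] - niche[2]) <= tol
        assert abs(lats[rows.min()] - niche[3]) <= tol
        assert abs(lats[rows.max()] - niche[1]) <= tol

    def test_duplicate_presence_rows_change_nothing_after_dedup(self):
        climate = _coordinate_climate((10, 10))
        rng = np.random.default_rng(9)
        pts = [(float(rng.uniform(1, 9)), float(rng.uniform(1, 9))) for _ in range(20)]
        base = fit_envelope_suitability(_occ(pts), climate, quantile_clip=0.0)
        dup = fit_envelope_suitability(_occ(pts + pts), climate, quantile_clip=0.0)
        assert np.array_equal(base.grid, dup.grid)


def _regions():
    return RegionSet({
        "A": box(0, 5, 5, 10), "B": box(5, 5, 10, 10), "C": box(0, 0, 10, 5),
    })


class TestMaskToRegions:
    def test_constant_surface_masked_to_one_region(self):
        surf = SuitabilitySurface("SpA", np.ones((10, 10)), T)
        masked = mask_to_regions(surf, _regions(), {"A"})
        assert masked.grid.sum() == 25.0  # 5x5 cells of region A
        assert masked.grid[:5, :5].min() == 1.0 and masked.grid[:5, 5:].max() == 0.0

    def test_no_listed_regions_warns_and_zeroes(self):
        surf = SuitabilitySurface("SpA", np.ones((10, 10)), T)
        with pytest.warns(UserWarning, match="no listed regions"):
            masked = mask_to_regions(surf, _regions(), set())
        assert masked.grid.max() == 0.0

    def test_nodata_preserved(self):
        grid = np.ones((10, 10))
        grid[0, 0] = -1.0
        masked = mask_to_regions(SuitabilitySurface("SpA", grid, T), _regions(), {"A"})
        assert masked.grid[0, 0] == -1.0

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        surf = SuitabilitySurface("SpA", rng.uniform(0, 1, (10, 10)), T)
        once = mask_to_regions(surf, _regions(), {"A", "C"})
        twice = mask_to_regions(once, _regions(), {"A", "C"})
        assert np.array_equal(once.grid, twice.grid)

    def test_masked_sum_equals_cell_by_cell_oracle(self):
        rng = np.random.default_rng(19)
        grid = rng.uniform(0, 1, (10, 10))
        grid[3, 7] = -1.0
        surf = SuitabilitySurface("SpA", grid, T)
        regions = _regions()
        masked = mask_to_regions(surf, regions, {"A", "B"})
        expect = oracle_masked_sum(grid, T, [regions["A"], regions["B"]])
        assert masked.grid[masked.grid != -1].sum() == pytest.approx(expect, abs=1e-9)


class TestSpatialIndex:
    def _world(self, n_species=5, shape=(100, 100), seed=101):
        t = GridTransform(west=0.0, north=float(shape[0]), xres=1.0, yres=1.0)
        rng = np.random.default_rng(seed)
        # 3x2 region tiling of the grid
        h, w = shape[0] / 2.0, shape[1] / 3.0
        regions = RegionSet({
            f"R{i}{j}": box(j * w, shape[0] - (i + 1) * h, (j + 1) * w, shape[0] - i * h)
            for i in range(2) for j in range(3)
        })
        species = [f"Sp{i}" for i in range(n_species)]
        surfaces = {
            sp: SuitabilitySurface(sp, rng.uniform(0, 1, shape), t) for sp in species
        }
        listings = []
        for sp in species:
            for rid in rng.choice(regions.ids, size=rng.integers(1, 4), replace=False):
                listings.append((sp, rid, True))
        checklist = pd.DataFrame(listings, columns=["taxon", "region_id", "is_invasive"])
        subset = PrioritySubset("potential", "total", frozenset(species))
        return t, regions, surfaces, checklist, subset

    def test_single_species_constant_surface_equals_region_mask(self):
        t, regions, _, _, _ = self._world()
        surf = SuitabilitySurface("SpA", np.ones((100, 100)), t)
        checklist = pd.DataFrame([("SpA", "R00", True)],
                                 columns=["taxon", "region_id", "is_invasive"])
        subset = PrioritySubset("potential", "total", frozenset({"SpA"}))
        index = spatial_index({"SpA": surf}, checklist, subset, regions)
        # region R00 spans x in [0, 33.33): cell centers 0.5 .. 32.5 fall in
        assert index.grid[:50, :33].min() == 1.0
        assert index.grid[:50, 33:].max() == 0.0 and index.grid[50:].max() == 0.0

    def test_disjoint_listed_regions_never_sum(self):
        t, regions, _, _, _ = self._world()
        surfaces = {sp: SuitabilitySurface(sp, np.ones((100, 100)), t)
                    for sp in ("SpA", "SpB")}
        checklist = pd.DataFrame(
            [("SpA", "R00", True), ("SpB", "R11", True)],
            columns=["taxon", "region_id", "is_invasive"])
        subset = PrioritySubset("potential", "total", frozenset({"SpA", "SpB"}))
        index = spatial_index(surfaces, checklist, subset, regions)
        assert index.grid.max() == 1.0

    def test_per_cell_equality_with_brute_force_double_loop(self):
        t, regions, surfaces, checklist, subset = self._world()
        index = spatial_index(surfaces, checklist, subset, regions)

        listed = checklist.groupby("taxon")["region_id"].agg(set)
        # brute force: for every cell, loop species and test containment
        from shapely.geometry import Point

        lons, lats = t.cell_centers((100, 100))
        geoms = {rid: regions[rid] for rid in regions.ids}
        expect = np.zeros((100, 100))
        for sp in subset.species:
            covered = {rid for rid in listed[sp]}
            for i in range(100):
                for j in range(100):
                    p = Point(lons[j], lats[i])
                    if any(geoms[rid].covers(p) for rid in covered):
                        expect[i, j] += surfaces[sp].grid[i, j]
        assert np.abs(index.grid - expect).max() <= 1e-9

    def test_additive_over_species(self):
        t, regions, surfaces, checklist, subset = self._world(n_species=4, shape=(20, 20))
        whole = spatial_index(surfaces, checklist, subset, regions)
        parts = np.zeros((20, 20))
        for sp in subset.species:
            single = PrioritySubset("potential", "total", frozenset({sp}))
            parts += spatial_index(surfaces, checklist, single, regions).grid
        assert np.abs(whole.grid - parts).max() <= 1e-12

    def test_index_bounded_by_subset_size(self):
        t, regions, surfaces, checklist, subset = self._world(n_species=5, shape=(20, 20))
        index = spatial_index(surfaces, checklist, subset, regions)
        assert index.grid.max() <= len(subset.species)
        assert index.grid[index.grid != index.nodata].min() >= 0.0

    def test_missing_surface_skipped_with_warning(self):
        t, regions, surfaces, checklist, subset = self._world(n_species=3, shape=(20, 20))
        del surfaces["Sp0"]
        with pytest.warns(UserWarning, match="Sp0"):
            index = spatial_index(surfaces, checklist, subset, regions)
        assert index.missing == ("Sp0",)

    def test_geotransform_mismatch_names_species(self):
        t, regions, surfaces, checklist, subset = self._world(n_species=2, shape=(20, 20))
        bad = GridTransform(west=1.0, north=20.0, xres=1.0, yres=1.0)
        surfaces["Sp1"] = SuitabilitySurface("Sp1", surfaces["Sp1"].grid, bad)
        with pytest.raises(AlignmentError, match="Sp1"):
            spatial_index(surfaces, checklist, subset, regions)
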