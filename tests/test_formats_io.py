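"""Reader validation, collect-and-report behaviour, and IO round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

from ias_indicators.errors import (
    FormatError,
    IndicatorError,
    RegionError,
    SchemaError,
    ValidationError,
    VocabularyError,
)
from ias_indicators.formats_io import (
    Dialect,
    SuitabilitySurface,
    read_checklist,
    read_eicat,
    read_occurrences,
    read_regions,
    read_surface,
    read_table,
    write_regions,
    write_surface,
    write_table,
)
from ias_indicators.grid import GridTransform


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


CHECKLIST_HEADER = "scientificName,locationID,establishmentMeans,isInvasive,occurrenceStatus\n"


class TestReadChecklist:
    def test_all_valid_rows_pass_with_empty_report(self, tmp_path):
        p = _write(tmp_path / "c.csv", CHECKLIST_HEADER + (
            "Sp a,R1,introduced,true,present\n"
            "Sp b,R1,uncertain,false,present\n"
            "Sp a,R2,introduced,invasive,present\n"
        ))
        rec, errors = read_checklist(p)
        assert len(rec) == 3 and len(errors) == 0
        assert rec["is_invasive"].tolist() == [True, False, True]

    def test_invasive_flag_requires_introduced_means(self, tmp_path):
        p = _write(tmp_path / "c.csv", CHECKLIST_HEADER +
                   "Sp a,R1,uncertain,true,present\n")
        rec, errors = read_checklist(p)
        assert len(rec) == 0
        assert errors["code"].tolist() == ["invasive_flag"]

    def test_conflicting_duplicate_flags_rejected_naming_both_rows(self, tmp_path):
        p = _write(tmp_path / "c.csv", CHECKLIST_HEADER + (
            "Sp a,R1,introduced,true,present\n"
            "Sp b,R1,introduced,false,present\n"
            "Sp a,R1,introduced,false,present\n"
        ))
        rec, errors = read_checklist(p)
        assert rec["taxon"].tolist() == ["Sp b"]
        conflict = errors[errors["code"] == "conflict"]
        assert sorted(conflict["row"]) == [2, 4]
        assert all("[2, 4]" in d for d in conflict["detail"])

    def test_identical_duplicate_keeps_first_and_reports(self, tmp_path):
        p = _write(tmp_path / "c.csv", CHECKLIST_HEADER + (
            "Sp a,R1,introduced,true,present\n"
            "Sp a,R1,introduced,true,present\n"
        ))
        rec, errors = read_checklist(p)
        assert len(rec) == 1
        assert errors["code"].tolist() == ["duplicate_row"]

    def test_non_present_status_reported_not_counted(self, tmp_path):
        p = _write(tmp_path / "c.csv", CHECKLIST_HEADER +
                   "Sp a,R1,introduced,false,absent\n")
        rec, errors = read_checklist(p)
        assert len(rec) == 0 and errors["code"].tolist() == ["occurrence_status"]

    def test_missing_mapped_column_names_it(self, tmp_path):
        p = _write(tmp_path / "c.csv", "scientificName,locationID\nSp a,R1\n")
        with pytest.raises(SchemaError, match="establishmentMeans"):
            read_checklist(p)

    def test_custom_dialect_mapping(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "name;region;means;inv\nSp a;R1;introduced;true\n")
        rec, _ = read_checklist(p, Dialect(
            taxon="name", region="region", establishment_means="means",
            is_invasive="inv", delimiter=";"))
        assert rec["taxon"].tolist() == ["Sp a"]


class TestReadEicat:
    def test_duplicate_mechanism_collapses_to_max_magnitude(self, tmp_path):
        p = _write(tmp_path / "e.csv", "scientificName,mechanism,magnitude\n"
                   "Sp a,predation,MO\nSp a,predation,MV\n")
        rec, errors = read_eicat(p)
        assert len(rec) == 1
        assert rec.iloc[0]["magnitude"] == "MV"
        assert errors["code"].tolist() == ["collapsed"]

    def test_unknown_magnitude_is_vocabulary_error(self, tmp_path):
        p = _write(tmp_path / "e.csv",
                   "scientificName,mechanism,magnitude\nSp a,predation,XX\n")
        with pytest.raises(VocabularyError, match="XX"):
            read_eicat(p)

    def test_distinct_rows_preserved_exactly(self, tmp_path):
        rows, expect = [], 0
        for i in range(11):
            for j in range(1 + i % 3):
                rows.append(f"Sp {i},mech_{j},M{'CNORV'[j]}")
                expect += 1
        p = _write(tmp_path / "e.csv",
                   "scientificName,mechanism,magnitude\n" + "\n".join(rows) + "\n")
        rec, errors = read_eicat(p)
        assert len(rec) == expect and len(errors) == 0


class TestReadOccurrences:
    HEADER = "occurrenceID,scientificName,decimalLatitude,decimalLongitude,eventDate\n"

    def test_out_of_bounds_latitude_flagged_unusable(self, tmp_path):
        p = _write(tmp_path / "o.csv", self.HEADER + "o1,Sp a,91.0,10.0,1999\n")
        rec, errors = read_occurrences(p)
        assert not rec.iloc[0]["usable"]
        assert "out of bounds" in rec.iloc[0]["reason"]

    def test_valid_row_keeps_verbatim_date(self, tmp_path):
        p = _write(tmp_path / "o.csv", self.HEADER + "o1,Sp a,-10.5,120.25,1987-05-03\n")
        rec, errors = read_occurrences(p)
        assert rec.iloc[0]["usable"] and rec.iloc[0]["event_date"] == "1987-05-03"
        assert len(errors) == 0

    def test_invalid_rows_counted_by_validation_pass(self, tmp_path):
        rng = np.random.default_rng(5)
        lines, n_bad = [], 0
        for i in range(100):
            if i % 14 == 3:  # 8 invalid rows planted
                lines.append(f"o{i},Sp x,999,abc,2000")
                n_bad += 1
            else:
                lines.append(f"o{i},Sp x,{rng.uniform(-60, 60):.4f},{rng.uniform(-150, 150):.4f},2000")
        p = _write(tmp_path / "o.csv", self.HEADER + "\n".join(lines) + "\n")
        rec, errors = read_occurrences(p)
        assert len(rec) == 100
        assert int((~rec["usable"]).sum()) == n_bad == len(errors)


class TestReadRegions:
    @staticmethod
    def _fc(features):
        return {"type": "FeatureCollection", "features": features}

    @staticmethod
    def _sq(rid, x0, y0, x1, y1):
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        return {"type": "Feature", "properties": {"region_id": rid},
                "geometry": {"type": "Polygon", "coordinates": [ring]}}

    def test_two_disjoint_squares(self, tmp_path):
        p = tmp_path / "r.geojson"
        p.write_text(json.dumps(self._fc([self._sq("A", 0, 0, 1, 1),
                                          self._sq("B", 2, 0, 3, 1)])))
        regions, errors = read_regions(p)
        assert len(regions) == 2 and len(errors) == 0

    def test_duplicate_region_id_raises(self, tmp_path):
        p = tmp_path / "r.geojson"
        p.write_text(json.dumps(self._fc([self._sq("A", 0, 0, 1, 1),
                                          self._sq("A", 2, 0, 3, 1)])))
        with pytest.raises(RegionError, match="'A'"):
            read_regions(p)

    def test_bowtie_polygon_repaired_to_valid_geometry(self, tmp_path):
        bowtie = {"type": "Feature", "properties": {"region_id": "X"},
                  "geometry": {"type": "Polygon", "coordinates": [
                      [[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]]]}}
        p = tmp_path / "r.geojson"
        p.write_text(json.dumps(self._fc([bowtie])))
        regions, errors = read_regions(p)
        geom = regions["X"]
        assert geom.is_valid and len(errors) == 0
        # repair preserves the vertex span of the original figure
        assert geom.bounds == (0.0, 0.0, 2.0, 2.0)

    def test_roundtrip_write_read(self, tmp_path, small_scenario):
        p = tmp_path / "w.geojson"
        write_regions(small_scenario.world.regions, p)
        back, errors = read_regions(p)
        assert set(back.ids) == set(small_scenario.world.regions.ids)
        assert len(errors) == 0
        for rid in back.ids:
            assert back[rid].equals(small_scenario.world.regions[rid])


class TestRasterIO:
    T = GridTransform(west=10.0, north=50.0, xres=0.5, yres=0.5)

    def test_constant_grid_roundtrip_identical(self, tmp_path):
        s = SuitabilitySurface("Sp a", np.full((4, 6), 0.5), self.T)
        write_surface(s, tmp_path / "s.tif")
        back = read_surface(tmp_path / "s.tif")
        assert back.taxon == "Sp a"
        assert np.array_equal(back.grid, s.grid)
        assert back.transform == self.T

    def test_value_above_one_is_validation_error_not_clamp(self, tmp_path):
        grid = np.full((3, 3), 0.5)
        grid[1, 1] = 1.2
        s = SuitabilitySurface("Sp a", grid, self.T)
        with pytest.raises(ValidationError, match="1.2"):
            write_surface(s, tmp_path / "bad.tif")

    def test_random_grid_roundtrip_error_below_tolerance(self, tmp_path):
        rng = np.random.default_rng(11)
        grid = rng.uniform(0, 1, size=(20, 30))
        grid[0, :5] = -1.0  # nodata band
        s = SuitabilitySurface("Sp b", grid, self.T)
        write_surface(s, tmp_path / "s.tif")
        back = read_surface(tmp_path / "s.tif")
        assert np.abs(back.grid - grid).max() < 1e-6
        assert back.transform == self.T


class TestTotality:
    """Readers return records+report or a typed error on arbitrary bytes."""

    READERS = [read_checklist, read_eicat, read_occurrences]

    @pytest.mark.parametrize("reader", READERS, ids=lambda f: f.__name__)
    def test_garbage_bytes_never_crash_uncontrolled(self, tmp_path, reader):
        rng = np.random.default_rng(99)
        for i in range(15):
            p = tmp_path / f"junk{i}"
            p.write_bytes(bytes(rng.integers(0, 256, size=rng.integers(0, 400))))
            try:
                rec, errors = reader(p)
            except IndicatorError:
                continue
            assert isinstance(rec, pd.DataFrame) and isinstance(errors, pd.DataFrame)

    def test_garbage_geojson_is_typed_error(self, tmp_path):
        p = tmp_path / "junk.geojson"
        p.write_bytes(b"\x00\xffnot json")
        with pytest.raises(FormatError):
            read_regions(p)

    def test_garbage_tiff_is_typed_error(self, tmp_path):
        p = tmp_path / "junk.tif"
        p.write_bytes(b"II*\x00garbage")
        with pytest.raises(FormatError):
            read_surface(p)


def test_output_table_roundtrip_lossless(tmp_path):
    df = pd.DataFrame({
        "region_id": ["R1", "R2"], "mode": ["total", "worst"], "count": [3, 0],
    })
    write_table(df, tmp_path / "t.csv", schema="region_counts")
    back = read_table(tmp_path / "t.csv")
    pd.testing.assert_frame_equal(back, df)
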