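"""End-to-end pipeline: load -> harmonize -> subsets -> indicators -> outputs.

The CLI is a thin shell over this module; everything here is callable as
a library. A run is described by a :class:`RunConfig` (usually parsed
from one YAML file), and every command writes a machine-readable
``manifest.json`` recording inputs, their checksums, the configuration
and the package version — enough to reproduce deterministic outputs
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, MissingDataError
from .formats_io import (
    Dialect,
    RegionSet,
    read_checklist,
    read_eicat,
    read_first_records,
    read_grid,
    read_occurrences,
    read_regions,
    read_surface,
    write_table,
)
from .harmonization import (
    SynonymTable,
    add_event_years,
    assign_region,
    canonicalize_names,
    dedup_occurrences,
    load_synonyms,
)
from .impact_indicators import cumulative_trend, region_counts, select_priority_subset
from .information_status import RdParams, information_status_table
from .suitability_spatial import (
    ClimateStack,
    fit_envelope_suitability,
    spatial_index,
    write_index,
)

__all__ = ["RunConfig", "HarmonizedData", "load_and_harmonize", "run_impact",
           "run_info_status", "write_manifest"]

log = logging.getLogger("ias_indicators")


@dataclass
class RunConfig:
    """Configuration of one indicator run (see README for the YAML keys)."""

    inputs: dict = field(default_factory=dict)  # name -> path
    dialect: dict | None = None
    rd: dict = field(default_factory=dict)
    subsets: list = field(default_factory=list)  # [{scope, mode}, ...]
    eval_year: int | None = None
    envelope: dict = field(default_factory=dict)  # quantile_clip, min_presences
    year_window: tuple[int, int] = (1500, 2030)
    date_granularity: str = "year"
    output_dir: str = "."
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as e:
            raise ConfigError(f"cannot read config {path!s}: {e}") from e
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "year_window" in raw:
            raw["year_window"] = tuple(raw["year_window"])
        return cls(**raw)

    def rd_params(self) -> RdParams:
        return RdParams(**self.rd)

    def require_inputs(self, *names: str) -> None:
        missing = [n for n in names if n not in self.inputs]
        if missing:
            raise ConfigError(f"config lacks required input path(s): {missing}")
        absent = [n for n in names if not Path(self.inputs[n]).exists()]
        if absent:
            raise ConfigError(
                "input file(s) not found: "
                + ", ".join(f"{n}={self.inputs[n]}" for n in absent)
            )


@dataclass
class HarmonizedData:
    """Validated, name-canonical, deduplicated, region-assigned inputs."""

    checklist: pd.DataFrame
    first_records: pd.DataFrame
    occurrences: pd.DataFrame
    eicat: pd.DataFrame | None
    regions: RegionSet | None
    regional_assessments: pd.DataFrame | None = None
    change_log: pd.DataFrame | None = None
    error_reports: dict = field(default_factory=dict)
    removed_duplicates: int = 0


def load_and_harmonize(cfg: RunConfig) -> HarmonizedData:
    """Read every configured input and run the harmonization steps.

    Required inputs: checklist. Optional: first_records, occurrences,
    eicat, regions, synonyms, regional_assessments. Error reports from the
    readers are collected per input name, never discarded.
    """
    cfg.require_inputs("checklist")
    dialect = Dialect.from_mapping(cfg.dialect)
    reports: dict[str, pd.DataFrame] = {}

    checklist, reports["checklist"] = read_checklist(cfg.inputs["checklist"], dialect)

    first_records = pd.DataFrame(columns=["taxon", "region_id", "year"])
    if "first_records" in cfg.inputs:
        first_records, reports["first_records"] = read_first_records(
            cfg.inputs["first_records"], dialect, year_window=cfg.year_window
        )

    eicat = None
    if "eicat" in cfg.inputs:
        eicat, reports["eicat"] = read_eicat(cfg.inputs["eicat"], dialect)

    regional_assessments = None
    if "regional_assessments" in cfg.inputs:
        # same schema as EICAT plus a region column; reuse the EICAT
        # vocabulary check by reading with the region column appended
        ra = pd.read_csv(cfg.inputs["regional_assessments"], dtype=str, keep_default_na=False)
        regional_assessments = ra.rename(
            columns={dialect.taxon: "taxon", dialect.region: "region_id",
                     dialect.mechanism: "mechanism", dialect.magnitude: "magnitude"}
        )

    regions = None
    if "regions" in cfg.inputs:
        regions, reports["regions"] = read_regions(cfg.inputs["regions"])

    occurrences = pd.DataFrame(
        columns=["record_id", "taxon", "lat", "lon", "event_date", "usable", "reason"]
    )
    if "occurrences" in cfg.inputs:
        occurrences, reports["occurrences"] = read_occurrences(cfg.inputs["occurrences"], dialect)

    change_log = None
    if "synonyms" in cfg.inputs:
        synonyms: SynonymTable = load_synonyms(cfg.inputs["synonyms"])
        logs = []
        checklist, l1 = canonicalize_names(checklist, synonyms)
        logs.append(l1)
        if len(first_records):
            first_records, l2 = canonicalize_names(first_records, synonyms)
            logs.append(l2)
        if len(occurrences):
            occurrences, l3 = canonicalize_names(occurrences, synonyms)
            logs.append(l3)
        if eicat is not None and len(eicat):
            eicat, l4 = canonicalize_names(eicat, synonyms)
            logs.append(l4)
        change_log = (
            pd.concat(logs, ignore_index=True)
            .groupby(["verbatim", "canonical", "status"], as_index=False)["count"]
            .sum()[["verbatim", "canonical", "count", "status"]]
        )

    removed = 0
    if len(occurrences):
        occurrences = add_event_years(occurrences, window=cfg.year_window)
        occurrences, removed = dedup_occurrences(occurrences, cfg.date_granularity)
        log.info("deduplication removed %d exact duplicate records", removed)
        if regions is not None:
            occurrences = assign_region(occurrences, regions)

    return HarmonizedData(
        checklist=checklist, first_records=first_records, occurrences=occurrences,
        eicat=eicat, regions=regions, regional_assessments=regional_assessments,
        change_log=change_log, error_reports=reports, removed_duplicates=removed,
    )


def _load_surfaces(cfg: RunConfig, data: HarmonizedData, species) -> dict:
    """Per-species suitability surfaces: read from ``surfaces_dir`` if
    given, else fit the built-in envelope model on climate rasters."""
    surfaces = {}
    if "surfaces_dir" in cfg.inputs:
        sdir = Path(cfg.inputs["surfaces_dir"])
        for path in sorted(sdir.glob("*.tif")):
            surf = read_surface(path)
            if surf.taxon:
                surfaces[surf.taxon] = surf
        return surfaces
    if "climate" not in cfg.inputs:
        return surfaces
    layers = {}
    transform = None
    for path in cfg.inputs["climate"]:
        grid, t, meta = read_grid(path)
        layers[str(meta.get("layer", Path(path).stem))] = grid
        transform = t
    climate = ClimateStack(layers=layers, transform=transform)
    occ = data.occurrences[data.occurrences["usable"]]
    env = cfg.envelope
    for sp in sorted(species):
        sp_occ = occ[occ["taxon"] == sp]
        try:
            surfaces[sp] = fit_envelope_suitability(
                sp_occ, climate,
                quantile_clip=float(env.get("quantile_clip", 0.025)),
                min_presences=int(env.get("min_presences", 10)),
            )
        except Exception as e:  # too few presences etc.: skip, keep going
            log.warning("no surface for %s: %s", sp, e)
    return surfaces


def run_impact(cfg: RunConfig, data: HarmonizedData | None = None) -> dict:
    """Compute trends, per-region counts and (when surfaces or climate
    are available) spatial indices for every requested (scope, mode).

    Writes one trend table, one region-count table and, for potential
    subsets with surfaces, one spatial-index GeoTIFF per request; returns
    a summary dict. Realized mechanism/worst requests without a
    regional-assessment table raise :class:`MissingDataError`.
    """
    if not cfg.subsets:
        raise ConfigError("impact run requested but config lists no subsets")
    if data is None:
        data = load_and_harmonize(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    trends = []
    counts = []
    summary: dict = {"subsets": {}, "removed_duplicates": data.removed_duplicates}
    want_maps = data.regions is not None and (
        "surfaces_dir" in cfg.inputs or "climate" in cfg.inputs
    )
    for req in cfg.subsets:
        scope, mode = req["scope"], req["mode"]
        subset = select_priority_subset(
            data.checklist, data.eicat, scope, mode,
            regional_assessments=data.regional_assessments,
        )
        trend = cumulative_trend(subset, data.first_records, eval_year=cfg.eval_year)
        trends.append(trend.to_frame())
        if trend.uncounted:
            log.info("%s: %d species lack first records and are uncounted in the trend: %s",
                     subset.label, len(trend.uncounted), sorted(trend.uncounted))
        counts.append(
            region_counts(data.checklist, data.eicat, scope, modes=[mode],
                          regional_assessments=data.regional_assessments)
        )
        summary["subsets"][subset.label] = {
            "species": len(subset),
            "trend_final": trend.final_value,
            "uncounted": sorted(trend.uncounted),
        }
        if want_maps and scope == "potential":
            surfaces = _load_surfaces(cfg, data, subset.species)
            index = spatial_index(surfaces, data.checklist, subset, data.regions)
            tif = out / f"spatial_index_{scope}_{mode.replace(':', '_')}.tif"
            if index.grid.size:
                write_index(index, tif)
                summary["subsets"][subset.label]["spatial_index"] = {
                    "path": tif.name,
                    "max": float(index.grid[index.grid != index.nodata].max())
                    if (index.grid != index.nodata).any() else 0.0,
                    "missing_surfaces": list(index.missing),
                }

    write_table(pd.concat(trends, ignore_index=True), out / "trends.csv", schema="trend")
    write_table(pd.concat(counts, ignore_index=True), out / "region_counts.csv",
                schema="region_counts")
    if data.change_log is not None:
        write_table(data.change_log, out / "name_change_log.csv", schema="change_log")
    write_manifest(cfg, out, command="impact", extra=summary)
    return summary


def run_info_status(cfg: RunConfig, data: HarmonizedData | None = None) -> pd.DataFrame:
    """Compute the per-region information-status table and write it.

    Regions known from the geometry input but absent from the checklist
    appear as no-data rows (undefined sub-indicators, burden 0), keeping
    "nothing reported" distinct from "reported and absent"."""
    if data is None:
        data = load_and_harmonize(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_list = None
    if data.regions is not None:
        region_list = sorted(
            set(data.regions.ids) | set(data.checklist["region_id"].unique())
        )
    table = information_status_table(
        data.checklist, data.first_records, data.occurrences,
        params=cfg.rd_params(), regions=region_list,
    )
    rounded = table.copy()
    for col in ("In", "Im", "Rd", "composite"):
        # reports round half-up to integers for display; the full-precision
        # values stay available through the library API
        rounded[col] = (
            rounded[col].map(lambda v: v if pd.isna(v) else _round_half_up(v))
        )
    write_table(rounded, out / "information_status.csv", schema="info_status")
    write_manifest(cfg, out, command="info-status",
                   extra={"regions": len(table), "removed_duplicates": data.removed_duplicates})
    return table


def _round_half_up(v: float) -> int:
    """Round half away from zero (display rounding for percentages)."""
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def write_manifest(cfg: RunConfig, outdir, command: str, extra: dict | None = None) -> None:
    """Record inputs (with SHA-256 checksums), config and version."""
    checksums = {}
    for name, path in cfg.inputs.items():
        paths = path if isinstance(path, list) else [path]
        for p in paths:
            p = Path(p)
            if p.exists() and p.is_file():
                checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "input_checksums": checksums,
    }
    if extra:
        manifest.update(extra)
    with open(Path(outdir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
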