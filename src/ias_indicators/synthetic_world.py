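"""Seeded synthetic invasion worlds for offline, closed-loop testing.

The real inputs behind the indicators — per-region alien species
checklists, first-introduction years, EICAT impact profiles, occurrence
downloads — are version-dependent external databases. This module
generates inputs with the same *statistical structure* on a rectangular
world: regions tile a lon/lat grid, each species occupies a rectangular
geographic niche, invades a random set of intersecting regions with
introduction years drawn from a two-phase history (slow before 1950,
accelerating after, so cumulative trends take their characteristic
shape), and is sampled with spatially and temporally uneven effort.
Reporting gaps — missing first records, unpopulated impact flags — are
planted at configured rates, and exact duplicate occurrence rows are
planted for deduplication bookkeeping.

Everything is deterministic per seed, and every generated scenario
carries its **ground truth** (niches, gap sets, planted-duplicate count,
true subset memberships), so downstream indicator values can be checked
against brute-force recomputation from the truth.

Default scale mirrors a global amphibian-style demonstration: 82 regions,
75 alien species of which 11 are invasive (priority) species with EICAT
profiles over seven impact mechanisms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .errors import ConfigError
from .formats_io import MAGNITUDES, MECHANISMS, RegionSet
from .grid import GridTransform
from .suitability_spatial import ClimateStack

__all__ = [
    "ScenarioConfig",
    "World",
    "InvasionHistory",
    "Scenario",
    "generate_world",
    "generate_invasion_history",
    "generate_occurrences",
    "generate_scenario",
    "write_fixture_bundle",
    "verify_fixture_bundle",
]


def _tiling(n_regions: int) -> tuple[int, int]:
    """Near-square (rows, cols) factorization of the region count."""
    rows = max(d for d in range(1, int(math.isqrt(n_regions)) + 1) if n_regions % d == 0)
    return rows, n_regions // rows


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one synthetic world; ``seed`` is mandatory.

    Rates are fractions in [0, 1]. ``first_record_gap`` is the share of
    introduction events whose year goes unreported (right-censoring of the
    introduction history); ``impact_flag_gap`` the share of regional
    listings of invasive species whose impact flag is left unpopulated.
    ``base_records_per_slice`` is the Poisson mean of occurrence records
    per species, region and 5-year slice at full sampling effort; actual
    effort varies by region and slice. ``rd_guarantee`` forces at least
    ``rd_min_records`` records in every slice (used by no-gap closure
    scenarios where every sub-indicator must reach 100%).
    """

    seed: int
    n_regions: int = 82
    n_species: int = 75
    n_invasive: int = 11
    mechanisms: tuple = MECHANISMS
    mechanism_extra_mean: float = 0.8  # multiplicity = 1 + Poisson(this)
    magnitude_probs: tuple = (0.15, 0.25, 0.30, 0.20, 0.10)  # over MC..MV
    intro_year_start: int = 1850
    intro_break: int = 1950
    intro_year_end: int = 2005
    intro_late_share: float = 0.7
    mean_extra_regions: float = 2.0  # invaded regions = 1 + Poisson(this)
    uncertain_share: float = 0.1
    first_record_gap: float = 0.3
    impact_flag_gap: float = 0.4
    sampling_effort: float = 0.6
    base_records_per_slice: float = 6.0
    duplicate_rate: float = 0.05
    bare_year_date_share: float = 0.2
    window_start: int = 1970
    window_end: int = 2019
    slice_years: int = 5
    rd_min_records: int = 10
    rd_guarantee: bool = False
    cell_size: float = 0.5
    tile_cells: int = 4  # grid cells per region tile, each axis
    west: float = 0.0
    north: float = 30.0

    def __post_init__(self) -> None:
        if self.n_invasive > self.n_species:
            raise ConfigError("n_invasive cannot exceed n_species")
        for name in ("first_record_gap", "impact_flag_gap", "duplicate_rate",
                     "uncertain_share", "intro_late_share", "bare_year_date_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_regions < 1 or self.n_species < 0:
            raise ConfigError("need at least one region and a non-negative species count")
        if self.tile_cells < 1 or self.cell_size <= 0:
            raise ConfigError("tile_cells and cell_size must be positive")
        if not np.isclose(sum(self.magnitude_probs), 1.0) or len(self.magnitude_probs) != 5:
            raise ConfigError("magnitude_probs must be 5 probabilities summing to 1")

    @property
    def region_tiling(self) -> tuple[int, int]:
        return _tiling(self.n_regions)

    @property
    def grid_shape(self) -> tuple[int, int]:
        tr, tc = self.region_tiling
        return tr * self.tile_cells, tc * self.tile_cells

    @property
    def n_slices(self) -> int:
        return (self.window_end - self.window_start + 1) // self.slice_years

    @classmethod
    def no_gaps(cls, seed: int, **overrides) -> "ScenarioConfig":
        """A closure scenario with no reporting gaps: every species is
        invasive, flagged and dated, and occurrence sampling meets the
        range-dynamics adequacy threshold in every slice — all three
        information sub-indicators must come out at 100%."""
        params = dict(
            seed=seed,
            first_record_gap=0.0,
            impact_flag_gap=0.0,
            uncertain_share=0.0,
            rd_guarantee=True,
        )
        params.update(overrides)
        params["n_invasive"] = params.get("n_species", cls.n_species)
        return cls(**params)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class World:
    regions: RegionSet
    climate: ClimateStack
    transform: GridTransform
    #: region id -> (row0, row1, col0, col1) half-open cell spans
    tiles: dict[str, tuple[int, int, int, int]]


@dataclass
class InvasionHistory:
    checklist: pd.DataFrame
    first_records: pd.DataFrame
    eicat: pd.DataFrame
    # --- ground truth for oracle tests ---
    niches: dict[str, tuple[float, float, float, float]]  # (west, south, east, north)
    invasive_species: frozenset
    intro_years: dict[tuple[str, str], int]  # every introduction, censored or not
    missing_first_records: frozenset  # (taxon, region) pairs censored
    unflagged_listings: frozenset  # (taxon, region) invasive listings left unflagged


@dataclass
class Scenario:
    config: ScenarioConfig
    world: World
    history: InvasionHistory
    occurrences: pd.DataFrame
    planted_duplicates: int
    effort: np.ndarray  # (n_regions, n_slices) sampling effort in [0, 1]


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per generation stage
    return np.random.default_rng([config.seed, stream])


def _species_names(n: int) -> list[str]:
    return [f"Species_{i:03d}" for i in range(n)]


def _region_ids(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


def generate_world(config: ScenarioConfig) -> World:
    """Tile regions over the grid and synthesize smooth climate layers.

    Regions are axis-aligned rectangles exactly partitioning the grid, so
    point-in-region containment has an exact arithmetic oracle. Climate is
    a north-south temperature gradient and an east-west moisture gradient,
    each with smoothed seeded noise.
    """
    rng = _rng(config, 0)
    nrows, ncols = config.grid_shape
    tr, tc = config.region_tiling
    t = GridTransform(config.west, config.north, config.cell_size, config.cell_size)

    tiles: dict[str, tuple[int, int, int, int]] = {}
    geoms = {}
    ids = _region_ids(config.n_regions)
    k = 0
    for i in range(tr):
        for j in range(tc):
            rid = ids[k]
            k += 1
            r0, r1 = i * config.tile_cells, (i + 1) * config.tile_cells
            c0, c1 = j * config.tile_cells, (j + 1) * config.tile_cells
            tiles[rid] = (r0, r1, c0, c1)
            geoms[rid] = box(
                t.west + c0 * t.xres, t.north - r1 * t.yres,
                t.west + c1 * t.xres, t.north - r0 * t.yres,
            )

    rows = np.arange(nrows, dtype=float)[:, None] * np.ones((1, ncols))
    cols = np.ones((nrows, 1)) * np.arange(ncols, dtype=float)[None, :]
    temp = 25.0 - 20.0 * rows / max(nrows - 1, 1)
    temp += 2.0 * gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=2.0)
    moist = 200.0 + 800.0 * cols / max(ncols - 1, 1)
    moist += 60.0 * gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=2.0)
    climate = ClimateStack(
        layers={"temperature": temp, "moisture": moist}, transform=t
    )
    return World(regions=RegionSet(geoms), climate=climate, transform=t, tiles=tiles)


def _draw_intro_year(rng: np.random.Generator, config: ScenarioConfig) -> int:
    if rng.random() < config.intro_late_share:
        return int(rng.integers(config.intro_break, config.intro_year_end + 1))
    return int(rng.integers(config.intro_year_start, config.intro_break))


def generate_invasion_history(config: ScenarioConfig, world: World) -> InvasionHistory:
    """Draw niches, invaded regions, introduction years, flags and EICAT
    profiles, with reporting gaps planted at the configured rates."""
    rng = _rng(config, 1)
    t = world.transform
    nrows, ncols = config.grid_shape
    west, south, east, north = t.bounds((nrows, ncols))
    span_x, span_y = east - west, north - south

    species = _species_names(config.n_species)
    invasive = frozenset(
        rng.choice(species, size=config.n_invasive, replace=False).tolist()
    ) if config.n_invasive else frozenset()

    region_boxes = {
        rid: (t.west + c0 * t.xres, t.north - r1 * t.yres,
              t.west + c1 * t.xres, t.north - r0 * t.yres)
        for rid, (r0, r1, c0, c1) in world.tiles.items()
    }

    niches: dict[str, tuple[float, float, float, float]] = {}
    checklist_rows = []
    fr_rows = []
    intro_years: dict[tuple[str, str], int] = {}
    missing_fr = set()
    unflagged = set()
    for sp in species:
        # rectangular geographic niche: random center, half-spans 15-50%
        # of the world extent per axis, clipped to the world
        cx = rng.uniform(west, east)
        cy = rng.uniform(south, north)
        hx = rng.uniform(0.15, 0.5) * span_x / 2
        hy = rng.uniform(0.15, 0.5) * span_y / 2
        nw, ne_ = max(west, cx - hx), min(east, cx + hx)
        ns, nn = max(south, cy - hy), min(north, cy + hy)
        niches[sp] = (nw, ns, ne_, nn)

        candidates = sorted(
            rid for rid, (bw, bs, be, bn) in region_boxes.items()
            if min(ne_, be) > max(nw, bw) and min(nn, bn) > max(ns, bs)
        )
        k = min(len(candidates), 1 + int(rng.poisson(config.mean_extra_regions)))
        invaded = sorted(rng.choice(candidates, size=k, replace=False).tolist())
        is_inv_sp = sp in invasive
        for rid in invaded:
            year = _draw_intro_year(rng, config)
            intro_years[(sp, rid)] = year
            if rng.random() < config.first_record_gap:
                missing_fr.add((sp, rid))
            else:
                fr_rows.append((sp, rid, year))
            if is_inv_sp:
                means = "introduced"
                flagged = rng.random() >= config.impact_flag_gap
                if not flagged:
                    unflagged.add((sp, rid))
            else:
                means = "uncertain" if rng.random() < config.uncertain_share else "introduced"
                flagged = False
            checklist_rows.append((sp, rid, "present", means, flagged))

    checklist = pd.DataFrame(
        checklist_rows,
        columns=["taxon", "region_id", "occurrence_status", "establishment_means", "is_invasive"],
    )
    first_records = pd.DataFrame(fr_rows, columns=["taxon", "region_id", "year"])
    if len(first_records):
        first_records = first_records.astype({"year": "int64"})

    eicat_rows = []
    mechs = list(config.mechanisms)
    # geometrically decaying mechanism weights: the first mechanisms
    # (predation, disease transmission) dominate, as impact profiles do
    weights = np.array([0.5 ** i for i in range(len(mechs))])
    weights /= weights.sum()
    for sp in sorted(invasive):
        n_mech = min(len(mechs), 1 + int(rng.poisson(config.mechanism_extra_mean)))
        chosen = rng.choice(mechs, size=n_mech, replace=False, p=weights)
        for mech in sorted(chosen):
            mag = rng.choice(MAGNITUDES, p=config.magnitude_probs)
            eicat_rows.append((sp, mech, mag))
    eicat = pd.DataFrame(eicat_rows, columns=["taxon", "mechanism", "magnitude"])

    return InvasionHistory(
        checklist=checklist, first_records=first_records, eicat=eicat,
        niches=niches, invasive_species=invasive, intro_years=intro_years,
        missing_first_records=frozenset(missing_fr),
        unflagged_listings=frozenset(unflagged),
    )


def generate_occurrences(
    config: ScenarioConfig, world: World, history: InvasionHistory
) -> tuple[pd.DataFrame, int, np.ndarray]:
    """Sample occurrence records under uneven region-by-slice effort.

    Points fall strictly inside the intersection of the species' niche and
    the listed region, years are uniform within each 5-year slice, and a
    configured fraction of rows is duplicated exactly (bookkeeping for the
    deduplication oracle). Returns (records, planted_duplicate_count,
    effort field).
    """
    rng = _rng(config, 2)
    effort = config.sampling_effort * rng.uniform(0.2, 1.0, size=(config.n_regions, config.n_slices))
    region_index = {rid: i for i, rid in enumerate(_region_ids(config.n_regions))}
    t = world.transform
    eps = 1e-9  # keep sampled points off shared tile boundaries

    region_boxes = {
        rid: (t.west + c0 * t.xres, t.north - r1 * t.yres,
              t.west + c1 * t.xres, t.north - r0 * t.yres)
        for rid, (r0, r1, c0, c1) in world.tiles.items()
    }

    rows = []
    rid_counter = 0
    listings = history.checklist[["taxon", "region_id"]].itertuples(index=False)
    for sp, region in listings:
        nw, ns, ne_, nn = history.niches[sp]
        bw, bs, be, bn = region_boxes[region]
        ix0, ix1 = max(nw, bw) + eps, min(ne_, be) - eps
        iy0, iy1 = max(ns, bs) + eps, min(nn, bn) - eps
        if ix1 <= ix0 or iy1 <= iy0:
            continue  # listing outside the niche (possible for tiny overlap)
        intro = history.intro_years.get((sp, region), config.window_start)
        for s in range(config.n_slices):
            year0 = config.window_start + s * config.slice_years
            year1 = year0 + config.slice_years - 1
            if not config.rd_guarantee and year1 < intro:
                continue  # not yet introduced in this slice
            lam = config.base_records_per_slice * effort[region_index[region], s]
            n = int(rng.poisson(lam))
            if config.rd_guarantee:
                n = max(n, config.rd_min_records)
            if n == 0:
                continue
            lons = rng.uniform(ix0, ix1, size=n)
            lats = rng.uniform(iy0, iy1, size=n)
            years = rng.integers(year0, year1 + 1, size=n)
            for lon, lat, year in zip(lons, lats, years):
                if rng.random() < config.bare_year_date_share:
                    date = str(year)
                else:
                    month = int(rng.integers(1, 13))
                    day = int(rng.integers(1, 29))
                    date = f"{year}-{month:02d}-{day:02d}"
                rows.append((f"occ{rid_counter:07d}", sp, float(lat), float(lon), date))
                rid_counter += 1

    occ = pd.DataFrame(rows, columns=["record_id", "taxon", "lat", "lon", "event_date"])
    occ["usable"] = True
    occ["reason"] = ""

    n_dup = int(round(config.duplicate_rate * len(occ)))
    if n_dup:
        picks = rng.integers(0, len(occ), size=n_dup)
        dups = occ.iloc[picks].copy()
        dups["record_id"] = [f"dup{i:07d}" for i in range(n_dup)]
        occ = pd.concat([occ, dups], ignore_index=True)
        perm = rng.permutation(len(occ))
        occ = occ.iloc[perm].reset_index(drop=True)
    return occ, n_dup, effort


def write_fixture_bundle(scenario: Scenario, outdir, overwrite: bool = False) -> dict:
    """Write the scenario as the exact on-disk formats the readers accept.

    Emits Darwin Core–headed delimited tables (checklist, first records,
    occurrences, EICAT), a regions GeoJSON, one georeferenced TIFF per
    climate layer, a ground-truth sidecar (JSON), and a manifest with the
    seed, config hash and per-file SHA-256 checksums. Refuses to touch a
    non-empty directory unless ``overwrite`` is set.
    """
    from pathlib import Path

    from .formats_io import write_grid, write_regions

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [p for p in out.iterdir() if p.name != "manifest.json"]
    if existing and not overwrite:
        raise ConfigError(f"output directory {out} is not empty; pass overwrite to replace")

    cfg, hist = scenario.config, scenario.history
    hist.checklist.rename(
        columns={
            "taxon": "scientificName", "region_id": "locationID",
            "occurrence_status": "occurrenceStatus",
            "establishment_means": "establishmentMeans", "is_invasive": "isInvasive",
        }
    ).to_csv(out / "checklist.csv", index=False)
    hist.first_records.rename(
        columns={"taxon": "scientificName", "region_id": "locationID"}
    ).to_csv(out / "first_records.csv", index=False)
    scenario.occurrences[["record_id", "taxon", "lat", "lon", "event_date"]].rename(
        columns={
            "record_id": "occurrenceID", "taxon": "scientificName",
            "lat": "decimalLatitude", "lon": "decimalLongitude",
            "event_date": "eventDate",
        }
    ).to_csv(out / "occurrences.csv", index=False)
    hist.eicat.rename(columns={"taxon": "scientificName"}).to_csv(
        out / "eicat.csv", index=False
    )
    write_regions(scenario.world.regions, out / "regions.geojson")
    for name, layer in scenario.world.climate.layers.items():
        # climate layers are physical quantities, not [0, 1] suitabilities,
        # so they go through the generic grid writer
        write_grid(layer, scenario.world.transform, out / f"climate_{name}.tif",
                   meta={"layer": name}, nodata=-9999.0)

    truth = {
        "niches": {sp: list(b) for sp, b in hist.niches.items()},
        "invasive_species": sorted(hist.invasive_species),
        "intro_years": {f"{sp}|{rid}": y for (sp, rid), y in sorted(hist.intro_years.items())},
        "missing_first_records": sorted(f"{sp}|{rid}" for sp, rid in hist.missing_first_records),
        "unflagged_listings": sorted(f"{sp}|{rid}" for sp, rid in hist.unflagged_listings),
        "planted_duplicates": scenario.planted_duplicates,
        "effort": scenario.effort.tolist(),
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh)

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    checksums = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "files": checksums,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest


def verify_fixture_bundle(outdir) -> list[str]:
    """Re-hash a bundle against its manifest; returns the names of files
    whose checksum no longer matches (empty list = intact)."""
    from pathlib import Path

    out = Path(outdir)
    with open(out / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    bad = []
    for name, digest in manifest["files"].items():
        p = out / name
        if not p.exists() or hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            bad.append(name)
    return bad


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full synthetic world: regions and climate, invasion
    history with planted gaps, and biased occurrence sampling."""
    world = generate_world(config)
    history = generate_invasion_history(config, world)
    occurrences, n_dup, effort = generate_occurrences(config, world, history)
    return Scenario(
        config=config, world=world, history=history,
        occurrences=occurrences, planted_duplicates=n_dup, effort=effort,
    )
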