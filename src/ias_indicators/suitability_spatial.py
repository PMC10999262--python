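"""Climatic suitability surfaces and the spatial index of potential impact.

The distribution of potential impact is mapped as the per-cell **sum of
relative likelihoods of occurrence** over a priority species subset, with
each species' suitability surface first masked to the regions where that
species is actually listed: climatic suitability projects impact only
within the species' current invaded range.

Surfaces normally come from ecological niche models run elsewhere; any
single-band georeferenced raster with values in [0, 1] on the shared grid
drops in (see :mod:`ias_indicators.formats_io`). For offline, fully
reproducible runs this module also provides a deliberately simple
**rectangular climate-envelope model**: per climate layer, the envelope
spans the presence-value quantiles ``[q, 1-q]``; a cell's score is the
fraction of layers whose value falls inside the envelope, max-rescaled to
[0, 1]. It is a baseline profile method in the BIOCLIM tradition, not a
calibrated niche model — cross-species magnitudes mean nothing beyond the
relative [0, 1] scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import AlignmentError, ValidationError
from .formats_io import RegionSet, SuitabilitySurface, write_grid
from .grid import GridTransform

__all__ = [
    "ClimateStack",
    "SpatialIndex",
    "fit_envelope_suitability",
    "mask_to_regions",
    "region_mask",
    "spatial_index",
    "write_index",
]


@dataclass
class ClimateStack:
    """Named environmental layers sharing one grid and one validity mask."""

    layers: dict[str, np.ndarray]
    transform: GridTransform
    valid: np.ndarray | None = None  # boolean; None means all cells valid

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(a).shape for name, a in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise AlignmentError(f"climate layers differ in shape: {shapes}")
        self.layers = {n: np.asarray(a, dtype=np.float64) for n, a in self.layers.items()}
        if self.valid is None:
            self.valid = np.ones(self.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.shape:
                raise AlignmentError("validity mask shape differs from layers")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)


def fit_envelope_suitability(
    occurrences: pd.DataFrame,
    climate: ClimateStack,
    quantile_clip: float = 0.025,
    min_presences: int = 10,
    nodata: float = -1.0,
) -> SuitabilitySurface:
    """Fit the rectangular climate envelope for one species.

    Parameters
    ----------
    occurrences
        Occurrence table for a single species (columns ``taxon``, ``lat``,
        ``lon``, optionally ``usable``). Presences falling outside the
        grid or on invalid cells are ignored. Duplicate rows have no
        effect on the envelope (quantiles of repeated identical values).
    climate
        Aligned environmental layers.
    quantile_clip
        Fraction clipped from each tail of the per-layer presence values;
        0 uses the full min–max envelope. Default 0.025 trims outlying
        presence records without hollowing out the envelope.
    min_presences
        Refuse to fit below this many usable presence cells-with-values
        (default 10, the same adequacy constant the range-dynamics
        sub-indicator uses).

    Returns a per-species surface in [0, 1], deterministic given inputs.
    """
    if not 0 <= quantile_clip < 0.5:
        raise ValidationError(f"quantile_clip must be in [0, 0.5), got {quantile_clip}")
    taxa = occurrences["taxon"].unique()
    if len(taxa) != 1:
        raise ValidationError(f"expected occurrences of one species, got {list(taxa)}")
    taxon = str(taxa[0])

    occ = occurrences
    if "usable" in occ.columns:
        occ = occ[occ["usable"]]
    row, col = climate.transform.rowcol(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    nrows, ncols = climate.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    row, col = row[inside], col[inside]
    on_valid = climate.valid[row, col]
    row, col = row[on_valid], col[on_valid]
    n = len(row)
    if n < min_presences:
        raise ValidationError(
            f"{taxon!r}: only {n} usable presences on the grid; need at least {min_presences}"
        )

    score = np.zeros(climate.shape, dtype=np.float64)
    for layer in climate.layers.values():
        values = layer[row, col]
        lo = np.quantile(values, quantile_clip)
        hi = np.quantile(values, 1.0 - quantile_clip)
        score += ((layer >= lo) & (layer <= hi)).astype(np.float64)
    score /= len(climate.layers)
    peak = score[climate.valid].max() if climate.valid.any() else 0.0
    if peak > 0:
        score = score / peak
    grid = np.where(climate.valid, score, nodata)
    return SuitabilitySurface(taxon=taxon, grid=grid, transform=climate.transform, nodata=nodata)


def region_mask(
    regions: RegionSet,
    region_ids,
    transform: GridTransform,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean grid of cells whose **center** lies in any named region
    (boundary inclusive)."""
    ids = [rid for rid in region_ids if rid in regions]
    if not ids:
        return np.zeros(shape, dtype=bool)
    union = shapely.union_all([regions[rid] for rid in ids])
    lons, lats = transform.cell_centers(shape)
    xx, yy = np.meshgrid(lons, lats)
    pts = shapely.points(xx.ravel(), yy.ravel())
    return shapely.covers(union, pts).reshape(shape)


def mask_to_regions(
    surface: SuitabilitySurface, regions: RegionSet, listed_regions
) -> SuitabilitySurface:
    """Zero a surface outside the regions where the species is listed.

    Cell-center containment decides membership; nodata cells stay nodata.
    Idempotent for a fixed listed-region set. An empty listed set yields an
    all-zero surface with a warning (the species contributes nowhere).
    """
    listed = sorted(set(listed_regions) & set(regions.ids))
    if not listed:
        warnings.warn(
            f"surface {surface.taxon!r}: no listed regions; masked surface is all zero",
            stacklevel=2,
        )
    mask = region_mask(regions, listed, surface.transform, surface.shape)
    data = surface.data_mask()
    grid = np.where(data & mask, surface.grid, np.where(data, 0.0, surface.nodata))
    return surface.copy_with(grid)


@dataclass(frozen=True)
class SpatialIndex:
    """Per-cell summed, region-masked suitabilities for one subset.

    Values run from 0 to the subset size (the ceiling is attained only
    where every subset species is listed and maximally suitable).
    """

    grid: np.ndarray
    transform: GridTransform
    subset: str
    n_species: int
    missing: tuple = field(default_factory=tuple)
    nodata: float = -1.0


def spatial_index(
    surfaces: dict[str, SuitabilitySurface],
    checklist: pd.DataFrame,
    subset,
    regions: RegionSet,
) -> SpatialIndex:
    """Sum region-masked suitability surfaces over a priority subset.

    Each species' surface is masked to the regions where the checklist
    lists that species, then the masked surfaces are added cell-wise; the
    index is therefore additive over species. Subset species without a
    surface are skipped with a warning and reported in ``missing``. All
    surfaces must share one grid (:class:`AlignmentError` names the
    offender). Cells with no data from any summed species are nodata.
    """
    species = sorted(subset.species)
    listed_by_species = checklist.groupby("taxon")["region_id"].agg(set)

    ref: SuitabilitySurface | None = None
    total = None
    any_data = None
    missing = []
    for sp in species:
        surf = surfaces.get(sp)
        if surf is None:
            missing.append(sp)
            warnings.warn(f"no suitability surface for {sp!r}; skipped", stacklevel=2)
            continue
        if ref is None:
            ref = surf
            total = np.zeros(surf.shape, dtype=np.float64)
            any_data = np.zeros(surf.shape, dtype=bool)
        elif surf.shape != ref.shape or not surf.transform.approx_equal(ref.transform):
            raise AlignmentError(
                f"surface for {sp!r} misaligned with {ref.taxon!r}: "
                f"{surf.shape}/{surf.transform} vs {ref.shape}/{ref.transform}"
            )
        listed = listed_by_species.get(sp, set())
        masked = mask_to_regions(surf, regions, listed)
        data = masked.data_mask()
        total[data] += masked.grid[data]
        any_data |= data

    if ref is None:
        # No surfaces at all: an empty index on a degenerate 0x0 grid would
        # help nobody; report an explicitly empty, all-zero 1x1 descriptor.
        return SpatialIndex(
            grid=np.zeros((0, 0)), transform=GridTransform(0.0, 0.0, 1.0, 1.0),
            subset=subset.label, n_species=0, missing=tuple(missing),
        )
    grid = np.where(any_data, total, -1.0)
    return SpatialIndex(
        grid=grid, transform=ref.transform, subset=subset.label,
        n_species=len(species) - len(missing), missing=tuple(missing),
    )


def write_index(index: SpatialIndex, path) -> None:
    """Write a spatial index as a georeferenced TIFF; the subset descriptor
    is embedded as a metadata tag."""
    write_grid(
        index.grid, index.transform, path,
        meta={"subset": index.subset, "n_species": index.n_species},
        nodata=index.nodata,
    )
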