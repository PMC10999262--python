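"""Information-status indicator: In, Im, Rd, composite, and burden.

Impact indicators are only as reliable as the evidence beneath them. For
each region this module scores three dimensions of that evidence, each as
a percentage of the alien species listed for the region:

* **In** — introduction-date evidence: share of listed species with a
  known year of first introduction in the region.
* **Im** — impact evidence: share of listed species whose regional impact
  has been assessed (the checklist's invasive flag is populated as
  impact-assessed).
* **Rd** — range-dynamics evidence: share of species x time-slice
  combinations with at least ``min_records`` unique occurrence records in
  the region, over consecutive 5-year slices of 1970-2019 by default. The
  threshold is inclusive ("at least"), deliberately low so the target is
  achievable regardless of species rarity.

The **composite** is the unweighted mean of the three. A region with no
listed alien species has *undefined* (not zero) sub-indicators — "nothing
reported" must stay distinguishable from "reported and absent" on maps.
The **information burden** — the count of listed alien species — says how
much evidence a region must curate, and is reported alongside, never
averaged in.

The denominator species set is every alien species listed for the region,
not only the invasive-flagged ones; an optional taxon filter supports
disaggregation by taxonomic group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "RdParams",
    "InformationStatus",
    "compute_In",
    "compute_Im",
    "compute_Rd",
    "compose_status",
    "information_burden",
    "information_status_table",
]


@dataclass(frozen=True)
class RdParams:
    """Window and adequacy parameters for the range-dynamics sub-indicator.

    Defaults: ten 5-year slices spanning 1970-2019, adequacy threshold 10
    records per species per slice. ``since_introduction`` restricts each
    species' denominator to the slices from its regional first record
    onwards (an interpretation variant; the fixed-window default is the
    primary definition).
    """

    window_start: int = 1970
    window_end: int = 2019
    slice_years: int = 5
    min_records: int = 10
    since_introduction: bool = False

    def __post_init__(self) -> None:
        span = self.window_end - self.window_start + 1
        if span <= 0 or span % self.slice_years:
            raise ConfigError(
                f"window {self.window_start}-{self.window_end} not divisible "
                f"into {self.slice_years}-year slices"
            )
        if self.min_records < 1:
            raise ConfigError("min_records must be >= 1")

    @property
    def n_slices(self) -> int:
        return (self.window_end - self.window_start + 1) // self.slice_years

    def slice_of(self, year: int) -> int:
        """0-based slice index of a year inside the window."""
        return (year - self.window_start) // self.slice_years


@dataclass(frozen=True)
class InformationStatus:
    """Per-region information-status record; None marks undefined."""

    region_id: str
    In: float | None
    Im: float | None
    Rd: float | None
    composite: float | None
    burden: int
    flags: str = ""


def _listed_species(checklist: pd.DataFrame, region_id: str,
                    taxon_filter=None) -> pd.Index:
    sel = checklist[checklist["region_id"] == region_id]
    if taxon_filter is not None:
        sel = sel[sel["taxon"].isin(set(taxon_filter))]
    return pd.Index(sel["taxon"].unique())


def compute_In(checklist: pd.DataFrame, first_records: pd.DataFrame,
               region_id: str, taxon_filter=None) -> float | None:
    """Percentage of the region's listed species with a first-record year
    for that region. Undefined (None) when no species are listed."""
    listed = _listed_species(checklist, region_id, taxon_filter)
    if not len(listed):
        return None
    fr = first_records[first_records["region_id"] == region_id]
    with_year = listed.intersection(pd.Index(fr["taxon"].unique()))
    return 100.0 * len(with_year) / len(listed)


def compute_Im(checklist: pd.DataFrame, region_id: str,
               taxon_filter=None) -> float | None:
    """Percentage of the region's listed species whose impact has been
    assessed (invasive flag populated). Undefined when none are listed."""
    listed = _listed_species(checklist, region_id, taxon_filter)
    if not len(listed):
        return None
    sel = checklist[(checklist["region_id"] == region_id) & checklist["is_invasive"]]
    assessed = listed.intersection(pd.Index(sel["taxon"].unique()))
    return 100.0 * len(assessed) / len(listed)


def compute_Rd(checklist: pd.DataFrame, occurrences: pd.DataFrame,
               region_id: str, params: RdParams = RdParams(),
               first_records: pd.DataFrame | None = None,
               taxon_filter=None) -> float | None:
    """Percentage of species x time-slice pairs meeting the adequacy
    threshold.

    ``occurrences`` must already be deduplicated and region-assigned;
    records outside the region or window, or without a year, do not count.
    With ``params.since_introduction`` a species' slices start at its
    regional first record (species without one fall back to the full
    window); ``first_records`` is then required.
    """
    listed = _listed_species(checklist, region_id, taxon_filter)
    if not len(listed):
        return None

    occ = occurrences
    if "usable" in occ.columns:
        occ = occ[occ["usable"]]
    occ = occ[
        (occ["region_id"] == region_id)
        & occ["taxon"].isin(listed)
        & occ["event_year"].notna()
    ]
    years = occ["event_year"].astype(int)
    occ = occ[(years >= params.window_start) & (years <= params.window_end)]

    if len(occ):
        slices = occ["event_year"].astype(int).map(params.slice_of)
        per_pair = occ.groupby([occ["taxon"], slices]).size()
        adequate = per_pair[per_pair >= params.min_records]
    else:
        adequate = pd.Series(dtype=int)

    if not params.since_introduction:
        denominator = len(listed) * params.n_slices
        return 100.0 * len(adequate) / denominator

    if first_records is None:
        raise ConfigError("since_introduction Rd variant requires first_records")
    fr = first_records[first_records["region_id"] == region_id]
    intro = fr.groupby("taxon")["year"].min()
    denominator = 0
    numerator = 0
    adequate_pairs = set(adequate.index)
    for sp in listed:
        first_slice = 0
        if sp in intro.index:
            first_slice = max(0, params.slice_of(int(intro[sp])))
            first_slice = min(first_slice, params.n_slices)
        n_sp_slices = params.n_slices - first_slice
        if n_sp_slices <= 0:
            # introduced after the window: no slices to assess
            continue
        denominator += n_sp_slices
        numerator += sum(
            1 for s in range(first_slice, params.n_slices) if (sp, s) in adequate_pairs
        )
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def compose_status(In: float | None, Im: float | None, Rd: float | None,
                   burden: int, region_id: str = "") -> InformationStatus:
    """Average the three sub-indicators into the composite.

    If any component is undefined the composite is undefined and flagged;
    components are stored at full precision (reports round for display
    only).
    """
    parts = (In, Im, Rd)
    flags = []
    if any(p is None for p in parts):
        composite = None
        missing = [n for n, p in zip(("In", "Im", "Rd"), parts) if p is None]
        flags.append("undefined:" + "+".join(missing))
    else:
        composite = (In + Im + Rd) / 3.0
    return InformationStatus(
        region_id=region_id, In=In, Im=Im, Rd=Rd,
        composite=composite, burden=int(burden), flags=";".join(flags),
    )


def information_burden(checklist: pd.DataFrame, region_id: str,
                       taxon_filter=None) -> int:
    """Number of distinct alien species listed for the region."""
    return len(_listed_species(checklist, region_id, taxon_filter))


def information_status_table(
    checklist: pd.DataFrame,
    first_records: pd.DataFrame,
    occurrences: pd.DataFrame,
    params: RdParams = RdParams(),
    regions: list[str] | None = None,
    taxon_filter=None,
) -> pd.DataFrame:
    """Per-region information status as a tidy table.

    ``regions`` defaults to every region appearing in the checklist; pass
    the full region list to surface no-data rows for regions with no
    listed species. Columns: region_id, In, Im, Rd, composite, burden,
    flags; undefined values are NaN with an explanatory flag.
    """
    if regions is None:
        regions = sorted(checklist["region_id"].unique())
    rows = []
    for rid in regions:
        status = compose_status(
            compute_In(checklist, first_records, rid, taxon_filter),
            compute_Im(checklist, rid, taxon_filter),
            compute_Rd(checklist, occurrences, rid, params,
                       first_records=first_records, taxon_filter=taxon_filter),
            information_burden(checklist, rid, taxon_filter),
            region_id=rid,
        )
        rows.append(status)
    df = pd.DataFrame(
        [
            (s.region_id,
             np.nan if s.In is None else s.In,
             np.nan if s.Im is None else s.Im,
             np.nan if s.Rd is None else s.Rd,
             np.nan if s.composite is None else s.composite,
             s.burden, s.flags)
            for s in rows
        ],
        columns=["region_id", "In", "Im", "Rd", "composite", "burden", "flags"],
    )
    return df
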