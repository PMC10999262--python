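"""Realized and potential impact sub-indicators.

The impact of an invasive alien species (IAS) assemblage is tracked
through *priority species subsets* and expressed two ways:

* a **trend** — the cumulative number of subset species over time, stepped
  at their years of first introduction and held flat ("plateau") from the
  most recent first record to the evaluation year; and
* a **per-region count** — how many subset species are listed in each
  region, the tabular form behind choropleth maps.

Subsets come in two scopes. *Realized* impact rests on region-level impact
evidence: the checklist's invasive flag (total mode), or a region-level
impact-assessment table for mechanism and worst-invader modes — a data
class not yet systematically published, so those two modes raise
:class:`MissingDataError` unless such a table is supplied. *Potential*
impact rests on global EICAT assessments joined to regional presence: a
species assessed anywhere is assumed capable of the same impact wherever
it is established. Within each scope, three modes select the subset:
``total`` (any impact evidence), ``mechanism:<token>`` (one impact
pathway), and ``worst`` (maximum EICAT magnitude major MR or massive MV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingDataError, ParameterError
from .formats_io import MAGNITUDE_RANK

__all__ = [
    "WORST_MAGNITUDES",
    "PrioritySubset",
    "TrendSeries",
    "select_priority_subset",
    "cumulative_trend",
    "region_counts",
    "parse_mode",
]

#: EICAT magnitudes defining the "worst invaders" subset (major, massive).
WORST_MAGNITUDES = frozenset({"MR", "MV"})

_SCOPES = ("realized", "potential")


def parse_mode(mode: str) -> tuple[str, str | None]:
    """Split a mode token into (kind, mechanism). Kinds: total, worst,
    mechanism."""
    if mode == "total" or mode == "worst":
        return mode, None
    if mode.startswith("mechanism:"):
        mech = mode.split(":", 1)[1].strip()
        if mech:
            return "mechanism", mech
    raise ParameterError(
        f"unknown subset mode {mode!r}; expected 'total', 'worst' or 'mechanism:<token>'"
    )


@dataclass(frozen=True)
class PrioritySubset:
    """A resolved priority species subset.

    ``species`` holds canonical names; ``region_filter`` is None for the
    global subset or a region id for the regional one.
    """

    scope: str
    mode: str
    species: frozenset = field(default_factory=frozenset)
    region_filter: str | None = None

    @property
    def label(self) -> str:
        suffix = f"@{self.region_filter}" if self.region_filter else ""
        return f"{self.scope}/{self.mode}{suffix}"

    def __len__(self) -> int:
        return len(self.species)


def _present_species(checklist: pd.DataFrame, region_filter: str | None) -> pd.DataFrame:
    if region_filter is None:
        return checklist
    return checklist[checklist["region_id"] == region_filter]


def select_priority_subset(
    checklist: pd.DataFrame,
    eicat: pd.DataFrame | None,
    scope: str,
    mode: str,
    region_filter: str | None = None,
    regional_assessments: pd.DataFrame | None = None,
) -> PrioritySubset:
    """Resolve the priority species subset for one (scope, mode).

    Parameters
    ----------
    checklist
        Validated checklist (taxon, region_id, is_invasive, ...).
    eicat
        Global assessments (taxon, mechanism, magnitude); needed for
        potential-scope modes.
    scope
        "realized" (regional impact evidence) or "potential" (global
        evidence projected onto regional presence).
    mode
        "total", "worst", or "mechanism:<token>".
    region_filter
        Restrict presence to one region; None means any region.
    regional_assessments
        Optional region-level impact table (taxon, region_id, mechanism,
        magnitude). Required for realized mechanism/worst modes, which the
        published data landscape cannot yet populate.

    Notes
    -----
    Species carrying a global assessment but present in no checklist
    region are excluded from potential subsets — the indicator describes
    the regional IAS assemblage, not the assessment catalogue.
    """
    if scope not in _SCOPES:
        raise ParameterError(f"unknown scope {scope!r}; expected one of {_SCOPES}")
    kind, mechanism = parse_mode(mode)
    present = _present_species(checklist, region_filter)

    if scope == "realized":
        base = set(present.loc[present["is_invasive"], "taxon"])
        if kind == "total":
            species = base
        else:
            if regional_assessments is None:
                raise MissingDataError(
                    f"realized/{mode} requires a regional impact-assessment table; "
                    "regional mechanism and magnitude evidence is not currently "
                    "available from published checklists"
                )
            ra = regional_assessments
            if region_filter is not None:
                ra = ra[ra["region_id"] == region_filter]
            species = base & _evidence_species(ra, kind, mechanism)
    else:
        if eicat is None:
            raise ParameterError("potential-scope subsets require an EICAT table")
        species = set(present["taxon"]) & _evidence_species(eicat, kind, mechanism)

    return PrioritySubset(
        scope=scope, mode=mode, species=frozenset(species), region_filter=region_filter
    )


def _evidence_species(assessments: pd.DataFrame, kind: str, mechanism: str | None) -> set:
    """Species selected by an assessment table under one mode kind."""
    if not len(assessments):
        return set()
    if kind == "total":
        return set(assessments["taxon"])
    if kind == "mechanism":
        return set(assessments.loc[assessments["mechanism"] == mechanism, "taxon"])
    ranks = assessments["magnitude"].map(MAGNITUDE_RANK)
    max_rank = ranks.groupby(assessments["taxon"]).max()
    worst_rank = min(MAGNITUDE_RANK[m] for m in WORST_MAGNITUDES)
    return set(max_rank.index[max_rank >= worst_rank])


@dataclass(frozen=True)
class TrendSeries:
    """Yearly cumulative species count for one subset.

    The series runs from the subset's earliest first record to the
    evaluation year; its value at year *t* is the number of subset species
    first recorded at or before *t*. After the most recent first record
    the series is flat: the current indicator value is taken to sit at the
    level of the latest introduction on record. Species lacking any usable
    first record cannot enter the series; they are carried in
    ``uncounted`` and reported, not silently dropped.
    """

    subset: str
    mode: str
    years: np.ndarray
    counts: np.ndarray
    uncounted: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.years)

    @property
    def final_value(self) -> int:
        return int(self.counts[-1]) if len(self.counts) else 0

    def value_at(self, year: int) -> int:
        """Cumulative count at an arbitrary year (0 before the series)."""
        if not len(self.years) or year < self.years[0]:
            return 0
        i = min(int(year - self.years[0]), len(self.counts) - 1)
        return int(self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": self.subset,
                "mode": self.mode,
                "year": self.years,
                "cumulative_count": self.counts,
            }
        )


def cumulative_trend(
    subset: PrioritySubset,
    first_records: pd.DataFrame,
    eval_year: int | None = None,
) -> TrendSeries:
    """Build the cumulative-introductions trend for a priority subset.

    For a global subset each species counts once, at its earliest first
    record across regions; for a region-filtered subset the region's own
    first record is used. ``eval_year`` (default: latest relevant record)
    must not precede the latest first record in the subset.
    """
    fr = first_records[first_records["taxon"].isin(subset.species)]
    if subset.region_filter is not None:
        fr = fr[fr["region_id"] == subset.region_filter]
        years_by_species = fr.groupby("taxon")["year"].min()
    else:
        years_by_species = fr.groupby("taxon")["year"].min()

    uncounted = frozenset(subset.species - set(years_by_species.index))
    if not len(subset.species):
        warnings.warn(f"empty subset {subset.label}; empty trend series", stacklevel=2)
    if not len(years_by_species):
        return TrendSeries(
            subset=subset.label, mode=subset.mode,
            years=np.array([], dtype=int), counts=np.array([], dtype=int),
            uncounted=uncounted,
        )

    first = int(years_by_species.min())
    last = int(years_by_species.max())
    if eval_year is None:
        eval_year = last
    if eval_year < last:
        raise ParameterError(
            f"eval_year {eval_year} precedes the latest first record {last} in {subset.label}"
        )
    years = np.arange(first, eval_year + 1)
    # step function: count of species with first record <= t
    counts = np.searchsorted(np.sort(years_by_species.to_numpy()), years, side="right")
    return TrendSeries(
        subset=subset.label, mode=subset.mode,
        years=years, counts=counts.astype(int), uncounted=uncounted,
    )


def region_counts(
    checklist: pd.DataFrame,
    eicat: pd.DataFrame | None,
    scope: str,
    modes: list[str] | None = None,
    regions: list[str] | None = None,
    regional_assessments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region species counts for a family of subset modes.

    Counting is species-level: a species with two assessed mechanisms adds
    one to each mechanism's count but only one to the total. Returns a
    long table (region_id, mode, count) joinable to the region GeoJSON.

    ``modes`` defaults to total, worst, and one ``mechanism:<m>`` per
    mechanism present in the evidence table of the given scope.
    """
    if regions is None:
        regions = sorted(checklist["region_id"].unique())
    if modes is None:
        modes = ["total", "worst"]
        evidence = regional_assessments if scope == "realized" else eicat
        if evidence is not None and len(evidence):
            modes += [f"mechanism:{m}" for m in sorted(evidence["mechanism"].unique())]

    rows = []
    for rid in regions:
        for mode in modes:
            subset = select_priority_subset(
                checklist, eicat, scope, mode,
                region_filter=rid, regional_assessments=regional_assessments,
            )
            rows.append((rid, mode, len(subset)))
    return pd.DataFrame(rows, columns=["region_id", "mode", "count"])
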