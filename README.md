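# ias-indicators

Indicators of the environmental impacts of invasive alien species (IAS)
and of the adequacy of the information behind them, computed from
GRIIS-style regional checklists, first-introduction records, Darwin
Core occurrence data, global EICAT impact assessments and per-species
climatic-suitability surfaces.

The package is aimed at invasion ecologists and biodiversity-informatics
practitioners who need reproducible, country-by-country indicator values
of the kind called for by Target 6 of the Kunming–Montreal Global
Biodiversity Framework: *which* IAS impacts are growing, *where* they are
distributed, and *how much the underlying evidence can be trusted*.

## The indicators

**Impact indicators** are computed over *priority species subsets* in two
scopes:

- *realized* impact — species with region-level impact evidence (the
  checklist's `isInvasive` flag; region-level mechanism/magnitude modes
  are implemented but require a regional assessment table that published
  data cannot yet supply);
- *potential* impact — species present in a region whose impact has been
  assessed globally under EICAT (Environmental Impact Classification for
  Alien Taxa), on the assumption that a species impactful anywhere is
  potentially impactful wherever it is established.

Within each scope three modes select the subset: **total** (any impact
evidence), **mechanism:`<m>`** (one impact pathway, e.g. predation), and
**worst** (maximum EICAT magnitude MR "major" or MV "massive"). Each
subset is expressed as:

- a **trend** — the cumulative number of subset species over time,
  stepped at years of first introduction and held flat from the most
  recent first record to the evaluation year;
- **per-region counts** of subset species (the tabular form of the
  indicator maps); and
- the **spatial index of potential impact**

  *I*(x) = Σ_s  m_s(x) · p_s(x),

  the per-cell sum over subset species *s* of climatic suitability
  *p_s* ∈ [0, 1], masked by m_s(x) ∈ {0, 1} to the regions where *s* is
  actually listed.

**Information-status indicator** — for each region, three percentages
over the alien species listed there:

- *In*, species with a known year of first introduction;
- *Im*, species whose regional impact has been assessed;
- *Rd*, species × 5-year-slice combinations (1970–2019) with at least 10
  unique occurrence records;

their unweighted mean (the composite), and the **information burden**
(number of listed alien species). A region with no listed species is
*no-data*, never zero.

## Worked example

Generate a small synthetic world (regions tiling a grid, species with
rectangular niches, seeded sampling effort and reporting gaps), then run
the indicators on it:

```bash
ias-indicators simulate --seed 7 --out bundle \
    --n-regions 12 --n-species 20 --n-invasive 5

cat > run.yaml <<'EOF'
inputs:
  checklist: bundle/checklist.csv
  first_records: bundle/first_records.csv
  occurrences: bundle/occurrences.csv
  eicat: bundle/eicat.csv
  regions: bundle/regions.geojson
  climate: [bundle/climate_temperature.tif, bundle/climate_moisture.tif]
subsets:
  - {scope: potential, mode: total}
  - {scope: potential, mode: worst}
  - {scope: realized, mode: total}
eval_year: 2020
output_dir: out
EOF

ias-indicators impact --config run.yaml
ias-indicators info-status --config run.yaml
```

which prints

```
potential/total: 5 species, trend final 4
potential/worst: 2 species, trend final 2
realized/total: 5 species, trend final 4
information status for 12 regions written to out
```

Read: 5 of the 20 species carry global impact evidence (2 of them with
major/massive maximum magnitude); 4 of the 5 have at least one dated
first record, so the cumulative trend plateaus at 4 while the fifth is
reported as uncounted in the log. `out/` then contains `trends.csv`
(`subset, mode, year, cumulative_count`), `region_counts.csv`
(`region_id, mode, count`, joinable to `regions.geojson` for maps),
one `spatial_index_*.tif` per potential subset, and
`information_status.csv` (`region_id, In, Im, Rd, composite, burden,
flags`), e.g.

```
region_id,In,Im,Rd,composite,burden,flags
R000,100,0,0,33,5,
R001,83,17,0,33,6,
```

— region R000 has first-record years for all 5 listed species (In = 100)
but no impact assessments (Im = 0) and inadequate occurrence coverage
(Rd = 0), so its composite information status is 33%.

Real data drop in the same way: delimited tables with Darwin Core–style
headers (configurable via the `dialect` mapping), RFC 7946 GeoJSON
regions, and single-band georeferenced GeoTIFF suitability surfaces from
any niche-modelling tool (values in [0, 1], shared grid) via
`inputs.surfaces_dir`. The built-in rectangular climate-envelope model is
a deliberately simple offline stand-in, not a calibrated niche model; see
`docs/methods.md`.

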