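# baar — deforestation risk mapping and nested REDD+ baseline allocation

`baar` implements the *baseline allocation for assessed risk* (BAAR)
workflow for nested REDD+ programs: it maps near-term deforestation risk
from historical forest-loss patterns, validates the candidate risk maps
against a held-out period, and distributes a jurisdictional forest
reference emission level (FREL, tCO₂e/yr) to high/low-risk strata and
nested project accounting areas with carbon-stock weighting. It is aimed at
analysts and program designers who need transparent, reproducible
project-level baselines that stay consistent with a national FREL and NDC
target.

## The model

The premise is that the strongest spatial predictor of future deforestation
is past deforestation. Working on categorical rasters in an equal-area
projection, the pipeline runs in three phases:

**1. Exploratory risk mapping.** Contiguous forest blocks under 5,000 ha
are removed; contiguous deforestation patches of at least 0.18 ha (two
30 m pixels) from the calibration period are extracted. Each patch of area
*aₚ* is buffered outward by the dynamic radius

```
r_high = √((aₚ·m + aₚ)/π) − √(aₚ/π)
```

the ring width that multiplies the patch's equivalent circle by the area
multiple *m*, so larger patches — stronger frontiers — project risk
further. Forest inside any buffer is **high risk**; the remaining eligible
forest is **low risk**. A series of maps is built over a sweep of
multiples (canonically m = 1…120).

**2. Production risk mapping.** Each map is scored against the validation
period:

- predictive power `PP = 100 · A_def_high / A_def` (share of validation
  loss captured by the high-risk stratum),
- scaled predictive power `PPs = PP · n_cal / n_val` (period-length
  correction),
- precision `Pr = 100 · A_def / A_high`,
- minimum project efficacy `MPE = NDC / PPs` (both as fractions): the
  share of the high-risk area that must remain forest to meet the NDC
  target given the map's quality. A perfect map gives `MPE = NDC`.

The production map is the candidate whose MPE is the median among feasible
(MPE < 100%) candidates.

**3. Allocation.** The FREL is split between strata by a policy ratio
(e.g. 90:10), spread uniformly per hectare within each stratum, and
re-weighted by relative forest-type carbon stock (mean-preserving within
each stratum, so the jurisdictional total is untouched). Each project is
credited over its project accounting area (PAA) — the part of its polygon
continuously forested for the 10 years before the project start — by
summing the per-cell densities.

A seeded synthetic-landscape generator (`baar.synthetic_landscape`)
produces forest histories with validation loss clustered near calibration
patches, so the whole pipeline is testable without the (undistributed)
national rasters.

## Worked example

The bundled 80 × 80 toy landscape has four hand-placed calibration patches
(4, 9, 2 and 16 ha, lost 2005), ten validation-period cells (2012), two
forest types (747 vs 409 tCO₂e/ha) and two projects starting 2015:

```python
import numpy as np
import baar
import baar.patch_analysis as pa
import baar.risk_model as rm
import baar.evaluation as ev
import baar.allocation as al

history, carbon, projects, _ = baar.fixture_small()

eligible = pa.extract_eligible_forest(history.forest_t0)
calib = pa.period_defor_mask(history, 2000, 2010)
patches = pa.label_patches(calib)
print(f"{len(patches)} calibration patches, {patches.total_area_ha:.0f} ha")

eligible_now = eligible.like(
    (eligible.values.astype(bool)
     & (history.forest_remaining(2010).values == 1)).astype(np.int32))
valid = pa.period_defor_mask(history, 2010, 2014)

maps = rm.risk_map_series(patches, eligible_now, [1, 6, 45])
periods = ev.PeriodConfig(10, 4)
policy = ev.PolicyConfig(ndc_percent=21.0, frel_annual=10_000.0)
results = ev.evaluate_series(maps, valid, patches.total_area_ha, periods, policy)
print(ev.write_results(results, split_high=90.0).round(3).to_string(index=False))

chosen = ev.select_m(results)
print(f"selected m={chosen.m} (MPE {chosen.mpe:.1f}%)")

risk = maps[[r.m for r in maps].index(chosen.m)]
config = al.AllocationConfig(frel_annual=10_000.0, split_high=90.0, split_low=10.0)
dens = al.carbon_weighted_densities(al.stratum_densities(config, risk), carbon, risk)
for project in projects:
    paa = al.derive_paa(project, history)
    b = al.allocate_project(paa, risk, dens, project_id=project.project_id)
    print(f"project {b.project_id}: PAA {b.paa_area:.0f} ha, "
          f"baseline {b.baseline_weighted:,.0f} tCO2e/yr "
          f"({b.per_ha:.2f} tCO2e/ha/yr)")
```

prints

```
4 calibration patches, 31 ha
 m  aggregate_multiple   pp   pps     pr  efficiency  frel_high_share  mpe
 1               1.032 40.0 100.0 31.250      12.500             90.0 21.0
 6               6.645 80.0 200.0  4.854       3.883             90.0 10.5
45              47.161 80.0 200.0  0.684       0.547             90.0 10.5
selected m=6 (MPE 10.5%)
project 1: PAA 394 ha, baseline 1,877 tCO2e/yr (4.76 tCO2e/ha/yr)
project 2: PAA 383 ha, baseline 2,652 tCO2e/yr (6.92 tCO2e/ha/yr)
```

Reading the table: at m = 1 the buffers of the two smallest patches do not
yet reach their neighbouring cells, so only 40% of the validation loss is
captured; by m = 6 every near-patch loss cell is inside a buffer (PP 80%),
and pushing on to m = 45 only inflates the high-risk area (precision falls
from 4.9% to 0.7% with no PP gain). With a 10-year calibration and 4-year
validation period PPs doubles PP; the 21% NDC target then requires 10.5%
minimum project efficacy on the selected map. Project 2's baseline per
hectare is higher than project 1's because its PAA sits mostly in the
high-risk stratum and partly in denser forest.

The same pipeline runs from the shell:

```bash
baar simulate --seed 42 --out run/sim --rows 120 --cols 120
baar risk-map --forest run/sim/forest_t0.asc --defor-year run/sim/defor_year.asc \
     --m-list 1,6,45 --min-forest-ha 3000 --out run/risk
baar evaluate --forest run/sim/forest_t0.asc --defor-year run/sim/defor_year.asc \
     --risk-dir run/risk --ndc 21 --frel 100000 --out run/eval
baar allocate --forest run/sim/forest_t0.asc --defor-year run/sim/defor_year.asc \
     --risk-map run/risk/risk_m45.asc --frel 100000 --split 90:10 \
     --carbon-table run/sim/carbon_table.csv --strata run/sim/strata.asc \
     --projects run/sim/projects.geojson --out run/alloc
```

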