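# birdrisk

Count-based bird strike risk assessment for airfields.

Bird strikes — collisions between birds and aircraft, mostly during takeoff
and landing — are a persistent flight-safety hazard. Airfields that already
run systematic bird counts, strike reporting and movement logging can turn
those counts into a *leading* risk indicator: a number that rises before a
strike happens, so bird-control units can act on specific species in time.
`birdrisk` is a library and CLI for bird-control units, airfield safety
managers and the ecologists supporting them.

## The two indices

**Species Strike Impact** — the risk posed by one individual of species *i*
on the airfield, combining strike probability and severity:

```
SSI_i = ln(BS_ratio_i / density_i + 1) × mass_i
```

with `BS_ratio_i` the species' strikes per 10,000 aircraft movements,
`density_i` its mean abundance in birds per 10 ha over all transect counts,
and `mass_i` its body mass in kg. Species counted but never struck receive a
floor strike ratio (default 0.0035 per 10,000 movements); species struck but
never counted get SSI predicted from a power regression on body mass.

**Bird Strike Risk Index** — the aggregate risk of one runway inspection,
in which birds are recorded per species in count classes (1–2, 3–5, …,
\>1000):

```
BSRI = ln( Σ_i n_i × SSI_i + 1 )
```

with `n_i` the class middle of the recorded class. Thresholds calibrated as
the 80% and 95% empirical quantiles of a pooled BSRI reference set assign a
local bird status — normal, **alert** or **critical** — which is validated
against the statuses logged by bird-control observers via a confusion
matrix. Monthly OLS trends and cyclic-spline seasonal profiles summarise the
long-term record. A synthetic-data generator produces complete multi-airbase
scenarios with known ground truth for testing and training.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Three species at a 500 ha airfield, 60,000 movements over three years, five
transect counts, three strikes:

```python
from datetime import date, datetime
from birdrisk import (SpeciesProfile, CountSurvey, StrikeRecord, MovementEntry,
                      AirbaseProfile, InspectionRecord, build_ssi_table,
                      compute_bsri, assign_status, DEFAULT_THRESHOLDS)

airbase = AirbaseProfile("meadow_afb", 500.0, date(2020, 1, 1), date(2022, 12, 31))
movements = [MovementEntry("meadow_afb", y, 20_000) for y in (2020, 2021, 2022)]
species = [SpeciesProfile("buzzard", "Common Buzzard", 0.85),
           SpeciesProfile("jackdaw", "Western Jackdaw", 0.24),
           SpeciesProfile("lapwing", "Northern Lapwing", 0.21)]
surveys = [CountSurvey(date(2021, 5, 3), "meadow_afb", "buzzard", 4),
           CountSurvey(date(2021, 5, 3), "meadow_afb", "jackdaw", 60),
           CountSurvey(date(2021, 5, 6), "meadow_afb", "buzzard", 2),
           CountSurvey(date(2021, 5, 6), "meadow_afb", "jackdaw", 40),
           CountSurvey(date(2021, 5, 6), "meadow_afb", "lapwing", 150)]
strikes = [StrikeRecord(date(2021, 6, 1), "meadow_afb", "buzzard", "takeoff"),
           StrikeRecord(date(2022, 4, 9), "meadow_afb", "buzzard", "landing"),
           StrikeRecord(date(2022, 7, 2), "meadow_afb", "jackdaw", "landing")]

entries, _ = build_ssi_table(strikes, surveys, movements, species, [airbase])
for e in entries:
    print(f"{e.species_id:8s} strikes={e.n_strikes} ratio={e.bs_ratio:.4f} "
          f"density={e.density:.3f} ssi={e.ssi:.4f} ({e.method})")

insp = InspectionRecord(datetime(2022, 7, 2, 7), "meadow_afb",
                        {"buzzard": "1-2", "jackdaw": "26-50"}, "alert")
res = compute_bsri(insp, {e.species_id: e.ssi for e in entries})
print(f"BSRI = {res.bsri:.4f}")
print("status:", assign_status(res.bsri, DEFAULT_THRESHOLDS))
```

prints

```
buzzard  strikes=2 ratio=0.3333 density=0.060 ssi=1.5983 (observed)
jackdaw  strikes=1 ratio=0.1667 density=1.000 ssi=0.0370 (observed)
lapwing  strikes=0 ratio=0.0035 density=1.500 ssi=0.0005 (floor)
BSRI = 1.5693
status: normal
```

Two strikes on a scarce, heavy buzzard give it an SSI forty times the
jackdaw's, even though jackdaws outnumber buzzards more than tenfold on the
field: the jackdaw is struck rarely *relative to its abundance* and is
light. Lapwings, never struck, sit at the floor. The inspection — a pair of
buzzards and a few dozen jackdaws on the runway — scores BSRI 1.57, well
below the default alert threshold of 3.1, so the field stays at status
normal.

## Command line

```
birdrisk synth    --out scenario/ --seed 1          # generate a test scenario
birdrisk summary  --from-summary rows.csv --out summary.csv
birdrisk ssi      --strikes ... --surveys ... --movements ... \
                  --species ... --airbases ... --out ssi_table.csv
birdrisk bsri     --inspections ... --ssi-table ssi_table.csv --out bsri.csv
birdrisk validate --bsri bsri.csv --out report.json
birdrisk trends   --bsri bsri.csv --out-dir trends/ --plots
```

All commands are deterministic functions of their inputs, config (YAML via
`--config`: class middles, quantiles, fixed thresholds, floor settings) and
seed.

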