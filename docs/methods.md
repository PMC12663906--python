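# Methods

## The problem and the two indices

Airfields are grasslands, grasslands attract birds, and birds collide with
aircraft during takeoff and landing. A bird-control unit needs a *leading*
indicator: a number computed from what is on the field right now, before any
strike happens. `birdrisk` implements a count-based pair of indices for that
purpose.

**Species Strike Impact (SSI)** scores the risk posed by one individual of
species *i*:

    SSI_i = ln(BS_ratio_i / density_i + 1) * mass_i

* `BS_ratio_i` — strikes of species *i* per 10,000 aircraft movements,
  pooled over all airbases and years. A movement is one takeoff or one
  landing; touch-and-gos count as both. Only *local* strikes enter (flight
  phases final approach, landing, touch-and-go, takeoff, climb) and only
  strikes identified to species level.
* `density_i` — mean abundance in birds per 10 ha over **all** transect
  survey occasions (a survey on which the species was not seen contributes
  zero), pooled across airbases.
* `mass_i` — mean body mass in kg, the severity proxy: impact energy and
  damage scale strongly with mass.

The quotient `BS_ratio/density` is a per-individual strike propensity: how
often the species is hit relative to how often it is present. The `ln(x+1)`
transform tames the heavy right tail of count data and makes SSI exactly
zero for a species with no strikes and any positive density.

**Bird Strike Risk Index (BSRI)** aggregates one runway inspection:

    BSRI = ln( sum_i n_i * SSI_i + 1 )

where `n_i` is the *class middle* of the count class recorded for species
*i* (inspection counts are binned: 1–2, 3–5, 6–10, 11–25, 26–50, 51–100,
101–250, 251–500, 501–1000, >1000). An inspection with no birds scores 0.

## Species without both data streams

Three cases need a rule beyond the formula:

* **observed** — ≥1 strike and positive density: the formula applies
  directly.
* **floor** — counted on the field (density ≥ 0.001 birds/10 ha) but never
  struck: the strike ratio is bounded above by "less than one strike over
  the whole movement record". We use that bound as a usable number,
  default `floor_ratio = 0.0035` per 10,000 movements (≈ one strike in 2.9
  million movements); `floor_mode="from_movements"` derives it as
  10,000/total movements instead. Entries are flagged `floor` because the
  value is an upper-bound estimate.
* **regression** — struck but never counted (typical of owls: rare, active
  at night): `BS_ratio/density` is undefined and any direct value would be
  unreliable. SSI is instead predicted from a power regression
  `SSI = a * mass^b`, fitted by OLS on the log-log scale to the `observed`
  and `floor` entries only (no circularity). The fit refuses to run with
  fewer than 3 points or zero mass spread.

Never-struck species below the eligibility density are omitted: there is no
evidence of presence worth scoring. The eligibility cutoff is the arbiter
between the floor rule and omission; the regression is reserved for species
with strikes but no counts.

## Thresholds and statuses

Local bird status (normal / alert / critical) is assigned from BSRI with two
thresholds calibrated as empirical quantiles of a pooled reference set of
BSRI values: the 80% quantile for alert, 95% for critical. The quantile is
the order statistic at rank ceil(q·n) — the smallest value with at least a
fraction q of the set at or below it — rather than an interpolated quantile,
so the threshold is always an attained value and reproducible across
implementations. Status comparisons are strictly greater-than, so a value
sitting exactly on a threshold keeps the lower status and at least 80% / 95%
of the calibration set classifies at or below alert / critical. When no
local calibration data exist, the published reference values 3.1 (alert) and
3.7 (critical) are the defaults.

Class middles default to the arithmetic midpoint of the class bounds
(1–2 → 1.5, …, 501–1000 → 750.5). The open class ">1000" has no midpoint;
its default representative value 1500 is a declared convention and, like all
middles, configurable.

Validation compares the BSRI-derived status with the status the bird-control
observer logged, as a 3×3 confusion matrix with overall accuracy and
per-class recall/precision (undefined cells are reported as missing, not
zero). Inspections with unknown observer status — nocturnal or
low-visibility rounds — are excluded from validation but still scored.

## Trends and seasonality

Long-term change is summarised as OLS of monthly mean BSRI on time in
fractional years, per airbase, over the whole record and over the last 120
calendar months, reported as slope per year with adjusted R² and residual
df (n − 2). The time covariate is centred at the period midpoint for
conditioning; centring does not change the slope.

Seasonal structure is a smoothed profile of daily mean BSRI on the 1–366
day-of-year grid. The smoother minimises

    sum_d w_d (f_d − y_d)^2 + λ sum_d (f_{d−1} − 2 f_d + f_{d+1})^2

with circular indexing, i.e. a discrete cyclic smoothing spline; λ is chosen
by generalized cross-validation over a log-spaced grid (10⁻² … 10⁶) unless
fixed. The smoother is linear in the daily means, reproduces constants
exactly, is periodic by construction (day 366 adjacent to day 1), and tends
to the grand mean of the observed days as λ → ∞. We deliberately specify the
smoother by these properties rather than by equivalence to any particular
GAM implementation: the scientific content is the periodic penalized fit,
not a package's exact output.

## The synthetic-data generator

`birdrisk.synth` generates complete multi-airbase datasets with known ground
truth, so every stage is testable end to end. Per species it draws a body
mass (log-normal, median 0.3 kg, σ = 1.1 on the log scale — passerines to
geese), a mean density (log-normal, median 0.08 birds/10 ha), a sinusoidal
seasonal cycle (amplitude U(0, 0.7), random phase) and a strike proneness
(log-normal, the relative per-encounter collision probability). Then:

* transect counts are negative binomial (dispersion 2) around
  density × seasonal factor × area/10 — birds flock, so counts are
  overdispersed, which stresses the class binning and the BSRI tail;
* runway inspection counts draw from the runway subpopulation (25% of the
  field density) with stronger overdispersion (0.6) and are binned into the
  fixed classes;
* strikes are Poisson with rate proneness × density × total movements ×
  `strike_scale` (3.5·10⁻⁴), allocated to airbases proportional to their
  movements; 9% of records get an unidentified species and 5% a non-local
  flight phase, exercising the strike filter;
* each inspection's observer status is the status implied by its *true*
  BSRI (ground-truth SSI, thresholds calibrated at the configured quantiles
  over the generated set), flipped to an adjacent status with probability
  `observer_noise` (default 0.10).

Defaults describe a six-airbase programme — two transect counts a week, four
runway inspections a day, 10–35 thousand movements per airbase-year — over
five years. Five years is the package's chosen record length for a standard
scenario: long enough for trend and seasonal structure, small enough that a
full scenario generates and analyses in seconds; real multi-decade archives
are simply longer, not structurally different.

Because the observer labels are derived from the true BSRI, a pipeline run
that scores inspections with the generator's exported ground-truth SSI table
and thresholds reproduces the labels *exactly* when `observer_noise = 0`
(validation accuracy 100%), and with noise ε the expected accuracy is
1 − ε. When SSI is instead re-estimated from the realized (Poisson-noisy)
strikes, inspections near a threshold can flip status, so agreement is high
but not identically 100% — this is a property of estimation, not a defect.

What the generator does **not** emulate: territorial behaviour, weather,
habitat differences between airbases, observer effort variation, and
correlated multi-species flocking. Passing tests therefore demonstrate that
the pipeline recovers the parameters of this statistical structure, not that
the indices capture every feature of real airfield ecology.

## Numerical and design choices

* Natural logarithm throughout.
* SSI is computed on the pooled multi-airbase dataset (total strikes /
  total movements, density over all surveys); per-airbase computation is
  possible by subsetting the inputs but is not the default.
* The unknown-species sentinel is the reserved string `UNKNOWN`; rejected
  as a species id at profile load, so the strike filter is well defined.
* Flight phases outside the five local ones map to `other` and are dropped
  by the default filter.
* Percentage-table reconstruction (species-known counts from a printed
  per-airbase percentage) rounds half away from zero per airbase, then
  sums.
* Ties in SSI sorting break by species id for deterministic output.
* Problem sizes in tests and the acceptance script (scenarios of 2–6
  airbases, 10–25 species, 2–5 years; 120-month trend series) are the
  package's standard scaled scenario sizes described above.

## Known limitations

* SSI carries no uncertainty interval; a species with one strike has a
  noisy ratio, visible only through `n_strikes` in the output table.
* The floor value is a bound treated as a number; ranking among floor
  species reflects density and mass only.
* Calibrated thresholds are pooled across airbases; a field whose BSRI
  distribution differs strongly from the pool (e.g. multiple independent
  runways) should calibrate per runway.
* The class-middle convention for ">1000" is arbitrary above 1000 birds;
  inspections in that class are rare but their BSRI depends directly on it.
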