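# rayvisits

Visitation analysis for passive acoustic telemetry arrays: a tested,
reusable pipeline for asking *how often, how long, and under which
conditions do tagged animals use a monitored habitat?* The package was
built around a concrete system — whitespotted eagle rays (*Aetobatus
narinari*) and cownose rays (*Rhinoptera* spp.) visiting hard-clam
aquaculture leases and nearby inlet/river-mouth reference sites in the
Indian River Lagoon near Sebastian, FL — but every stage is generic to
array-based telemetry studies.

It is aimed at movement ecologists who have receiver-download CSVs, tag
and receiver metadata, tide predictions and water-quality series, and who
want the full chain from raw detections to mixed-model inference in
scriptable Python.

## What it computes

**Detection filtering** (`rayvisits.io`). Exact duplicates are dropped; a
reproducible isolation rule flags suspected tag-collision false positives
(a detection with fewer than `min_hits` same-transmitter detections within
±`window_min` anywhere in the array is removed). Study-window clipping is
inclusive of the end date.

**Covariate annotation** (`rayvisits.annotate`). Day/night classification
on a local-clock window (default 07:00–18:59 day, 19:00–06:59 night,
derivable from mean sunrise/sunset at the array); illuminated moon
fraction from a truncated lunar-ephemeris series; astronomical seasons and
12-month study years; and tide state (High / Incoming / Low / Outgoing,
±1/8-cycle slack bands around extrema) lagged per receiver using the tidal
rate of movement

    TRM = d / ΔT,        lag_receiver = distance / TRM,

with defaults d = 3,698 m and ΔT = 2 h 20 min between an inlet and
river-mouth reference pair (TRM ≈ 0.44 m s⁻¹).

**Visit extraction** (`rayvisits.visits`). A *visit* (residence event) is
a maximal run of same-receiver detections of one transmitter whose
inter-detection gaps never exceed a time-out; a detection at a new
receiver, or a gap strictly greater than the time-out, terminates it. The
time-out is derived from detection geometry and swimming speed,

    timeout = 60 · (detection diameter / 1000) / rate of movement  [min],

giving 17.1 min for a 400 m diameter traversed at 1.4 km h⁻¹. The same
17.1-min threshold separates short from long visits (long: duration
strictly > threshold). Visits need at least two detections.

**Summaries** (`rayvisits.summarize`). Per-species × per-receiver
detection counts with within-species proportions; diel split means (per
tag-date counting units) and totals; visit-duration tables (N, range,
mean ± SE, total time) with margins; visit-time proportions by receiver
group; long-visit counts.

**Models** (`rayvisits.models`). A Poisson GLMM for detection counts with
a diel × receiver × sex interaction and a per-transmitter random
intercept, fit by adaptive Gauss–Hermite quadrature, with Tukey-adjusted
pairwise contrasts on estimated marginal means; a Gamma GAMM for visit
duration (cyclic smooth of decimal hour, smooths of moon fraction,
temperature, salinity and dissolved oxygen, parametric tide state and
general location, ridge-penalized random intercept; inverse link attempted
first with a flagged log-link fallback); a correlation + VIF collinearity
screen; and AICc all-subsets ("dredge"-style) model selection.

**Synthetic telemetry** (`rayvisits.simdata`). A seeded generator —
diel-weighted continuous-time movement among the six named sites,
Gamma-distributed occupancy bouts with log-linear covariate effects,
uniform-interval tag transmissions thinned by detection probability,
spurious detections, and collinear environmental series — so every stage
can be validated against known ground truth.

## Worked example

`examples/01_simulate_and_extract_visits.py` simulates a 30-day, 8-tag
deployment and runs the extraction chain:

```
simulated 2,321 detections from 8 tags
isolation filter removed 17 suspected false detections
time-out = 17.1 min (400 m diameter at 1.4 km/h)
67 visits extracted; 47 exceed the 17.1-min threshold
an ideal (probability-1) detector would have reported 67 visits
```

The extracted visit count equals the ideal-detector count because the
detection probability (0.9) is high and ping intervals are far below the
time-out. `examples/03_summary_tables.py` recomputes the reported shares
from the bundled two-year study tables:

```
eagle-ray share of detections at SINJ: 64.5 %
pooled cownose share at the clam leases: 11.3 %
total visits across species: 17014
eagle-ray total visit time: 413583.3 min
eagle rays spent 85.3% of visit time at the inlet receivers
Atlantic cownose rays spent 41.6% of visit time over the clam leases
```

i.e. eagle rays concentrated at the inlet while cownose rays put a large
minority of their visit time over the clam leases. The remaining examples
(`02` covariate annotation, `04` detection GLMM, `05` duration GAMM with
collinearity screen and AICc selection) each print the fitted quantities
next to the values used to generate the data.

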