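# Methods

This note records the scientific and numerical choices behind the
package, in the spirit of a model-description vignette: what is assumed,
what is tunable, what the synthetic data do and do not emulate, and where
the genuinely open design decisions were resolved.

## Detection filtering

Receiver downloads contain exact duplicates (re-downloads, node merges)
and occasional false positives from tag-collision code corruption. True
positives arrive in bursts while an animal swims through a detection
range; collision artifacts are temporally isolated. The screen therefore
removes a detection when fewer than `min_hits` detections of the same
transmitter occur within ±`window_min` of it anywhere in the array
(defaults 2 and 60 min, counting the detection itself). Both parameters
are exposed because the choice is a judgement call, not an estimate; the
default window is deliberately generous so that only fully isolated pings
are discarded. Filtering is idempotent and order-independent, and the
implementation is verified against an all-pairs scan.

## Diel, lunar, tidal and seasonal covariates

*Diel.* Timestamps are stored UTC and classified on a configurable local
clock (default America/New_York) because day/night windows are local-time
conventions. The default window — day [07:00, 19:00) — equals the mean
sunrise/sunset over a two-year window at the Sebastian, FL array, rounded
to the nearest hour; `derive_diel_window` recomputes it for any site and
date range from the NOAA solar-position equations (~1-min accuracy at
mid-latitudes; polar day/night raises an error).

*Moon.* The illuminated fraction uses a truncated lunar/solar longitude
series (phase angle i, fraction = (1 + cos i)/2), accurate to a few
tenths of a percent — ample for a [0, 1] covariate. It reproduces
almanac full/new moons through 2017–2019 to < 0.01.

*Tide.* Tide state at a receiver is read from a reference station's
extrema series shifted by the receiver's lag. The lag comes from the
tidal rate of movement TRM = d/ΔT (defaults: 3,698 m and 8,400 s for the
inlet/river-mouth pair, TRM = 0.4402 m s⁻¹) applied to great-circle
distances. Published discretizations of "tide state" rarely define
boundaries; we use symmetric slack bands: within 1/8 of a full cycle
(2× the bracketing extremum gap) of a high or low extremum the state is
High or Low, otherwise Incoming on the rising limb and Outgoing on the
falling limb. This makes the four states occupy equal quarters of a
clean sinusoidal cycle and is configurable via `slack_fraction`. The lag
model assumes a constant propagation rate along the shortest path — it
ignores bathymetry and within-cycle rate variation.

*Season and study year.* Seasons switch at the astronomical equinoxes and
solstices (tabulated per year, 2016–2020); study years are 12-month
blocks from the deployment start (default 1 June 2017).

*Environment join.* Water-quality series are matched to visit start times
by nearest timestamp within a 30-min tolerance; unmatched visits keep
missing values and are dropped (with a warned count) by the model layer.

## Visit extraction

The time-out is the time to traverse the average detection diameter
(2 × 200 m radius) at the species' average rate of movement
(1.4 km h⁻¹), i.e. 60·0.4/1.4 = 17.142… min, reported and applied at the
conventional 1-decimal rounding (17.1). Scanning each transmitter's
detections chronologically, a run continues while the receiver is
unchanged and the gap is ≤ the time-out; the gap comparison is inclusive
because termination is defined by a gap *greater than* the time-out.
Runs need ≥ 2 detections to become visits; duration is last − first
detection, so a visit's duration underestimates the true occupancy bout
by up to about two ping intervals at high detection probability.
Simultaneous detections at two receivers (overlapping ranges) are
processed in receiver-ID lexical order, which deterministically splits
both runs — consistent with the new-receiver rule. Long visits are those
with duration strictly greater than the threshold (default = time-out).
The extractor is property-tested against an independent brute-force
segmentation and is monotone in the time-out (visits under a smaller
time-out nest inside visits under a larger one).

## Summary conventions

Proportions are printed to one decimal, rounding half away from zero
(matching the usual report-table convention). SE of a single value is
reported as 0 by convention. Diel cell means are over per-tag per-date
detection counts (tag-dates with zero detections do not contribute a
zero; the counting unit is switchable).

## Detection-count GLMM

Counts per tag × date × receiver × diel cell are modelled as Poisson
with log link, a full diel × receiver × sex interaction and a Gaussian
random intercept per transmitter. Because the random effect is a scalar
per independent group the marginal likelihood factors into 1-D
integrals; these are evaluated by adaptive Gauss–Hermite quadrature (15
nodes by default, centred at each group's posterior mode with curvature
scaling), and (β, log σ_u) is maximized by BFGS with numerical
gradients. Wald SEs come from the numerical Hessian. The implementation
matches `lme4::glmer` (adaptive quadrature) to ~1e-3 on fixed effects
and σ_u in the cross-check test, and collapses to the plain Poisson GLM
when σ_u → 0. Pairwise receiver (and diel-within-receiver) comparisons
use estimated marginal means on the link scale with the
studentized-range (Tukey) adjustment at asymptotic df. Significance is
assessed at α = 0.05 throughout.

## Visit-duration GAMM

Durations (min, strictly positive) are Gamma; the linear predictor has a
cyclic cubic smooth of local decimal hour (0 ≡ 24), B-spline smooths
(default basis dimension 9) of moon fraction, temperature, salinity and
dissolved oxygen, parametric tide-state and general-location
(clam-lease vs other) terms, and a per-animal random intercept
represented as a ridge-penalized one-hot basis — the standard
smooth-term formulation of a random intercept, with the penalty weight
mapping to scale/σ_u². The inverse (canonical) link is attempted first;
since it does not guarantee positive means, a failed or numerically
degenerate fit triggers a refit with the log link, flagged
`link_fallback=True` in the result. Oxygen saturation is screened out
before modelling by the collinearity screen (Pearson correlations plus
VIFs from auxiliary regressions; covariates with VIF above 3 are
dropped last-listed-first, so the first-listed member of a collinear
pair survives).

Smoothing weights are selected by generalized cross-validation —
coordinate descent over a log-spaced grid (1e-2…1e8), two sweeps —
rather than REML; GCV is the criterion statsmodels' penalized IRLS
exposes, and on the generator's data it shrinks pure-noise smooths to
near-linear effective df while leaving real effects unpenalized. Fits
are validated structurally: per-column effective df must lie in
(−0.5, 1.6) and sum below 0.9 n; a violating (numerically singular) fit
is retried under 100× stronger smoothing and otherwise rejected.

Model selection fits every subset of the candidate fixed terms (the
intercept and random intercept are always retained) and ranks by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k the total effective df plus
one for the Gamma scale and ℓ the unpenalized log-likelihood; the
correction is set to +∞ when n − k − 1 ≤ 0. The full model's GCV-chosen
smoothing weights are reused across subsets so the search costs one
penalized fit per candidate; ties within 0.01 AICc resolve to fewer
terms. Non-converging subsets are recorded and excluded from ranking.

## Synthetic telemetry generator

The generator emulates the study system's structure, not its exact
rates: six receivers (IR16 river mouth, SCLN/SCLS clam leases,
SINJ/SISO/SIWP inlet, 200 m radii), two species with ~20 tags each over
a two-year window, V16 (30–90 s) and V13 (60–180 s) ping intervals,
12.42-h tides, 29.5-d lunar cycle via the same ephemeris the annotator
uses, and a temperature–oxygen-saturation pair constructed collinear
(r > 0.9) to exercise the screen. Animals alternate off-array absences
with site bouts; sites are drawn from diel-dependent weights (eagle rays
inlet-heavy and present year-round; cownose rays lagoon-heavy, more
nocturnal, with elevated summer absence), and bout durations are Gamma
with mean exp-linked to an hour-of-day harmonic (default peak 10:00,
amplitude 0.35), centred moon fraction (0.4), clam-lease occupancy
(0.25) and tide state — so the duration models have a recoverable
signal. Everything is deterministic under the seed (per-tag child seeds;
byte-identical CSVs across runs).

What the generator does *not* emulate: spatially continuous movement and
range-dependent detection probability (detection is a site-level
Bernoulli), acoustic propagation and environmental detection-range
variation, receiver outages, tag battery death, and behavioural
autocorrelation beyond the bout process. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own stated
assumptions, not robustness to every field pathology.

The ideal-detector oracle (`truth_visit_table`) segments each tag's full
transmission record with the same inclusive-gap/receiver-change rule,
implemented independently as a plain scan: same-site bouts separated by
less than the time-out are indistinguishable to any detector and merge
into one expected visit.

## Test problem sizes

The statistical suites run at fixed, documented sizes chosen to give
stable verdicts at interactive cost: end-to-end recovery on a 60-day,
6-tag array at detection probability 0.95 (≥ 90% of ideal-detector
visits recovered at interval-Jaccard ≥ 0.8); GLMM coverage over 100
replicates of 200 tag-days (95% CI covers the true diel ratio in ≥ 90%);
type-I calibration over 200 null replicates (KS uniformity of Wald
p-values); GAMM hour-peak recovery at n = 2,000 (±1.5 h); location-term
power over 10 replicates of n = 2,000 (+30% lease effect, p < 0.05 in
≥ 80%); and AICc-selection recovery over 50 replicates of n = 400 (top
model exactly the generating {hour, moon} pair in ≥ 80%).

## Known limitations

- The GLMM supports a single scalar random intercept (the study design);
  crossed or nested random effects are out of scope.
- GCV rather than REML smoothing selection can undersmooth in small
  samples; the structural fit validation and the boosted-penalty retry
  mitigate the worst cases.
- The inverse Gamma link frequently fails on realistic duration data
  (it lacks guaranteed positivity); results are then log-link fits and
  are flagged as such. Coefficient signs must always be interpreted
  relative to the link actually used.
- Tide lags assume a constant propagation speed along great-circle
  distances; estuarine bathymetry violates this.
- The false-detection screen is a temporal-isolation heuristic; it
  cannot identify collision artifacts that happen to fall inside a burst
  of genuine detections.
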