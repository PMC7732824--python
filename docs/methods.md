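# Methods

This note documents the models, defaults and numerical choices behind the
pipeline, what the synthetic-data generator does and does not emulate, and
the places where a genuinely open design decision was made.

## Solar ephemeris

`flyway.solar` implements a truncated-series solar position (declination
and equation of time derived from the apparent solar longitude, Meeus'
low-accuracy formulation), good to about 0.01° over 1950–2100. Elevations
are geometric: no atmospheric refraction is applied, because the
calibrated sun elevation angle absorbs refraction together with sensor
response and habitat shading — only the *difference* between forward model
and inversion matters for threshold geolocation, and both use the same
ephemeris. Twilight crossing times solve the sunrise equation with the
declination and equation of time re-evaluated at the event (two fixed-point
iterations, convergent to well under a second of time).

## Light model and shading noise

Tag radiometry is irrelevant downstream; only the threshold-crossing time
matters. The generator therefore uses a logistic response in solar
elevation with a dark floor (0.3) and saturation (64, on an arbitrary
Intigeo-like scale), anchored so that log(light) = 1 exactly at the
configured threshold elevation (default −3.5°). Shading can only remove
light, so twilight errors act one-sided: per local day, one gamma draw
(default shape 2, rate 0.5 min⁻¹) delays dawn and an independent draw
advances dusk, implemented by shifting the evaluation time on the morning
and evening side of local solar noon. The light units and saturation
behaviour of the real tags are not constrained by anything downstream; any
monotone response yields identical twilights.

## Calibration

The reference sun elevation angle minimises the summed absolute
twilight-time residuals at the known deployment site (least absolute
residual, bounded search over −12°…+3°). Residual delays — oriented so
shading is positive for both twilight kinds — are then fitted to a gamma
distribution by maximum likelihood after an envelope shift (the minimum
residual is stored as `delay_offset_min`), since the least-absolute-residual
angle absorbs the median shading delay. With noise-free input the
residuals collapse below 0.75 min; the calibration is then flagged
degenerate and a point-mass tolerance replaces the gamma in downstream
likelihoods. Calibration refuses to run with fewer than 10 twilight pairs.

## Threshold positions and the equinox flag

Longitude comes from the twilight midpoint via true solar time; latitude
solves the day-length equation by bracketed root finding over ±89°,
preferring the root nearest to the previous day's latitude. The equinox
window is flagged by sensitivity, not by a fixed date range: if perturbing
the day length by ±5 minutes moves the solved latitude by more than 3°
(configurable), the latitude is flagged; an infeasible day length flags
the pair as an outlier while still reporting longitude. Days with a
missing twilight contribute no estimate.

## Residency grouping

Day-to-day changes of same-kind twilight times are compared with the null
envelope of the calibrated error — the difference of two twilight errors,
approximated as normal with sd √2·σ (σ = √shape/rate). A twilight scores
1 when its deviation exceeds the 95 % envelope; scores smoothed over three
adjacent twilights give the movement probability, and probability ≥ 0.5 —
or a single deviation beyond 1.5× the envelope — marks movement.
Residency groups spanning under 2 days are dissolved into movement, and
adjacent groups separated by a gap of at most 3 days whose mean sunrise
and sunset times are statistically indistinguishable are merged back;
this is what discards one-day excursions and noise-induced splits while a
true relocation (which shifts noon and/or day length) keeps groups apart.
Grouping tools in the geolocator literature differ in how they
operationalise the movement probability; the explicit rule above is this
package's documented choice, with the standard observable behaviour
(movement probability > 0.5, 2-day minimum residency).

## MCMC refinement

One location is sampled per residency group and one per movement twilight
pair. The likelihood is the calibrated gamma density on oriented twilight
delays (with a smooth quadratic penalty for physically impossible negative
delays, and a Gaussian of width equal to the tolerance in the degenerate
case); the prior is a relaxed gamma (shape 2.2, rate 0.08) on great-circle
ground speeds between consecutive locations, with time gaps measured edge
to edge (last twilight of one node to first twilight of the next — using
group mid-times would let week-long residencies absorb any jump). The
first and, when the tag is recording back at the deployment site, last
locations are fixed there (`fix_first` / `fix_last`). Sampling is a
per-location Gaussian random walk Metropolis scheme: 1000 initialisation
sweeps, three tuning runs of 300 sweeps that double or halve each
location's proposal scale outside the 20–40 % acceptance band, then 2000
recorded sweeps summarised as medians with 2.5/97.5 % quantiles. A
split-chain potential scale reduction above 1.2 on any coordinate raises a
warning; results are still returned. All counts are configurable; the
test suite uses shorter schedules (a few hundred sweeps) on short tracks,
which those tracks' posteriors resolve comfortably.

## Stopover segmentation under a duty cycle

Consecutive fixes are clustered against a running centroid with a 150 km
radius (robust to within-site drift; the cluster closes exactly when a fix
leaves the radius, so interior clusters are flanked by > 150 km
displacements by construction). A 10 h on / 48 h off transmitter truncates
the observed span of any residency — a 3-day stopover can surface as a
single 10-hour window of fixes — so arrival and departure are
back-projected into the flanking transmission gaps at the bird's travel
speed (median apparent speed ≥ 20 km/h, falling back to 55 km/h):
arrival = last distant fix time + distance-to-centroid / speed, clamped
into the gap, and symmetrically for departure. The ≥ 3-day rule applies to
this credited duration. Under the 10/48 cycle a 48-hour pause can
intersect at most one transmission window, so 2-day pauses stay below a
3-day threshold structurally, while planted 3–20-day stopovers are
recovered with arrival/departure errors well inside one duty-cycle window
(58 h). Clusters containing the first or last fix are the deployment and
destination residencies and are reported separately from stopovers. A
stopover's location is summarised as the spherical centroid of its member
fixes (the summary convention for a site is otherwise arbitrary).

## Phases, timing and distances

The residency containing the first fix is the non-breeding residency; the
northernmost residency at or above the breeding latitude (default 30° N
for plateau-breeding Redshanks, 60° N appropriate for Russian-breeding
Whimbrels, configurable) is the breeding residency; a track that never
reaches it is flagged a partial migration (sub-adult behaviour) and gets
no breeding/southward phase. Dates and whole-day durations are plain
calendar-date differences in SGT (UTC+8) — other conventions (e.g.
rounding elapsed time in days) can differ by one or two days on the same
date pair, so the convention is fixed and stated rather than inferred per
case. Distances are great-circle on a 6371 km sphere
(`great_circle_km`), summed through consecutive retained fixes with each
stopover collapsed onto its centroid; phase windows include the bracketing
fixes because phase boundaries are back-projected into transmission gaps.
Apparent speeds use legs shorter than 24 h and exclude values below
20 km/h, with speed error (r₁ + r₂)/Δt from the fixes' maximum error
radii. The detour is the phase distance minus the chord between the
non-breeding and breeding centroids.

## Environmental annotation

Wind is sampled at the leg midpoint, bilinear in space and nearest in
time (the annotation convention for a finite flight segment is otherwise
arbitrary). Support is v_w·cos α along the leg's initial great-circle
bearing; the "max" level is the pointwise maximum of the three signed
supports. Airspeed is the scalar ground speed minus support — crosswind is
deliberately ignored because the downstream regressions use scalar
airspeed; the two agree exactly when crosswind is zero. Minimum-elevation
profiles densify the route along great circles (step ≤ 0.05°), sample the
DEM bilinearly and take minima in half-open 0.1° latitude bins; the
per-individual summary weights bins equally (not by route length per bin).
Sampled bin minima agree with 10× denser sampling to within the DEM's own
cell-to-cell relief — the residual is pure sampling resolution on steep
flanks, not a binning error. Altitude from tag temperature uses the mean
of the blocks in the 24 h before the wetness-derived departure as the
baseline and converts each post-departure drop at 6.5 °C/km; the
conversion is exactly linear in the drop.

## Permutation test

The two-group statistic is T = Σ(group A), standardized with its exact
permutation-null moments (E[T] = n_a·mean, Var[T] = n_a(N−n_a)/(N−1)·var);
this is the standardized linear statistic whose Z matches a mean-difference
test. When C(N, n_a) ≤ 20 000 the null is enumerated exhaustively;
otherwise the two-sided p is the raw proportion of |Z*| ≥ |Z| over the
requested Monte-Carlo resamplings (default 9999), floored at
1/n_resamples — the raw proportion rather than the (x+1)/(B+1) correction,
a documented and switch-free convention here since enumeration covers the
small-sample cases where the distinction matters. Zero pooled variance
degenerates to Z = 0, p = 1. Seeds are explicit in the API. Regressions
(speed on support; support on route × direction with eastern/northward
reference levels; north-vs-south duration correlation) are ordinary least
squares via statsmodels, treating each measurement as independent;
degenerate all-equal responses return zero coefficients with R² = 0.

## Synthetic data: what it emulates and what it does not

Truth tracks run at 1-hour cadence — finer than any consumer (5-min light
is positioned by interpolation; Argos windows subsample it), so
interpolation error stays below fix noise. Residency jitter is 0.5 km,
far below the 150 km segmentation radius. Argos classes draw isotropic
errors uniformly within their nominal radii (G3 ≤ 0.25 km, G2 ≤ 0.5,
G1 ≤ 1.5, LOW ≤ 5), so class bounds hold by construction. Temperature is
a latitude-ramp surface climatology (30 °C at the equator, −0.35 °C per
degree) minus the lapse term; wetness is binomial immersion (cap 14)
only while stationary at coastal (sea-level) phases. The DEM is an
east-west Gaussian ridge (crest 5500 m between 27–30° N, 75–97° E) over a
cosine-tapered plateau, with optional low passes notched at stated
longitudes; winds are per-level mean vectors plus smooth seeded
sinusoidal perturbations.

Not emulated: flight detours within a leg (legs are exact great circles),
weather-driven twilight autocorrelation (shading draws are independent
per day), Argos location-class temporal clustering, orographic winds, and
seasonal temperature cycles. Passing tests therefore demonstrate that the
estimators invert their own forward models under realistic noise levels
and duty cycles — not that they are robust to every artefact of real
tags; the reader should treat recovery numbers as upper bounds on
real-data performance.

## Problem sizes

The shipped test suite and acceptance script use: 100 days of simulated
light for calibration (200 twilights), 15-day noiseless windows for the
mid-winter inversion, 20 seeded migrations (3–20-day stopovers) plus 10
two-day controls for segmentation, 1000 null replicates at 9999
resamplings for permutation calibration, n = 200 for regression recovery,
and 0.005° dense sampling for the elevation oracle. MCMC checks run
shortened schedules (200–600 recorded sweeps) on 20–40-day tracks.
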