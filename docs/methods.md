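# Methods

This note documents the measurement rules, the statistical models, the
synthetic-data generator, and the numerical and design choices behind
`leisuregps`.

## Epoch model and alignment

All processing happens on a fixed 15-s epoch grid. Device timestamps are
**floored** (not rounded) to the grid — the epoch-start convention — which
makes alignment deterministic and idempotent. The aligned stream is the
union of grid points covered by either device; a side with no sample
carries absent fields, and a speed value is never retained without a
positional fix. Duplicate timestamps after flooring indicate a corrupted
log and abort the read with a per-participant report. When a GPS source
has no speed channel (GPX commonly does not), speed is recomputed from
consecutive fixes as great-circle distance over elapsed time. A single
study-local timezone is assumed; device clocks are assumed synchronized.

## Wear and inclusion rules

* **Non-wear**: a maximal run of consecutive zero counts lasting ≥60 min
  (`nonwear_min`). The rule is strict — a single positive epoch breaks the
  run; no spike allowance is applied, because allowing spikes would need a
  tolerance parameter with no principled default here.
* **Valid day**: ≥9 h (`min_wear_hours`) of *combined* coverage, i.e.
  epochs that are simultaneously accelerometer wear and GPS-fixed. The
  combined (conjunctive) reading was chosen over either-device coverage:
  transport outcomes need both instruments at once, so a day quantifies
  measurable time only where both streams exist. The participant's first
  calendar day is always invalid (devices are handed out during that day).
  A "day" is a local calendar date; weekend = Saturday/Sunday.
* **Inclusion**: ≥4 valid days (`min_valid_days`) including ≥1 valid
  weekend day (`min_weekend_days`).

## Trip detection

Epoch speeds are banded: stationary <1 km/h, walking [1, 10) km/h, cycling
[10, 25) km/h, passive ≥25 km/h (`movement_kmh`, `walk_max_kmh`,
`cycle_max_kmh`). An absent speed (no fix) counts as stationary, which
also implements the dropout rule below. Detection then:

1. chains moving epochs into **runs**, merging across stationary gaps of at
   most 5 min (`max_pause_min`); a longer gap terminates the run — so GPS
   dropout gaps ≤5 min inside movement are treated as pause time, and
   longer ones end the trip;
2. **splits** a run where the band changes and the new band persists for
   ≥4 consecutive moving epochs (`split_persistence_epochs`, 1 min).
   Splitting is required because a trip has a single mode, but epoch-level
   band flicker (a cyclist slowing through the walking band, a speed
   spike) must not fragment trips — the persistence rule is the
   disambiguation. Short off-band excursions attach to the preceding
   sustained band (the following one at the head of a run);
3. discards segments whose total extent — first to last moving epoch,
   internal pauses included — is under 3 min (`min_trip_min`). The
   duration-based reading (extent, not moving time) matches how diary
   trips are bounded ("lasted at least 3 minutes").

The trip **mode** is the band of the median moving-epoch speed, robust to
residual flicker. Before detection, speeds pass a centred running median
(`smooth_window` = 5 epochs = 75 s; window 1 disables), which suppresses
isolated speed spikes from positional error; NaNs are ignored within a
window and preserved in place. At a wear boundary the truncated window can
extend a trip by one epoch — recovery guarantees are therefore stated to
one-epoch resolution.

Equivalence with an independently written brute-force segmenter is part of
the test suite (500 random streams up to 2000 epochs, exact agreement).

## Leisure time and outcomes

Leisure time is the whole day on weekends and the complement of school
hours on school days, using each school's timetable (Belgian primary
schools close at 12:00 on Wednesdays, so Wednesday afternoons are
leisure). A trip is assigned to the leisure window by its **temporal
midpoint**, which avoids double counting boundary-straddling trips. Trips
with one endpoint inside the home geofence and the other inside the school
geofence (either direction) are school commutes and are excluded
**unconditionally**, weekends included. The geofence radius defaults to
100 m — generous relative to the receiver's 2.9-m median dynamic error,
sized for schoolyard extent.

Outcomes per participant × stratum (week/weekend) × mode use **valid days
only** as denominators: trips/day and min/day are valid-day means;
min/trip is total minutes over total trips; engagement is "any trip in the
stratum". Diary outcomes use the same denominators so the two instruments
are comparable per day; diary rows on invalid days and school-trip rows
are excluded symmetrically.

## Validity statistics

Pearson r with the t-transform p-value, classified low (|r| ≤ 0.30),
moderate (0.31–0.50), high (>0.50); two-sided paired t-tests at α = 0.05,
available from raw paired vectors and from summary statistics
(M₁, SD₁, M₂, SD₂, r, n) — the two forms agree to 1e-10 and the summary
form reconstructs published table rows from printed inputs. Participants
missing one instrument are dropped pairwise per comparison.

## Association models

All models carry a **school-class random intercept** (participants cluster
within classes) and adjust for age (continuous), sex, SES, school
(categorical fixed effect; classes are nested in schools) and wear time
(mean combined minutes/day over valid days — minutes, configurable). The
seven environment scores enter simultaneously as one multivariable model
per outcome.

* Approximately normal outcomes: Gaussian identity linear mixed model,
  maximum likelihood (statsmodels MixedLM); Wald 95% CIs; singular
  random-effect fits fall back to OLS with a warning.
* Positive skewed outcomes: Gamma GLMM with log link; exp(b) is the
  proportional change in the outcome per unit predictor.
* Zero-heavy outcomes: a **hurdle** of a mixed logistic model on the
  any-engagement indicator (all participants, OR scale) and a mixed
  Gamma-log model on the positive subset (exp(b) scale).

The logistic and Gamma-log GLMMs are fitted by **adaptive Gauss–Hermite
quadrature**. Per cluster the random intercept's integrand mode is found
by Newton's method (both integrands are log-concave in u), nodes are
recentred at the mode and rescaled by the curvature, and the marginal
likelihood is accumulated with log-sum-exp; 25 quadrature points by
default, and refining to 101 changes well-conditioned estimates by <1e-4.
The Gamma shape is estimated jointly by ML. Maximisation is L-BFGS-B with
three-point numeric gradients over (β, log σ_u[, log shape]); predictors
are standardised internally for conditioning and estimates mapped back to
the original scale. Standard errors come from the central-difference
Hessian of the marginal log-likelihood; CIs are Wald on the link scale,
exponentiated for OR/exp(b). Failed convergences retry from up to five
jittered starts, keeping the best likelihood. `fix_re_sd=0` collapses the
model to the ordinary GLM (agreement to 1e-6 is tested). AIC = 2k − 2·logL
compares converged candidate families on identical data, first-by-order on
ties. In tests, lme4 `glmer` (nAGQ = 25) is the external oracle for the
logistic model and glmmTMB for the Gamma model; they are never used in the
implementation.

## Synthetic-data generator

The generator emulates the target study design: one week (Monday start,
two weekend days), 15-s epochs, suburban/urban schools with Belgian
timetables, wear from roughly 07:30 to 21:30 with overnight zero-count
blocks, occasional ≥60-min daytime non-wear, whole-day GPS failures, and a
fraction of participants engineered to miss the wear criteria. Default
trip intensities (walk 4.0/1.6, cycle 1.2/0.9, passive 1.9/2.1 trips/day
for week/weekend) and trip lengths (≈3.5–14 min) sit at the magnitudes
typical for this age group. Trips are placed by a thinned Poisson process
inside eligible (wear ∩ leisure) windows — simple and rate-interpretable —
with a 6-min separation buffer so distinct true trips can never merge
under the 5-min pause allowance. School days gain morning and afternoon
home↔school commutes at walking or cycling pace depending on distance.

Epoch speeds are drawn per mode around (4.5, 15, 40) km/h with jitter
clamped inside the band; a small leakage probability (0.02) draws
unclamped speeds. Positional noise is isotropic Gaussian in a local metric
frame, 2.9 m by default (the receiver's published median dynamic error);
GPS dropout removes 5% of fix epochs. Stationary epochs carry residual
speeds capped below the 1 km/h movement threshold.

The diary model reports each true trip independently: probability 0.2 for
walking and cycling, 0.9 for passive transport — active trips are heavily
under-reported, passive trips reported reliably. A reported passive trip
is additionally split into two diary entries with probability 0.1,
representing combined trips recorded as multiple rows; the net effect is
that passive trip counts are reported nearly one-to-one while active
counts are not.

Questionnaire items are drawn from per-subscale latent traits (so internal
consistency is realistic); trip rates link to standardised subscale scores
through log-linear coefficients and to engagement through a logistic link,
with class-level random intercepts, all configurable.

What the generator does **not** emulate: street networks and routing,
behaviourally realistic activity scheduling, clock drift between devices,
systematic (non-Gaussian) GPS error such as urban-canyon multipath, and
accelerometer spike artefacts. Passing recovery tests therefore shows the
pipeline implements its stated rules faithfully under plausible noise —
not that the rules themselves are free of the ~20–25% trip
misclassification reported for speed-based classifiers on real data.

## Problem sizes

Test and acceptance runs use scaled cohorts chosen to exercise every rule
while staying desk-sized: 6–25 participants for pipeline recovery, 500
random streams (≤2000 epochs) for the trip oracle, 1000 streams for the
non-wear oracle, and 100 replicates of 25 classes × 20 participants for
hurdle-model recovery. The acceptance script reports the problem size next
to every quantity it computes.

## Known limitations

* Trip endpoints inherit positional noise directly; no endpoint snapping
  or map matching is attempted, so geofence classification very near a
  fence boundary is noise-sensitive.
* The hurdle parts are fitted independently (no shared random effect
  across parts), matching the two-separate-analyses formulation.
* Gamma dispersion is a single global shape; no per-cluster dispersion.
* The Gaussian mixed model relies on statsmodels MixedLM; its fallback on
  singular random-effect variance is OLS rather than a boundary-corrected
  mixed fit.
* Cronbach's alpha uses listwise-complete respondents per subscale.
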