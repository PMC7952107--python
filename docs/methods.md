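# Methods

## The model in one paragraph

`edflow` is a discrete-event simulation (DES) of a low-acuity pediatric
emergency-department track.  Patients triaged Emergency Severity Index
(ESI) 4 or 5 arrive by a non-homogeneous Poisson process, pass through
nurse screening and vital signs, wait for one of a fixed pool of rooms,
are evaluated by a clinician, undergo diagnostic testing and treatment
with a fixed per-ESI probability, and are discharged by a nurse.  Rooms,
nurses and clinicians are contended FIFO resources, so every process can
queue.  The scientific question the package answers is a what-if: how much
shorter would length of stay (LOS) and wait times be if providers ordered
diagnostic tests at an *achievable benchmark* rate — the rate already
achieved by the best-performing providers — instead of the current rate?

## Patient pathway

```
arrival -> nurse screening -> vitals -> [queue: room] -> transfer to room
        -> [queue: clinician] -> evaluation
             trainee path:  resident/trainee evaluation -> attending review
             attending path: attending evaluation
        -> if tested: testing & treatment (room held) -> attending reassessment
        -> nurse discharge -> disposition -> bed cleaning -> room freed
```

* **Wait** = arrival to the start of the first clinician evaluation.
* **LOS** = arrival to disposition (the end of the discharge process).
  Bed cleaning happens after disposition and never extends LOS.
* Untested patients skip testing and reassessment entirely and are
  discharged after evaluation.
* One nurse hold spans screening + vitals; nurses also serve discharge.
  A config switch (`pathway_variant: vitals_in_room`) instead takes vitals
  in the room after transfer, since the true ordering at the modelled site
  is not documented; the shipped default keeps vitals at triage.
* Queues are FIFO with no priority between ESI 4 and ESI 5: the track is a
  single low-acuity stream and no prioritisation among these levels is
  described for the modelled unit.

## Service-time distributions

Each process duration is a declarative spec: a base family plus an
additive shift (minutes) and a multiplier.  Parameters follow the
convention of the commercial simulation tool in which the original model
family was authored, i.e. scale-like parameter first: Gamma(scale, shape),
Weibull(scale, shape), Lognormal(arithmetic mean, arithmetic SD) —
converted internally to log-scale μ, σ — Beta(shape1, shape2) on [0, 1],
Triangular(min, mode, max), Exponential(mean).  The shipped pathway
(means in parentheses):

| process | spec | mean (min) |
| --- | --- | --- |
| nurse screening | Gamma(0.567, 4.9) | 2.78 |
| vital signs | 1 + Gamma(1.58, 1.51) | 3.39 |
| transfer to room | Triangular(5, 10, 12) | 9.00 |
| attending evaluation | 2 + 28 × Beta(0.726, 1.08) | 13.26 |
| trainee evaluation | 2 + 28 × Beta(1.11, 1.04) | 16.46 |
| attending/trainee review | −0.001 + Weibull(6.4, 1.27) | 5.94 |
| attending reassessment | −0.001 + Exponential(3.88) | 3.88 |
| testing & treatment, ESI 4 | 5 + Gamma(136, 0.874) | 123.86 |
| testing & treatment, ESI 5 | 5 + Weibull(45.1, 0.701) | 62.01 |
| nurse discharge | Triangular(5, 10, 15) | 10.00 |
| bed cleaning | 2 + Lognormal(17.4, 16.2) | 19.40 |

Draws are `max(0, shift + mult × X)`.  The clamp exists only to absorb the
tiny negative fitted offsets (−0.001); for every shipped spec the clamped
mass is negligible, and `analytic_mean` deliberately ignores it.  Whether
the original fitted expressions truncated rather than clamped is unknown;
at these offsets the two are numerically indistinguishable.

Testing is a single combined testing-and-treatment delay holding the room
but no staff resource — a deliberate simplification (no separate lab or
radiology sub-resources), which if anything understates the congestion
relief of reduced testing.

## Arrival process

Arrivals follow a piecewise-constant-rate Poisson process over 24 hourly
rates.  Only three facts about the modelled site's profile are documented:
hourly rates span 1.63–8.56 patients/hour, and annual volumes are 35,838
ESI-4 and 9,124 ESI-5 visits (44,962 total; ESI-4 fraction 0.797).  The
default profile is therefore a smooth diurnal sinusoid (trough 05:00, peak
~19:00) affinely mapped to [1.63, 8.56] and then *power-warped* so the
24-hour sum equals 44,962/365 exactly while the extremes stay pinned to
the documented range.  The warp exponent is found by bisection; the
profile is fully overridable in the YAML config.  Each arrival is labelled
ESI 4 independently with probability 35,838/44,962.

## Random-number architecture

Each replication derives one named, independent stream per stochastic
ingredient (arrivals, each of the 11 service processes, the testing
Bernoulli, trainee routing) from a master seed via `numpy` SeedSequence
spawning.  All of a patient's durations and uniforms are pre-drawn at
arrival.  Consequences: (i) identical seeds give bitwise-identical visit
logs; (ii) two scenarios run with the same seeds are synchronised
patient-by-patient (common random numbers, CRN), and because the testing
decision is `u < p`, the tested set at a lower rate is a strict subset of
the tested set at a higher rate — which makes ladder comparisons of
testing rates nearly noise-free in direction.

Scenario rep seeds are keyed by (master seed, scenario label, rep), so
experiment outputs are invariant to scenario ordering; with
`paired_streams` the label is dropped from the key and arms share streams.
Arms are *independent* by default, matching the interval arithmetic used
for reporting (the published intervals treat arms as independent).

## Calibration of the unpublished unit configuration

The modelled unit's resource counts and staffing structure are not
published; only the outcome surface is: at current testing rates (22.5% of
ESI-4, 11.9% of ESI-5 visits) mean LOS 156.8/133.3 min and mean wait
87.6/85.1 min (ESI 4/5), and at benchmark rates (13.5%/4.2%) mean LOS
137.7/122.4 and wait 78.7/77.7.  `calibrate_resources` grid-searches
integer resource counts (and optionally the trainee-routing share)
minimising the summed squared relative error against a four-value LOS/wait
target surface, using short replications for speed; the analysis driver
re-scores the leaders against *both* published arms at full length.

Two structural findings from that calibration shaped the shipped defaults:

1. **Waits are room-constrained but only mildly testing-sensitive.**  With
   no trainee routing, the only queue long enough to produce ~87-minute
   waits is the room queue, and a room queue that long is strongly
   testing-sensitive (reducing testing frees ~10 room-minutes per visit),
   overshooting the published between-arm wait differences several-fold.
2. **Trainee first-touch routing supplies the missing testing-insensitive
   service content.**  The pathway retains trainee-evaluation and
   attending-review distributions, and routing visits through a small
   trainee pool adds ~9 minutes of post-evaluation content plus queueing
   that does not depend on testing rates.  With routing active, levels and
   differences can be matched simultaneously.

The shipped defaults are the grid argmin on the two-arm surface:
**12 rooms, 2 nurses, 2 attending-level providers, 2 trainee-level
clinicians, trainee routing fraction 1.0** (every visit gets a first-touch
evaluation followed by an attending review — the pattern of an academic
unit staffed by trainees and mid-level providers under attending
supervision).  Wait is recorded at the start of the *first* clinician
evaluation.  On fresh master seeds this configuration lands all eight
published quantities (four current-arm levels, four between-arm
differences) inside their reported uncertainty.

These counts are an *equivalent* configuration reproducing the observed
surface, not a claim about the real unit's staffing; several nearby
configurations fit almost as well (the level/sensitivity trade-off is the
identifying constraint, and it is partly degenerate).

## Replication design and inference

Experiments follow the published design: 5 replications of 365 recorded
days per arm, preceded by a 7-day warm-up whose arrivals are discarded
(the run is drained so every recorded patient reaches disposition; the
warm-up removes the empty-department initialisation bias and its length is
a package choice — the source design does not document one).  Comparisons
of two arms use the pooled-variance two-sample t interval on the per-rep
means (df = n_a + n_b − 2).  This interval, applied to the printed means
and SDs, reproduces every published validation interval (model n = 5 vs
n = 12 administrative months) and experiment interval (5 vs 5) to one
decimal — which is how both the method and the administrative n were
identified, since neither is stated explicitly.  Monthly normality of the
administrative summaries is assumed consistently with that reconstruction.

Display rounding is half-away-from-zero to 1 decimal; internal arithmetic
is unrounded.  Patient-hours = n × (per-patient LOS difference in
minutes)/60, rounded to the nearest hour.  The 15-minute a-priori
clinical-impact threshold is inclusive at the boundary.

## Achievable benchmark of care

Testing is overuse, so the desirable event is a visit *without* a test.
Providers are ranked by the adjusted performance fraction
APF = (x+1)/(d+2) of desirable events (Bayesian shrinkage against small
denominators), ties broken by provider id; top providers are selected
until they cover ≥ 10% of visits (the pared-mean convention; coverage is
configurable); the benchmark testing rate is 1 − (pooled no-test rate of
the selected).  The published benchmark values (13.5% ESI-4, 4.2% ESI-5)
cannot be re-derived because the underlying provider table is
unpublished; the scenario layer therefore takes them as inputs, while
`compute_abc` operates on real or synthetic provider tables.  Provider
percentiles for the high-testing scenarios use the nearest-rank rule on
unweighted provider-level rates.

## Synthetic administrative data

The generator emulates the three EMR extracts the study consumed:

* **Provider table** — provider testing rates with the documented ~10-fold
  p90/p10 spread around visit-weighted means 22.5%/11.9%.  Rates are
  `exp(a + b z)` with z standard normal: `b` pins the *realised* p90/p10
  to the spread target, `a` (bisection, respecting a 0.995 cap) pins the
  realised visit-weighted mean.  Visits are allocated by a symmetric
  Dirichlet (concentration 5) over 30 providers — a typical low-acuity
  roster size — summing exactly to the annual census; tests are
  Binomial(visits, rate).  The log-normal family, the Dirichlet
  allocation and the provider count are invented conventions: the real
  distributions are unpublished.
* **Monthly admin summaries** — 12 monthly mean LOS/wait per ESI, normal
  around the published fiscal-year means/SDs.

What passing tests on synthetic data do *not* show: the generator contains
no case-mix, seasonality, day-of-week structure, or correlated
provider-month effects, so pipeline results on it validate the arithmetic
and the qualitative mechanics, not site-specific magnitudes.

## Numerical and degenerate-input choices

* Event ties are broken by insertion order (stable heap sequence), making
  runs deterministic even with zero-duration processes.
* A released resource unit is handed directly to the longest waiter
  (FIFO), never re-entering the free pool first.
* An all-zero arrival profile is legal and yields an empty log; empty ESI
  strata report n = 0 with absent means rather than NaNs.
* Invalid distribution parameters are rejected when the spec is built,
  not when first sampled.
* Calibration declares failure when the best configuration misses any
  target by more than 25% (relative).

## Problem sizes used by the shipped analyses and tests

The headline experiment is 2 arms × 5 replications × (7 + 365) days at
~45k patients/year — about 450k simulated visits, ~10 s on one core.
Property tests use 10⁵-draw Monte-Carlo checks per distribution, an
M/M/1 run of ≥10⁵ arrivals checked against W = 1/(μ−λ) within 5%, a
1,000-instance brute-force cross-check of the benchmark computation, and
short-horizon (15–40 day) system runs for pathway and monotonicity
properties.  The calibration driver's full grid is minutes-long; a
`--quick` flag runs a reduced grid.

## Known limitations

* High-acuity patients, admissions, consults and boarding are out of
  scope; the real unit shares some resources with the wider department,
  which the single-track model folds into its calibrated counts.
* Static resource levels: no shift schedules or dynamic staffing.
* Testing is one pooled delay; no lab/radiology queues, so the congestion
  benefit of reduced testing is likely conservative.
* No return-visit or missed-diagnosis modelling; the benchmark scenarios
  assume behaviour change is achievable and safe.
* The calibrated configuration is observationally equivalent to, not
  identical with, the real unit.
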