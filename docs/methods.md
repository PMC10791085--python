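# Methods

This note documents the models implemented in `urgentsim`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data experiments do and do not demonstrate.

## Scope and design intent

The package realises a symbiotic-simulation architecture for urgent
care: a *descriptive* layer (the data feed), a *diagnostic* layer (the
crowding trigger), a *predictive* layer (the census forecaster) and a
*prescriptive* layer (the patient-flow DES), closed into an update loop
that runs every 30 minutes in virtual time. The real deployment context
— a 24-hour ED plus three minor treatment centres sharing a live data
platform — supplies the structure; since neither the live data nor the
fitted service parameters of that system are public, every numeric
default here is a synthetic placeholder, chosen once to give a plausible
mid-size ED and clearly overridable in configuration.

## Arrival process

Arrivals follow a non-homogeneous Poisson process with piecewise-constant
rate λ(t) = `hourly_rates[hour(t)] · dow_factors[weekday(t)]`, sampled
by thinning against λmax. Thinning is exact for this rate structure and
costs O(candidate events). Acuity (1–5) and mode (walk-in/ambulance)
are i.i.d. marks from mode-specific mixes; walk-ins skew to categories
3–5 and ambulances to 1–3, reflecting the usual triage composition, with
the specific numbers being synthetic defaults. Ambulance arrivals occur
only at the ED.

The default demand (≈170 patients/day, peak 11/h mid-day, trough 2/h at
night, Monday ≈15% above mid-week) is in the range of a mid-size UK ED.

## ED patient-flow model

The pathway is: triage (nurse pool, FIFO) → assessment queue → assessment
→ optional investigation → optional treatment → at most one extra
investigation/treatment cycle → disposition into discharge, admission or
the clinical decision unit (CDU). Key semantics:

- **Assessment queue.** A patient needs a cubicle *and* a doctor; both
  queues are priority queues ordered by (acuity, arrival time), so more
  urgent patients overtake but equal-acuity patients are FIFO. The
  cubicle is held from assessment start until departure (or CDU entry);
  the doctor only during assessment and treatment activities.
- **Boarding.** Admitted patients wait a downstream delay for a ward
  bed; by default this keeps the cubicle occupied (exit block). This is
  a switch (`boarding_holds_cubicle`) because the resource effect of the
  delay-to-discharge is a modelling choice, not a law.
- **CDU clock stop.** Entry to the CDU stops the operational
  waiting-time clock: time-in-ED for CDU patients is measured to CDU
  entry. CDU capacity is not modelled (observation units rarely bind in
  the short horizon of interest); CDU occupants remain in the census.
- **Redirection.** At arrival, an eligible patient (default: category
  4/5 walk-in) is redirected with probability `redirect_fraction` via a
  per-entity uniform draw; the target MTC is drawn by routing weight
  among MTCs that are open and accept the category, the patient incurs
  the network travel delay and then queues at the MTC (single FIFO
  multi-server queue). If no target is open the patient stays at the
  ED, so overnight (default MTC hours 08:00–20:00) redirection is
  inactive — a deliberate piece of realism.
- **Service times.** Lognormal for clinical activities (the standard
  positive-skew choice when only a mean and spread are meaningful) and
  exponential for the boarding delay; both are configurable per activity
  (`lognormal | exponential | fixed`). Durations are produced by inverse
  CDF from pre-drawn per-patient uniforms, which is what makes common
  random numbers exact (below).

Default resourcing (8 doctors, 20 cubicles, 3 triage nurses) was sized
by offered-load arithmetic: at the default mix a patient consumes ≈39
doctor-minutes, so the peak 11/h offered load is ≈7.2 doctors; 8 gives a
strained-but-stable peak (instantaneous utilisation ≈0.9) that recovers
overnight. A first draft with 6 doctors was super-critical at peak and
produced unbounded queues, which is not a useful default.

The simulation kernel is a small process-based event engine
(`urgentsim.engine`): generator processes, a single event heap keyed by
(time, insertion sequence) so simultaneous events fire in schedule
order, and counting-semaphore resources with stable priority queues and
busy-time integration. Determinism is byte-level: identical seeds give
identical event logs.

## Mixed real-time initial conditions

`warmup_then_align(network, pathway, profile, warmup_hours, targets, seed)`
returns an initial state that *exactly* reproduces a live snapshot
(census, waiting count, maximum wait) per facility:

1. Run the DES from empty for the warm-up using the arrival profile and
   freeze the final state (who is waiting since when; who is in which
   activity with how much time remaining).
2. Adjust waiting entities: drop newest-first or synthesise (walk-in
   acuity mix) until the count matches; pin the oldest waiting arrival
   at now − max-wait and redraw any other waiting arrival that falls
   outside (−max-wait, 0].
3. Adjust in-service entities: drop or synthesise until census − waiting
   matches; synthesised stages are drawn proportional to expected stage
   occupancy (stage probability × mean stage duration, a Little's-law
   shape), and remaining time is U·(fresh duration draw), the
   stationary-residual heuristic.

Carried-over entities keep their acuity and elapsed wait but are
namespaced (`C_…`) so their IDs can never collide with the injected
run's own arrival stream. Initial occupants seize resources
*unconditionally* (a crowded department physically exceeds nominal
capacity); new requests queue until occupancy drops below capacity.
Entities present at time zero have incomplete timestamp chains and are
excluded from patient-level KPIs (they still count in census and flow
conservation), which matches how a warm-started window should be scored.

## Forecaster

Target: ED patients-in-department at update-interval resolution,
default 8 steps × 30 min = 4 h. Two methods:

- `seasonal_naive`: ŷ(t+h) = y(t+h−m), m = 48 slots/day. Interval
  half-width z·σ from the pooled spread of one-season-back residuals
  y(t) − y(t−m) over the training window. Exact on any perfectly
  periodic series, and the guaranteed-available fallback.
- `sarima`: statsmodels SARIMAX, default orders (1,0,1)×(0,1,1)₄₈, lbfgs,
  stationarity/invertibility enforcement off for robustness. Any fit
  failure or non-convergence falls back to seasonal-naive with a logged
  warning and a `model_tag` of `seasonal_naive(fallback:sarima)` — the
  tag always records what actually ran, and the loop never aborts on a
  forecasting failure.

Training window default 28 days (≥4 weekly cycles). Point forecasts are
clipped at zero and interval bounds forced to bracket the point. Weekly
seasonality is *not* modelled explicitly (no day-of-week dummies or
7-day differencing): the daily cycle is the dominant structure at a
4-hour horizon, the pooled residuals of the seasonal-naive method absorb
the weekday offset into the interval width, and SARIMAX does not support
a second seasonal period. This is a simplification, documented rather
than hidden.

`rolling_backtest` evaluates per-step MAE/MAPE and interval coverage
over rolling origins and is the tool for method comparison on a given
history.

## Crowding trigger

Thresholds are empirical quantiles (numpy's linear-interpolation
definition) of historical census values pooled by hour of day, default
q = 0.85 — an "upper-typical" level so that an exceedance means
unusually crowded for that time of day. Pooling all days is the
default; a weekday/weekend split is available (`days=` argument). At
least 14 days of history are required. Detection scans the forecast
horizon in order and fires at the first step whose *point* forecast
strictly exceeds its hour's threshold (equality does not fire);
`conservative=True` compares the interval upper bound instead. Strict
exceedance of the point forecast is the documented reading of
"threshold reached"; both choices are monotone in the thresholds.

## The update loop

Per tick: append the ED snapshot to the census history → refit the
forecast → test the trigger → on an event, align initial conditions to
the tick's snapshots, run every scenario (baseline always included)
under common random numbers, and emit a recommendation ranked by mean
ED census over the recovery window (default 8 h), ties broken by 4-hour
performance. Census over the recovery window is the primary criterion
because relieving crowding is the point of the intervention; the
ranking rule is a package choice.

After a recommendation the trigger is *suppressed* for one recovery
window (cooldown) so the loop does not re-launch simulations for the
same episode every 30 minutes; suppression (rather than detect-and-
ignore) keeps the invariant "scenario results present iff trigger event
present" true on every tick. Stream gaps up to a tolerance (default
90 min) are padded with the last value; wider gaps skip the tick with a
logged warning. The loop runs in virtual time against a replayed
stream, is fully deterministic under the master seed (per-tick seeds are
spawned from it), and is restartable: resuming from a persisted
`LoopState` reproduces the remaining ticks exactly.

## Common random numbers and aggregation

For replication r, one arrival stream and one matrix of per-patient
uniforms (redirection draw, branch draws, one uniform per potential
activity duration) are generated from seeds derived from (base seed, r)
and reused by every scenario. Because each patient consumes a
fixed-size draw block regardless of path, scenarios stay synchronised:
the same patient gets the same service times and branches wherever they
are treated. Scenario KPIs are aggregated as means with t-distribution
95% confidence intervals across replications; with one replication the
interval is degenerate and flagged. Paired (per-replication) deltas
against baseline, with t intervals, are reported in recommendations.

## Synthetic end-to-end validation

`end_to_end_validation` realises, on synthetic data, the procedure of
checking the model's census and waiting counts against the historical
feed: generate arrivals from a known profile, run the model once as
"ground truth", then refit from the profile alone (optionally with
deliberately perturbed rates) and run R independent replications. The
report gives the hour-of-day mean census/waiting trajectories, the mean
absolute deviation, a sign-based systematic-bias flag (≥20 of 24 hours
deviating the same way), and the fraction of hours where ground truth
lies inside the 95% replication band. The band is a t prediction
interval, mean ± t₀.₉₇₅·s·√(1+1/R): the ground-truth run is one more
independent draw of the same statistic, and a plain percentile band of
R = 30 runs would under-cover (~90%) by construction. The first day of
each run is excluded from the hourly means as warm-up.

## Numerical and tie-break choices

- Simultaneous events fire in schedule order (stable heap); boundary
  recorders are scheduled first, so a census at time t excludes events
  occurring exactly at t — the convention the conservation checks use.
- Quantiles: numpy linear interpolation everywhere.
- Lognormal parameterised by (mean, cv): σ² = ln(1+cv²), μ = ln m − σ²/2.
- Uniform draws are clipped to [1e-12, 1−1e-12] before the normal
  inverse CDF to avoid infinities.
- Recommendation ranking rounds the primary KPI to 9 decimals before
  comparison so ties are broken by 4-hour performance, not float noise.
- Degenerate inputs: zero arrival rates give an empty process (not an
  error); an empty simulation yields NaN time-based KPIs and zero
  counts; a replications=1 batch yields degenerate flagged intervals.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their experiments for
stable conclusions on a single CPU: the M/M/c comparison pools waits
from 200 replications of 30/20/12 simulated days for c = 1/2/5 (first
12 h discarded), which puts the Monte Carlo standard error near 1% of
the Erlang-C value being checked at 5%; the redirection-monotonicity
contrast uses 25 common-random-number replications of 2 days; the
ground-truth validation uses 8 days × 30 replications; alignment and
trigger equivalence use 1,000 randomised cases each.

## What the synthetic experiments do and do not show

The generators emulate the *statistical shape* of urgent-care data —
daily/weekly seasonality, autocorrelated noise, acuity-dependent
pathways, Poisson arrivals — with known ground truth, so the tests
demonstrate internal correctness: the flow model converges to the right
queueing limit, state alignment is exact, the loop is deterministic,
and the forecaster recovers seasonal structure it was built to recover.
They do not demonstrate calibration to any real ED: real arrival
processes are over-dispersed relative to Poisson, service times and
branch probabilities vary by hour and by staff, real feeds have outages
and revisions, and behavioural responses to redirection are not
modelled. Deploying this toolkit on a real network requires estimating
every `arrivals`/`pathway` parameter from local data and re-validating
against the live feed.

## Known limitations

- No staff rosters or shift effects; server counts are constant.
- MTCs are simple queues with a single clinician pool; no MTC-side
  triage or disposition structure.
- At most two investigation/treatment cycles; no inter-facility
  transfers other than arrival-time redirection; no ambulance-service
  or patient-choice model.
- The trigger uses census only (an arrivals-count series can be passed
  in its place, but no composite crowding index is provided).
- The update loop runs in virtual time; a wall-clock deployment wrapper
  and live connectors are out of scope.
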