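# Methods

## The modeling problem

Conventional discrete-event simulations of an emergency department (ED)
treat the physician as a passive capacitated resource: a patient seizes it,
holds it for a service time, and releases it.  That picture omits the
supervisory relationship between an attending physician and a *delegate*
(resident, physician assistant, nurse practitioner): the delegate assesses
and treats low-acuity patients but must review the treatment plan with the
physician before treating, and that consultation occupies both providers at
once.  `edsim` models the two providers as **interacting pseudo-agents** —
simulation entities carrying embedded hierarchical decision logic — inside
an otherwise ordinary queue-and-resource DES, and quantifies how much the
consult protocol changes provider utilization and patient flow times
compared with the conventional construction that ignores it.

## Decision logic

Each provider agent is a process with states IDLE, ASSESSING (delegate
only: developing the treatment plan), CONSULTING and TREATING, plus an
internal AWAITING_CONSULT mark while the delegate holds for the physician.

* **Physician**, at every decision epoch (completing any activity, or waking
  on a signal): treat a queued high-acuity patient first; otherwise answer a
  pending consult; otherwise treat a queued low-acuity patient; otherwise go
  idle.
* **Delegate**: claim a queued low-acuity patient (never high acuity); work
  up the treatment plan; when interaction is enabled, raise a consult
  request and hold until the physician joins; consult (one sampled duration
  logged identically by both agents); then treat and implement the plan.

Idle agents hold on two broadcast signals: `patient_waiting` (sent to both
when a patient joins a queue) and `consult_request` (delegate to
physician).  A signal wakes every process holding at that instant exactly
once; processes busy at send time are unaffected and re-inspect the queues
at their next decision epoch, so no work is lost.

**Claim tie-break.**  When both providers could claim the same low-acuity
patient, a configurable rule orders the wake-ups: `delegate_first`
(default), `physician_first`, `idle_longest`, or `random`.  The default
follows the decision hierarchy — treating low-acuity patients is the
physician's last-resort activity — and it is also the rule that reproduces
the published validation utilizations (0.64 physician / 0.72 delegate,
implying the physician treats ~46% of low-acuity patients); `idle_longest`
yields an even 50/50 split and a 0.67/0.67 pair instead.

**Consult preemption (off by default).**  `consult_preempts_low` lets a
consult request pause an in-progress low-acuity treatment (never a
high-acuity one), resuming it afterwards.  It is a plausible alternative
reading of "attend to delegates before low-priority patients", but the
literal non-preemptive reading reproduces the published flow times better,
so the switch defaults to off in both models.

## Validation model

A deliberately bare system — one queue, no beds or nurses — isolating the
provider-dispatch programming from system feedback.  Defaults: exponential
inter-arrivals, mean 12 min (~5 patients/h), 20% high acuity; deterministic
treatment times 20 min (high) and 10 min (low) plus a 10-min surcharge when
the delegate treats; with interaction, a 5-min joint consult and 5 further
delegate minutes implementing the plan; 24 h warm-up, 24 h recording, 500
independent replications (replication *r* uses seed substream `(seed, r)`,
so run modes share random numbers replication-by-replication).
Utilization is the busy fraction of the recording day (ASSESSING +
TREATING + CONSULTING; waiting for the physician counts as idle); time to
disposition is arrival-to-exit for patients disposed in the recording day,
stratified by (provider, acuity).

Three run modes: `conventional` (providers as passive resources under a
greedy work-conserving dispatcher), `pseudo_disabled` (agents, consult off)
and `pseudo_enabled`.  Under common random numbers the first two produce
bit-identical patient trajectories — the package's core correctness check,
enforced by a test.

**Known discrepancy.**  The published interaction-enabled utilization pair
(0.89 physician, 0.93 delegate) is not jointly attainable under the stated
rules: with consults adding (1−p)/3 to the physician and the delegate busy
2(1−p) of the day (p = physician's share of low-acuity patients), physician
0.89 implies p ≈ 0.67 while delegate 0.93 implies p ≈ 0.53.  This
implementation reproduces the physician utilization (0.885), the high- and
low-acuity disposition times and the delegate-low disposition time within
the published confidence intervals, but the delegate's enabled utilization
comes out ≈ 0.65: the time it spends holding for the physician (excluded
from utilization by definition) displaces treating.  The corresponding
acceptance check is left failing rather than redefining utilization to
make it pass.

## Hospital ED model

Patient flow (in order): arrival → triage nurse (Poisson, mean 10 min) →
registrar (lognormal, mean 2) → wait for charge nurse *and* bed, with
leave-without-being-seen (LWBS) risk → 2-min charge-nurse transfer →
bedside-nurse assessment (beta, mean 10) → provider episode by acuity →
blood draw by a bedside nurse if ordered (triangular 4; results never block
flow) → radiology if ordered (beta 9; the patient keeps the bed) →
admission (probability 0.15, bed released at departure) or nurse-assisted
discharge (triangular 10).  All queues are priority (high acuity first),
FIFO within priority.  Capacities: triage nurses and registrars 1 overnight
/ 2 during the day, 2 bedside nurses, 1 charge nurse, 1 physician,
1 delegate, 5 beds, 1 radiology unit.

CTAS probabilities (0.01, 0.16, 0.56, 0.25, 0.02 for levels 1–5; levels 1–2
are "high" acuity), blood-work and radiology probabilities per CTAS level
(independent draws), and the LWBS band probabilities (0.01 under 30 min up
to 0.40 beyond 300 min) are table inputs.

**Arrival schedule.**  The true hospital's hourly/daily arrival pattern is
not published numerically; the shipped default is a synthetic two-peak
diurnal curve (trough ≈ 04:00, peaks ≈ 11:00 and 19:00, peak-to-trough
≈ 4:1) with a mild Monday-heavy weekday effect, scaled so the long-run
volume is 50,000 patients/year.  Within each hour, inter-arrival times are
exponential at that hour's rate (restarted at hour boundaries, which is
exact for a piecewise-constant-rate Poisson process).  Halving the walk-in
rate (80% of volume by default) leaves ambulance arrivals untouched.

**LWBS mechanics.**  The inputs table gives band probabilities, not a
hazard.  Default `hazard` mode: a patient who must queue for a bed draws
the first band's probability on joining, then at each band boundary crossed
while still waiting draws the *incremental* probability
p(band) − p(previous); the cumulative leave probability then matches the
band table to good approximation (e.g. ≈ 0.10 for a 2-hour wait).
`single_draw` mode applies one draw at bed assignment using the realized
wait's band.  Measured base-case loss is ≈ 10% of arrivals.

**Delegate episode calibration.**  The inputs table gives only a 4-min
delegate treatment and a 4.5-min consultation, yet the published outputs
show 14.50 min of patient-delegate time without interaction and 24.51 with
(+10.01).  The episode is therefore calibrated to those printed outputs:
work-up 10.5 min (triangular) + treatment 4 min without interaction
(= 14.5); work-up + consult 4.5 (joint) + treatment 4 + implementation
5.5 (= 24.5) with interaction.  The model reproduces both printed values to
0.01 min.  All stage means are config-overridable.

**Run protocol and outputs.**  One long replication: 40 warm-up days
discarded, 420 days recorded (the warm-up length is confirmed by the
moving-average stabilization of the daily mean length-of-stay series within
40 days).  Utilizations are busy fractions of the recording window with
batch-means CIs over the per-day series; stratified flow times
(arrival-to-bed, wait for provider, time with provider, total
length-of-stay) are batch means over patients ordered by departure.

**ED accuracy.**  At 50,000 arrivals/year the model reproduces the
published delegate utilization without interaction (54% vs 56%) and
physician utilization with interaction (43% vs 41%) within 3 percentage
points, and the printed patient-delegate times exactly; the remaining pair
(physician without interaction 27% vs 23%; delegate with interaction 65%
vs 71%) differs by 4–6 points.  Flow balance shows the published quartet is
only jointly consistent at an effective treated rate of ≈ 4.75 patients/h
with the physician taking ≈ 41% of low-acuity patients; at the configured
annual volume minus the measured ≈ 10% LWBS loss, a work-conserving
physician takes ≈ 50%.  The shipped defaults keep the stated study
conditions rather than tuning volume or split to the outputs; the two
out-of-band checks are left failing with this analysis.

## Output analysis

* **Warm-up (Welch-style):** trailing moving average of a recorded series;
  the truncation index is the first point after which the average stays
  within a relative tolerance (default 5%) of its terminal level; a series
  that never settles returns a "no steady state" sentinel.
* **Batch means:** one long run is cut into batches whose size doubles
  until the lag-1 autocorrelation of the batch means is statistically
  negligible (|r₁| ≤ 1.96/√m), then mean ± t-based 95% half-width.  The
  point estimate always equals the plain sample mean; batching only changes
  the variance estimate.  Empirical coverage on i.i.d. streams is 93–97%
  (tested at 1,000 repeats).
* **Comparisons:** Welch two-sample t-tests on batch/replication means,
  reporting the difference, its standard error and significance at 0.05.

## Numerical and design choices

* Simultaneous events execute in (time, priority, insertion-sequence)
  order; runs are bit-reproducible for a fixed seed.
* Every sampling site draws from its own named substream of the master
  seed, so model variants consume identical variates site-by-site (common
  random numbers).
* Distribution families beyond their mean are under-determined by the
  inputs table; conventions (lognormal CV 0.5, symmetric beta on
  [0, 2·mean], symmetric triangular ±50%, Poisson minutes taken literally
  for triage) are explicit and overridable.
* Capacity schedules are hourly step functions; reductions never preempt
  work in progress.
* Charge nurse and bed are acquired bed-first (the scarce resource), then
  the charge nurse for a 2-min transfer; a pure zero-hold gate would make
  the charge-nurse count meaningless in sensitivity runs.
* The admit/discharge split (0.15) is not published; it only shifts how the
  bed is released.

## What the synthetic defaults do and do not show

The generator's defaults emulate the published study conditions: printed
means, capacities and probabilities, with invented-but-stated stand-ins
only where the source is silent (arrival shape, distribution shapes,
admit probability, walk-in share).  Passing tests therefore demonstrate
the *mechanics* — dispatch logic, consult protocol, output analysis — and
reproduction of the published quantities that are reachable from the
printed inputs; they do not validate against any hospital's observed data,
do not model re-assessments, multiple diagnostic loops, triage bypass for
the sickest patients, or more than one delegate per shift.
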