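# Methods

This note records the model behind `walktrigger`, the choices made where
the design was genuinely open, and what the bundled simulator can and
cannot establish about real deployments.

## The trigger state machine

The engine distinguishes two states, *stationary* and *nonstationary*,
and advances on a fixed 60 s tick — the granularity of the accelerometer
epochs, which are the finest unit of exchange (raw 64 Hz waveforms are
never handled; the 1-minute "movement acceleration" aggregate is taken as
given from the device pipeline).

At a tick `t` the three firing conditions are:

| condition | rule | default |
|---|---|---|
| acceleration | every complete epoch in the trailing sustain window strictly above threshold | 0.1 g over 60 s (one epoch) |
| displacement | fresh fix (age ≤ `gps_staleness` = 120 s) strictly more than `move_radius` from the anchor | 100 m |
| geofence | same fix strictly more than `home_radius` from the residence | 100 m |
| day window | prompts only between `day_window` bounds, checked at fire time | 06:00–22:00 local |

Strict inequalities follow the published formulation of the thresholds
("> 0.1 g", "beyond a radius of 100 m"). Timestamps are naive local civil
time: both daily windows are wall-clock rules, so no timezone machinery is
involved. Unworn epochs fail the acceleration condition — a device off
the body cannot evidence walking.

**Anchor semantics.** The 100 m displacement is measured against the last
stationary location: the anchor latches onto the first valid fix and
thereafter resets only on a nonstationary → stationary reversion. This is
the simplest semantics consistent with stay-point detection; it also means
that after relocating passively (e.g. a low-acceleration vehicle trip) the
displacement condition is already satisfied, and firing is gated by the
acceleration and geofence rules alone.

**Repeat scheduling.** On each fire the next follow-up time is drawn
uniformly from `repeat_interval ± repeat_jitter` (420 ± 300 s, i.e.
Uniform[120, 720]; the symmetric reading of "±300 s"). Conditions are
re-checked at the scheduled fire time only — there is no continuous
cancellation between fires. On a failed re-check the state reverts and
re-anchors at the current fix. Because fire times land on the next minute
tick and 720 s is a whole number of minutes, consecutive prompts of an
episode are always 120–720 s apart. A prompt scheduled before 22:00 but
due after it is dropped (window checked at fire time). The jitter draw is
the only stochastic element; `repeat_jitter=0` gives a fully derandomized
engine for testing.

**Random schedule.** The time-based comparator draws `random_count` = 3
times per day uniformly over the feasible set (all inside 10:00–22:00,
pairwise gaps ≥ 9000 s) by rejection sampling on the order statistics;
infeasible configurations are rejected at validation time.

## Route reconstruction

Four filters define a walking route: accuracy ≤ 30 m (inclusive — the
reported error must be *at least as good as* 30 m), retained-fix spacing
60–120 s (streams sampled faster are greedily thinned to ≥ 60 s from the
stream start; a gap > 120 s splits the track), cumulative haversine path
length ≥ 100 m (inclusive), and mean speed of the whole route < 10 km/h
(strict). The spacing rule is read as *fix spacing*, not route duration —
the duration reading would forbid any walk longer than two minutes.
Distances use the haversine formula on the IUGG mean-radius sphere
(6 371 008.8 m); at mobility scales the difference from an ellipsoidal
geodesic is orders of magnitude below GPS error. Routes are raw-fix
polylines; map-matching to a street network affects cartography, not the
counting analyses, and is out of scope.

## Evaluation

A route is *matched* iff at least one main/repeated prompt falls in
`[start, end + 120 s]`, closed at both ends ("during or immediately
after"). Percentages are rounded half-up to one decimal, and every
reported percentage is recomputable from the report's own integer counts.
An empty route set yields an explicitly undefined (None) sensitivity
rather than a NaN.

Pre-prompt activity sums steps over the two complete epochs preceding a
main prompt and flags whether the window acceleration exceeds 0.1 g
(strict) and reaches 0.2 g (inclusive). Whether a "situation" crosses a
threshold is decided by the window *mean* epoch acceleration by default; a
per-epoch ("any epoch") variant is available behind the `mode` switch,
since the aggregate-level definition is not uniquely determined by the
published phrasing. Unanswered prompts form their own stratum — they are
reported, never imputed. Compliance is reported per prompt kind, for
triggered prompts (main + repeated — the denominator of the headline
answer rate), and across all kinds.

Participant-days with under 8 h of accelerometer wear are excluded from
analyses; exclusion counts are returned alongside the filtered set.

## The simulator

Each simulated day tiles 00:00–24:00 with behavior bouts placed without
overlap in an 08:00–20:00 activity window (rejection placement, 5 min
buffer): by default 2 outdoor walks of 10–40 min, 2 indoor-activity bouts,
1 vehicle trip, 1 near-home stroll, with home rest filling the gaps. The
defaults are chosen so a day resembles the low-activity regime that makes
walking a *rare event*: roughly 50 min of outdoor walking in a 16 h wear
day.

Per-minute emissions (acceleration N(μ, σ) truncated at 0, steps, GPS
availability/accuracy/noise):

| behavior | accel (g) | steps/min | speed | GPS avail. | noise sd |
|---|---|---|---|---|---|
| walk_outdoor | 0.25 ± 0.05 | 100 ± 15 | 4.5 km/h | 0.95 | 10 m |
| stroll_near_home | 0.15 ± 0.05 | 60 ± 15 | 2 km/h | 0.90 | 15 m |
| indoor_active | 0.15 ± 0.05 | 30 ± 10 | — | 0.10 | 15 m |
| vehicle | 0.05 ± 0.02 | 0 | 30 km/h | 0.90 | 15 m |
| home_rest | 0.02 ± 0.01 | 0 | — | 0.10 | 15 m |

The walking acceleration and step levels mirror the activity contrast the
evaluation is meant to expose (high steps while walking outdoors, low
while not); stroll GPS availability and the accuracy distributions are
simulator choices with no published counterpart. Walking and vehicle
paths are out-and-back random-turn polylines starting and ending at home
(so positions are continuous across the day without street topology);
strolls bounce back whenever they approach 80 % of the home radius, which
keeps every noise-free stroll fix inside the geofence. Ground truth is
recorded per minute; "walking outdoors" is true only for `walk_outdoor`
bouts — near-home strolling is deliberately *not* walking, mirroring the
behavior class that produces self-denied trigger prompts.

Response behavior is independent of sensing: answering is Bernoulli per
kind (0.655 main / 0.729 repeated / 0.756 random — the observed compliance
rates), and answered main/repeated prompts report the ground-truth walking
state of their minute flipped with probability 0.1 (`report_accuracy` =
0.9, a simulator choice: self-perception is imperfect in both directions).

**The clean limit.** `EmissionProfile().clean()` defines the identifiable
noise-free regime used for the 100 %-sensitivity check: walking GPS exact
and always available, *all other behaviors GPS-silent*. Keeping indoor
fixes at full availability would chain an entire day into a single
track segment (no gap would ever exceed 120 s) and per-bout routes would
cease to exist; indoor GPS unavailability is a physical property of the
setting, not noise, so the clean limit retains it.

**What passing simulations do not show.** The generator has no urban
canyon multipath, no street network, no heterogeneous gait speeds or
accelerometer placements, no within-person behavioral correlation across
days, and GPS dropout is i.i.d. per minute rather than spatially
structured. Simulator-based results therefore validate the *logic* of the
trigger, route and evaluation rules — not field performance of the
hardware stack.

## Numerical and testing choices

- Percentage rounding is decimal half-up (banker's rounding would differ
  at exact halves); note that a ratio of 1479/1955 = 75.652 % prints as
  75.7 under this rule.
- All stochastic draws flow from one explicit seed per run
  (`numpy.random.default_rng`); the trigger consumes its generator exactly
  once per fired prompt, which makes seeded runs reproducible regardless
  of input content.
- Test problem sizes: the end-to-end suites use 10 × 10-day cohorts (100
  participant-days), 1000 randomized small instances for the
  oracle-equivalence checks of the state machine and the route matcher,
  and 10 000 seeded days for the random-scheduler law — sizes at which the
  binomial error of every empirical rate is well below the asserted
  margins.

## Known limitations

- Per-day prompt-count monotonicity in the acceleration threshold is not
  guaranteed: a single mid-walk epoch dipping below a higher threshold
  fails the repeat re-check, reverts and re-anchors the state, and
  continued walking then opens a *new* episode with its own main prompt.
  On ~1 % of simulated days this fragmentation makes a 0.2 g run emit one
  prompt more than the 0.1 g run on identical inputs. Aggregated over
  days, the higher threshold always produced substantially fewer prompts.
- The anchor never updates while stationary, so a long slow drift below
  the acceleration threshold (e.g. a quiet tram ride) leaves a stale
  anchor; the next supra-threshold minute outside the geofence then fires
  immediately. Whether the deployed hardware behaved this way is unknown;
  the geofence-at-every-fire reading was chosen over once-per-episode.
- GPX accuracy is read from a package-specific `<accuracy>` extension,
  falling back to `hdop × 5 m`; HDOP-to-metres scaling is conventional,
  not calibrated.
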