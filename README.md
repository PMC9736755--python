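# walktrigger

Event-triggered ambulatory assessment of outdoor walking: a walking-trigger
engine that fuses accelerometer epochs with GPS positioning to prompt
e-diary surveys *while a person is walking outdoors*, plus the GPS
walking-route reconstruction and the sensitivity/specificity analyses used
to validate such a trigger, and a synthetic mobility simulator that makes
the whole pipeline testable without any field data.

## Who this is for

Researchers in mobile sensing, urban health and ambulatory assessment
(EMA/GEMA) who want to detect walking episodes in situ and sample
self-reports during them, rather than at random times that almost always
miss rare behaviors — and who need to quantify how well such an
event-based design works before fielding it.

## The method

**Trigger.** A two-state machine (stationary / nonstationary) ticks once
per minute over fused streams of 1-minute accelerometer epochs (movement
acceleration `a` in g, gravity-removed) and GPS fixes. Inside the daily
window 06:00–22:00, the state switches to nonstationary — firing a *main*
e-diary — when all of the following hold at a tick `t`:

- `a > 0.1 g` for every complete epoch of the trailing 60 s,
- a fix no older than 120 s lies more than 100 m (haversine) from the
  stationary anchor (the last stationary location),
- that fix is outside the 100 m geofence of the place of residence.

While nonstationary, *repeated* e-diaries fire every `420 ± 300` s
(uniform jitter); a failed re-check at the scheduled fire time reverts the
state to stationary and re-anchors at the current fix. An independent
time-based schedule draws 3 *random* prompts/day, uniform over 10:00–22:00
subject to pairwise gaps ≥ 2.5 h.

**Walking routes (reference data).** From raw fixes, keep those with
reported accuracy ≤ 30 m, thin to ≥ 60 s spacing, split where gaps exceed
120 s, and keep segments with cumulative path length ≥ 100 m and mean
speed < 10 km/h. Routes are computed from GPS alone, independently of the
trigger.

**Evaluation.** *Sensitivity*: the fraction of routes with ≥ 1 main or
repeated prompt in `[start, end + 120 s]`, with the identical rule applied
to the random schedule as a time-based comparator. *Specificity*: steps,
movement acceleration (share of situations with window mean `> 0.1 g` and
`≥ 0.2 g`) and GPS presence in the 2 minutes before each main prompt,
stratified by whether the participant self-reported walking outdoors,
denied it, or did not answer. Plus compliance rates per prompt kind and
the 8-hour wear-time validity rule.

## Worked example

```python
from walktrigger import (
    TriggerConfig, match_routes, reconstruct_routes, run_trigger, simulate_cohort,
)

cohort = simulate_cohort(n_participants=3, n_days=5, seed=11)
matched = total = 0
for day in cohort.days:
    cfg = TriggerConfig(home_point=cohort.homes[day.participant_id])
    prompts = run_trigger(day.participant_id, day.date, day.epochs, day.fixes, cfg, seed=1)
    routes = reconstruct_routes(day.fixes)
    flags, report = match_routes(routes, prompts)
    matched += report.n_matched
    total += report.n_routes

print(f"routes reconstructed: {total}")
print(f"routes with an e-diary prompt: {matched}")
print(f"sensitivity: {100 * matched / total:.1f}%")
```

prints

```
routes reconstructed: 43
routes with an e-diary prompt: 30
sensitivity: 69.8%
```

The 15 simulated days contain 30 outdoor walking bouts; the routes fully
contained in a walking bout are all matched. The unmatched routes are
near-home strolls: slow, short movement inside the home geofence that
passes the four route filters but that the trigger deliberately ignores —
the same false-negative/false-positive trade-off the evaluation analyses
quantify. The same workflow is available from the shell:

```bash
walktrigger simulate --n 3 --days 5 --seed 11 --out sim/
walktrigger trigger  --epochs sim/P001_2020-09-01_epochs.csv \
                     --fixes  sim/P001_2020-09-01_fixes.gpx  \
                     --config cfg.yaml --seed 1 --out prompts.csv
walktrigger routes   --fixes sim/P001_2020-09-01_fixes.gpx --out routes.csv
walktrigger evaluate --fixes sim/P001_2020-09-01_fixes.gpx --prompts prompts.csv \
                     --epochs sim/P001_2020-09-01_epochs.csv --out report.json
```

## Layout

- `src/walktrigger/types.py`, `config.py`, `sensors_io.py`, `fixtures.py` —
  domain records, validated configuration, CSV/GPX/GeoJSON I/O, count fixtures
- `src/walktrigger/trigger_engine.py` — the state machine and schedulers
- `src/walktrigger/routes.py` — walking-route reconstruction
- `src/walktrigger/evaluation.py` — sensitivity, specificity, compliance
- `src/walktrigger/simulator.py` — behavior schedules, emission models, cohorts
- `docs/methods.md` — model assumptions, parameter defaults, limitations
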