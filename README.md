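# handseq

Sequential analysis of **hand-to-surface exposures (HSE)** — the timed
contacts between a healthcare worker's hands and the surfaces around a
patient — for hand-hygiene and pathogen-transmission research.

Observation studies that code every single hand contact (rather than whole
care tasks) reveal how often hands could carry microorganisms into the
patient zone or onto critical sites, and how rarely hand hygiene happens at
exactly those moments. `handseq` provides the full analysis stack for such
coded event streams:

- a plain-text **event-log dialect** (`handseq-v1`) for coded sessions:
  per-contact hand, glove state, surface taxonomy, timing; hand-hygiene
  actions; session metadata — one CSV file per session, with validation;
- **risk-event detection** over each hand's chronological contact stream;
- **adherence attribution** of hygiene actions to risk events;
- the standard **descriptive report** (per session and pooled);
- a calibrated, seedable **semi-Markov session simulator** so every stage is
  testable without access to recorded video;
- a **timeline renderer** (text and SVG) in the lane style of behavioral
  coding software, and a `handseq` command-line interface.

## The model

Surfaces are classified by a hierarchical scheme whose analytic level is the
WHO patient-zone concept: *inside patient zone*, *outside patient zone*, and
*critical sites* (wounds, mucous membranes, accessed invasive devices,
sterile equipment — physically inside the zone, analyzed as their own class).

For two consecutive contacts of the *same hand*, origin → destination:

- **colonization event**: any outside-zone surface → any inside-zone surface
  (critical sites excluded as destination). A modified WHO *Moment 1*: it
  counts hospital flora brought into the patient's surroundings, not only
  onto the patient.
- **infection event**: any surface → a critical site, unless the origin is
  the *same* critical site (repeated manipulation of one device). WHO
  *Moment 2*.

A hygiene action (handrub or wash) *covers* an event when it is completed
within the inter-contact gap of that hand; **adherence** is the covered
fraction, reported per event kind and as `NA` when a session has no events.

The simulator models each hand as an alternating renewal process: a Markov
chain on the ten surface-taxonomy leaves (default: the sticky rank-one family
`P = aI + (1-a)·1πᵀ`, whose stationary law is the observed leaf-share vector
π for any stickiness `a`), lognormal contact durations, exponential gaps,
episodic glove wear, and hygiene inserted into risk gaps with configurable
probability plus a background Poisson stream. `a` and the same-site retention
probability are solved in closed form from target colonization/infection
rates; see `docs/methods.md`.

## Worked example

The package ships a deterministic benchmark session set whose pooled
marginals equal the totals of a 10-session, 296.5-minute intensive-care
observation campaign (4222 contacts). Running the real pipeline over it:

```python
from handseq import (build_benchmark_sessions, detect_risk_events,
                     attach_hygiene, pooled_summary)
from handseq.risk_events import RiskKind

sessions = build_benchmark_sessions()
events = []
for s in sessions:
    evs = detect_risk_events(s)
    attach_hygiene(evs, s.hygiene_actions)
    events.append(evs)
overall = pooled_summary(sessions, events)
print(f"{overall.n_hse} HSE in {overall.coded_duration_s/60:.1f} min "
      f"({overall.hse_density_per_min:.1f}/min)")
col = overall.adherence[RiskKind.COLONIZATION]
inf = overall.adherence[RiskKind.INFECTION]
print(f"colonization events: {col.n_events} ({col.n_with_hygiene} with hygiene, "
      f"{col.adherence_pct:.1f}% adherence)")
print(f"infection events:    {inf.n_events} ({inf.n_with_hygiene} with hygiene, "
      f"{inf.adherence_pct:.1f}% adherence)")
print(f"hand hygiene: {overall.n_hygiene} actions "
      f"({overall.hygiene_density_per_hour:.1f}/hour)")
```

prints

```
4222 HSE in 296.5 min (14.2/min)
colonization events: 291 (14 with hygiene, 4.8% adherence)
infection events:    217 (3 with hygiene, 1.4% adherence)
hand hygiene: 97 actions (19.6/hour)
```

i.e. a contact every 4.2 seconds, a risk-relevant zone transition roughly
every 35 seconds, and hand hygiene at only ~5% of colonization and ~1% of
infection opportunities.

From the shell, the same pipeline over simulated data:

```sh
handseq simulate --seed 11 --n-sessions 3 --duration-min 10 --out-dir demo/
handseq all demo/session_*.csv --out-dir report/
handseq timeline demo/session_000.csv --start 0 --end 40
```

the last command drawing the 13-lane coding timeline:

```
session sim-11-000  window 0.0-40.0s  (1s/char)
          hygiene |........................................|
    bare R inside |........................................|
  bare R critical |........................................|
   bare R outside |.......#################################|
    bare L inside |.............................###########|
...
```

`report/` then contains `summary.json` (versioned schema), a report-shaped
`summary_table.csv` with one column per session plus an overall column, and
`risk_events.csv`.

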