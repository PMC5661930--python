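# Methods

This note documents the analytic conventions, the simulator's model and
calibration, the deterministic benchmark construction, and the numerical
choices made where the design was genuinely open.

## Event model and time conventions

Times are seconds from session start. Contacts and hygiene actions are
half-open intervals `[start, end)`, so abutting events do not overlap;
durations are strictly positive. The file dialect prints times at 3 decimals
(millisecond resolution); parsing a written file recovers the session
exactly, and writing is idempotent (canonicalization).

Overlapping contacts of the *same* hand are allowed and produce a validation
warning, not an error: lane-based coding tools legitimately emit visually
overlapping annotations. Streams are ordered by `(start, end, input order)`
with a stable sort; when a same-hand pair overlaps, its inter-contact gap is
empty or negative and no hygiene action can be strictly contained in it.
Contact of one hand with the worker's other hand is not a codable surface;
the reserved surface label `OTHER_OWN_HAND` turns accidental codings into a
validation error.

## Risk events and adherence

Transitions are evaluated *within each hand's own chronological stream* (the
per-hand event counts of observation campaigns are tallied that way); the
merged-stream variant is available as `stream_mode=INTERLEAVED` for
sensitivity analysis. Each consecutive pair yields at most one event:

- colonization: origin outside the patient zone, destination inside
  (critical destinations are handled by the infection rule, which takes
  precedence — destination zones are disjoint);
- infection: destination is a critical site and the origin is not excluded.
  The default exclusion is *same critical site only*; the stricter *any
  critical-site origin* exclusion is a config option. Site identity uses
  `surface_id` when both contacts carry one; for unlabeled data, two
  consecutive contacts of the same critical leaf type are conservatively
  treated as the same site (this never invents new risk events from
  unlabeled repeated device manipulation).

Hygiene is modeled as handless: every action is evaluated against both
hands' events. The default adherence policy is strict containment — the
action must complete inside the gap `(origin.end, destination.start)`; a
contact begun mid-rub is not protected. Any-overlap is available as an
option. Hygiene never suppresses an event; it only sets the adherence flag.
Glove changes are not hygiene actions and do not block detection (gloves
transport microorganisms like bare skin).

## Descriptive statistics

Sample (n−1) standard deviations; medians by the midpoint rule. Densities
divide by the *coded duration*, not the span from first to last event.
Pooled statistics are computed over the concatenated events: pooled density
is total count over total duration, never the mean of per-session densities.
Percentages are kept unrounded internally and displayed at one decimal,
rounded half-up (banker's rounding would corrupt printed table values such
as 54.45 → 54.5). Adherence with zero events is undefined and rendered `NA`.

## Synthetic session generator

Each hand is an alternating renewal process:

- **Categories**: a Markov chain on the ten surface-taxonomy leaves. The
  default transition matrix is the sticky rank-one family
  `P = a·I + (1−a)·1πᵀ`. Its stationary law is exactly π for every
  stickiness `a`, so the observed leaf shares (zone shares 42.0 / 46.3 /
  11.7%) are reproduced by construction while `a` independently controls
  how often the hand lingers on the same surface type.
- **Dwell times**: lognormal, moment-matched on the natural scale
  (mean 7.44 s, SD 14.1 s ⇒ σ² = ln(1+(sd/mean)²), μ = ln(mean) − σ²/2).
  The large SD/mean ratio implies strong right skew; the lognormal is the
  simplest two-parameter family matching both moments.
- **Gaps**: exponential, per hand. Observation data gives contact densities
  but no gap distribution; exponential is a modeling choice. Per-hand gap
  means are solved from the target density (14.24 contacts/min over both
  hands, right-hand share 54.5%) after subtracting mean dwell and the
  expected widening of hygiene-inserted gaps.
- **Hygiene**: when a sampled transition is a risk transition, a hygiene
  action is inserted into the (widened) gap with per-kind probability
  (defaults 0.048 for colonization, 0.014 for infection — the observed
  adherence levels), the way a worker pauses activity to rub. A background
  Poisson stream (default ≈16.2/h) supplies the many hygiene actions not
  adjacent to risk transitions, for a total near 19.6/h. Durations are
  gamma (mean 13.2 s, SD 8.6 s), floored at 2 s.
- **Gloves**: alternating gloved/bare episodes shared by both hands
  (exponential episode lengths, gloved episode mean 120 s), started in the
  stationary state so the gloved contact fraction (target 21.4%) is
  unbiased even in short sessions.
- **Critical-site identity**: each critical leaf has a pool of 2 named
  sites; on a repeated-leaf transition the same site is kept with retention
  probability `q`, otherwise the site is redrawn uniformly.
- **RNG**: one `SeedSequence` per session, spawned into independent child
  generators for left hand, right hand, background hygiene, and gloves, so
  toggling one sub-model does not perturb the draws of the others. Identical
  seeds give byte-identical session files.

### Calibration

With transition throughput fixed by the density target, the stationary
per-transition colonization rate of the rank-one chain is
`(1−a)·π_out·π_in`, giving `a` in closed form from the target colonization
rate (58.89/h). The infection rate decomposes into an off-diagonal part
(fixed once `a` is known) plus the repeated-leaf part
`Σ_j π_j P_jj · (1−q)(1−1/k)`, giving `q` from the target infection rate
(43.91/h). `expected_event_rates` evaluates these sums numerically for any
config and is the analytic oracle the Monte-Carlo tests check against.

### What the generator does and does not emulate

It reproduces marginal contact densities, zone/leaf shares, dwell and
hygiene duration moments, glove fraction, risk-event rates and adherence
levels. It does **not** emulate task structure (care activities impose long
correlated surface sequences, not first-order Markov ones), coordination
between hands (hands are independent by default; a mirrored mode exists),
time-of-day effects, or inter-worker variability. Passing recovery tests on
simulated data therefore validates the pipeline's correctness and the
calibration algebra, not first-order Markov realism of actual care work.

Known small biases, all accepted: contact counts run ~1% above the renewal
target in 30-minute sessions (transient of a renewal process with a
high-variance cycle); hygiene realizes ~3–5% below 19.6/h because insertions
too close to the session end are dropped; dwell means realize ~1% low from
end-of-session truncation.

## Deterministic benchmark session set

`handseq.benchmark` constructs 10 sessions totaling 296.5 min and 4222
contacts whose pooled marginals are *exact*: zone/leaf/hand/glove counts,
291 colonization (139 L / 152 R) and 217 infection (103 L / 114 R) events,
97 hygiene actions with 14 / 3 adherent, and two-point duration
distributions matching mean 7.44 (SD 14.1) s for contacts and 13.2 (8.6) s
for hygiene. Pooled totals are apportioned to sessions by largest-remainder;
categorical quotas are dealt from proportionally interleaved queues; each
hand's stream is a concatenation of `O^a [I^b] [C-run]` cycles so that risk
events arise *only* at designed transitions; adherent hygiene actions are
placed strictly inside their designated gap, and all other actions in a
buffer between the two hands' activity blocks where no inter-contact pair
can claim them. The set contains no randomness and is byte-stable; it is the
fixture behind the acceptance checks. Per-session values (durations
proportional to contact counts, quotas by apportionment) are a construction
convenience — only pooled values are meaningful.

## Numerical and testing choices

- `stationary_distribution` solves the null space of `(Pᵀ−I)` with a
  normalization row (least squares); reducible or periodic chains raise a
  diagnostic error, since the documented power-iteration cross-check would
  not converge there.
- Statistical tests use fixed seeds and 3-standard-error bands. The
  transition-matrix recovery check runs at ≥100k transitions (entrywise
  binomial z plus joint-frequency total variation < 0.02); the
  moderate-sample unit test restricts the entrywise z-check to cells with
  expected count ≥ 10, where the normal approximation is valid, and bounds
  total variation for the rest. Monte-Carlo event-frequency checks compare
  per-transition frequencies (invariant to timing effects) at ≥200k
  transitions in the acceptance suite and ~15k in the unit suite.
- Problem sizes throughout (session counts, durations, transition counts)
  were chosen to keep Monte-Carlo standard errors well inside the asserted
  bands while the full suite runs in seconds.
- SVG output fixes matplotlib's `svg.hashsalt` and omits the date metadata
  so rendering is deterministic; report JSON/CSV outputs contain no
  timestamps, making the whole pipeline byte-reproducible.

## Limitations

Only pairwise (first-order) transitions are analyzed; real contact
sequences form longer chains whose cumulative contamination is not modeled.
No microbial load, survival, or transmission dynamics are included — events
count *opportunities*, not transmissions. WHO Moments 3–5 (after-exposure
indications) are out of scope, as are multi-observer reliability statistics
and any parsing of proprietary coding-software project files beyond the
generic CSV dialect.
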