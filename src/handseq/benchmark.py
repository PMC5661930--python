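"""Deterministic benchmark session set with exactly specified pooled marginals.

Raw coded video data of ICU observation campaigns is generally not shareable,
but the *pooled* marginal totals of such a campaign are (contact counts by
zone/hand/glove, risk-event counts, hygiene counts, durations). This module
constructs — without any randomness — a set of sessions whose pooled
descriptive statistics and sequential-analysis results reproduce a given set
of marginal totals exactly. Running the real pipeline (dialect round-trip,
risk-event detection, hygiene attribution, pooled summary) over this set must
therefore reproduce every derived value (densities, shares, adherences) of
the campaign, which is what the acceptance checks do.

Construction idea: each hand's contact stream is a concatenation of *cycles*
``O^a [I^b] [C-run]`` over zone tokens (O = outside, I = inside non-critical,
C = critical). Every ``O -> I`` entry is one colonization event, every entry
into a C-run is one infection event, and all other adjacencies (O->O, I->I,
I->O, C->O, C->I, and same-site C->C within a run) classify as no event, so
event counts are exact by construction. Surface types, glove flags and
durations are dealt from global proportionally-interleaved queues so pooled
category totals are exact. Hygiene actions are placed either strictly inside
the inter-contact gap of a designated risk transition (adherent) or in a
buffer between the two hands' activity blocks (non-adherent).

The default marginals are a 10-session, 296.5-minute intensive-care campaign
with 4222 contacts; see :func:`benchmark_marginals`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from ._util import apportion, proportional_schedule
from .event_model import (
    CodedSession,
    Hand,
    HSEEvent,
    HygieneAction,
    HygieneKind,
    Profession,
    SelfSubtype,
    SurfaceCategory,
    SurfaceType,
    Zone,
    leaf_to_zone,
)

__all__ = ["BenchmarkMarginals", "benchmark_marginals", "build_benchmark_sessions"]

_EPS = 0.5  # clearance between contact edges and an adherent hygiene action
_SPACING = 1.0  # spacing around buffer (non-adherent) hygiene actions


@dataclass(frozen=True)
class BenchmarkMarginals:
    """Pooled totals the constructed session set must carry exactly."""

    total_duration_s: float = 17790.0  # 296.5 min
    hse_per_session: tuple[int, ...] = (494, 472, 314, 495, 474, 671, 553, 176, 526, 47)

    n_right: int = 2299
    n_gloved: int = 904
    leaf_counts: dict[SurfaceType, int] = field(
        default_factory=lambda: {
            SurfaceType.PATIENT_INTACT_SKIN: 178,
            SurfaceType.MOBILE_OBJECT_INSIDE: 1383,
            SurfaceType.IMMOBILE_SURFACE_INSIDE: 214,
            SurfaceType.HCW_SELF: 439,
            SurfaceType.MOBILE_OBJECT_OUTSIDE: 1194,
            SurfaceType.IMMOBILE_SURFACE_OUTSIDE: 320,
            SurfaceType.STERILE_EQUIPMENT: 207,
            SurfaceType.INVASIVE_DEVICE_ACCESS: 238,
            SurfaceType.MUCOUS_MEMBRANE: 4,
            SurfaceType.WOUND: 45,
        }
    )
    self_subtype_counts: dict[SelfSubtype, int] = field(
        default_factory=lambda: {
            SelfSubtype.CLOTHES: 165,
            SelfSubtype.PPE: 21,
            SelfSubtype.FACE: 24,
            SelfSubtype.BARE_SKIN_OR_HAIR: 229,
        }
    )

    hse_duration_mean_s: float = 7.44
    hse_duration_sd_s: float = 14.1

    n_colonization: int = 291
    n_colonization_right: int = 152
    n_infection: int = 217
    n_infection_right: int = 114

    n_hygiene: int = 97
    n_adherent_colonization: int = 14
    n_adherent_infection: int = 3
    hygiene_duration_mean_s: float = 13.2
    hygiene_duration_sd_s: float = 8.6
    handrub_count: int = 87

    @property
    def n_hse(self) -> int:
        return sum(self.hse_per_session)

    def validate(self) -> None:
        leaves = self.leaf_counts
        n = self.n_hse
        by_zone = {
            zone: sum(c for leaf, c in leaves.items() if leaf_to_zone(leaf) is zone)
            for zone in Zone
        }
        if sum(by_zone.values()) != n:
            raise ValueError("leaf counts must sum to the total HSE count")
        if sum(self.self_subtype_counts.values()) != leaves[SurfaceType.HCW_SELF]:
            raise ValueError("self-subtype counts must sum to the HCW_SELF count")
        if not (self.n_right <= n and self.n_gloved <= n):
            raise ValueError("hand/glove counts exceed the total")
        if self.n_adherent_colonization > min(self.n_colonization, self.n_hygiene):
            raise ValueError("adherent colonization count infeasible")
        if self.n_adherent_infection > min(self.n_infection, self.n_hygiene):
            raise ValueError("adherent infection count infeasible")


def benchmark_marginals() -> BenchmarkMarginals:
    """The default campaign totals (10 sessions, 296.5 min, 4222 contacts)."""
    m = BenchmarkMarginals()
    m.validate()
    return m


def _two_point_values(n: int, mean: float, sd_like_low: float, n_high: int) -> dict[float, int]:
    """A two-point duration distribution with the exact mean.

    ``n_high`` values at the solved high point, the rest at ``sd_like_low``;
    chosen so the sample SD lands near the target (the caller picks n_high
    from the SD by moment matching; the mean is exact up to the 3-decimal
    dialect resolution).
    """
    n_low = n - n_high
    high = round((mean * n - sd_like_low * n_low) / n_high, 3)
    return {sd_like_low: n_low, high: n_high}


class _Queue:
    """Deterministic dealer over a proportionally interleaved label sequence."""

    def __init__(self, counts: dict):
        self._items = proportional_schedule(counts)
        self._pos = 0

    def take(self):
        item = self._items[self._pos]
        self._pos += 1
        return item

    def remaining(self) -> int:
        return len(self._items) - self._pos


@dataclass
class _CriticalRun:
    leaf: SurfaceType
    length: int
    site_id: str


def _critical_runs(m: BenchmarkMarginals) -> list[_CriticalRun]:
    """All infection-entry runs: leaves apportioned by token mass, lengths spread."""
    crit_leaves = [
        leaf for leaf in m.leaf_counts if leaf_to_zone(leaf) is Zone.CRITICAL_SITE
    ]
    tokens = [m.leaf_counts[leaf] for leaf in crit_leaves]
    runs_per_leaf = apportion(m.n_infection, tokens)
    lengths_by_leaf: dict[SurfaceType, list[int]] = {}
    serial: dict[SurfaceType, int] = {}
    for leaf, t, r in zip(crit_leaves, tokens, runs_per_leaf):
        if r == 0:
            if t:
                raise ValueError(f"{leaf.value}: tokens but no runs")
            lengths_by_leaf[leaf] = []
            continue
        lengths = [1] * r
        for j in range(t - r):
            lengths[j % r] += 1
        lengths_by_leaf[leaf] = lengths
        serial[leaf] = 0
    order = proportional_schedule(
        {leaf: r for leaf, r in zip(crit_leaves, runs_per_leaf)}
    )
    runs = []
    for leaf in order:
        i = serial[leaf]
        serial[leaf] += 1
        runs.append(
            _CriticalRun(
                leaf=leaf,
                length=lengths_by_leaf[leaf][i],
                site_id=f"{leaf.value.lower()}_{i % 2 + 1}",
            )
        )
    return runs


@dataclass
class _StreamPlan:
    hand: Hand
    tokens: list[tuple[Zone, _CriticalRun | None]] = field(default_factory=list)
    # pair index (origin token position) of each risk transition, in order
    colonization_at: list[int] = field(default_factory=list)
    infection_at: list[int] = field(default_factory=list)
    n_adherent_col: int = 0
    n_adherent_inf: int = 0


def _plan_stream(
    hand: Hand, m_events: int, n_col: int, n_inf: int, i_extra: int, o_extra: int,
    run_queue: list[_CriticalRun],
) -> _StreamPlan:
    """Lay out one hand's zone-token sequence as cycles O^a [I^b] [C-run]."""
    plan = _StreamPlan(hand=hand)
    if m_events == 0:
        if n_col or n_inf or i_extra or o_extra:
            raise ValueError("empty stream cannot carry quota")
        return plan
    k = max(n_col, n_inf, 1)
    runs = [run_queue.pop(0) for _ in range(n_inf)]
    # spread O tokens over the k cycle heads, I tokens over the colonization runs
    o_lengths = [1] * k
    for j in range(o_extra):
        o_lengths[j % k] += 1
    if n_col > 0:
        i_lengths = [1] * n_col
        for j in range(i_extra):
            i_lengths[j % n_col] += 1
        trailing_i = 0
    else:
        i_lengths = []
        trailing_i = i_extra  # entered from a C-run: classifies as no event

    for idx in range(k):
        for _ in range(o_lengths[idx]):
            plan.tokens.append((Zone.OUTSIDE_PATIENT_ZONE, None))
        if idx < n_col:
            plan.colonization_at.append(len(plan.tokens) - 1)
            for _ in range(i_lengths[idx]):
                plan.tokens.append((Zone.INSIDE_PATIENT_ZONE, None))
        if idx < n_inf:
            plan.infection_at.append(len(plan.tokens) - 1)
            for _ in range(runs[idx].length):
                plan.tokens.append((Zone.CRITICAL_SITE, runs[idx]))
        if idx == 0 and trailing_i:
            if n_inf == 0:
                raise ValueError("trailing inside tokens need a critical run to follow")
            for _ in range(trailing_i):
                plan.tokens.append((Zone.INSIDE_PATIENT_ZONE, None))
    if len(plan.tokens) != m_events:
        raise AssertionError(
            f"stream planned {len(plan.tokens)} tokens, expected {m_events}"
        )
    return plan


def _emit_block(
    plan: _StreamPlan,
    block_start: float,
    block_span: float,
    duration_q: _Queue,
    glove_q: _Queue,
    outside_q: _Queue,
    inside_q: _Queue,
    self_q: _Queue,
    hyg_dur_q: _Queue,
    hyg_kind_q: _Queue,
    max_hse_dur: float,
) -> tuple[list[HSEEvent], list[HygieneAction], float]:
    """Place one stream's contacts in its time block; returns (events, hygiene, block_end)."""
    m = len(plan.tokens)
    if m == 0:
        return [], [], block_start
    adherent = {
        **{p: None for p in plan.colonization_at[: plan.n_adherent_col]},
        **{p: None for p in plan.infection_at[: plan.n_adherent_inf]},
    }
    durations = [duration_q.take() for _ in range(m)]
    hyg_meta: dict[int, tuple[float, HygieneKind]] = {}
    reserve = max_hse_dur
    for p in sorted(adherent):
        h_dur = hyg_dur_q.take()
        hyg_meta[p] = (h_dur, hyg_kind_q.take())
        reserve += max_hse_dur + h_dur + 2 * _EPS
    step = (block_span - reserve) / (m + 1)
    if step <= 0.02:
        step = 0.02

    events: list[HSEEvent] = []
    hygiene: list[HygieneAction] = []
    t = block_start + step
    for idx, (zone, run) in enumerate(plan.tokens):
        start = round(t, 3)
        end = round(start + durations[idx], 3)
        if zone is Zone.OUTSIDE_PATIENT_ZONE:
            leaf = outside_q.take()
            subtype = self_q.take() if leaf is SurfaceType.HCW_SELF else None
            category = SurfaceCategory(leaf, subtype)
            surface_id = None
        elif zone is Zone.INSIDE_PATIENT_ZONE:
            category = SurfaceCategory(inside_q.take())
            surface_id = None
        else:
            category = SurfaceCategory(run.leaf)
            surface_id = run.site_id
        events.append(
            HSEEvent(
                hand=plan.hand,
                gloved=glove_q.take(),
                category=category,
                surface_id=surface_id,
                start_s=start,
                end_s=end,
            )
        )
        if idx in hyg_meta:
            h_dur, h_kind = hyg_meta[idx]
            h_start = round(end + _EPS, 3)
            h_end = round(h_start + h_dur, 3)
            hygiene.append(HygieneAction(kind=h_kind, start_s=h_start, end_s=h_end))
            t = h_end + _EPS
        else:
            t = start + step
    block_end = max(max(e.end_s for e in events), max((h.end_s for h in hygiene), default=0.0))
    if block_end > block_start + block_span + 1e-6:
        raise AssertionError("block layout exceeded its span")
    return events, hygiene, block_end


def build_benchmark_sessions(m: BenchmarkMarginals | None = None) -> list[CodedSession]:
    """Construct the session set; fully deterministic, no randomness anywhere."""
    m = m or benchmark_marginals()
    m.validate()
    n_sessions = len(m.hse_per_session)
    n_total = m.n_hse
    weights = list(m.hse_per_session)

    # session durations in integer milliseconds so the pooled total is exact
    total_ms = round(m.total_duration_s * 1000)
    dur_ms = [round(n * total_ms / n_total) for n in weights[:-1]]
    dur_ms.append(total_ms - sum(dur_ms))
    durations_s = [ms / 1000.0 for ms in dur_ms]

    # per-session and per-stream quotas (largest-remainder, so totals are exact)
    right = apportion(m.n_right, weights)
    col = apportion(m.n_colonization, weights)
    inf = apportion(m.n_infection, weights)
    col_r = apportion(m.n_colonization_right, col)
    inf_r = apportion(m.n_infection_right, inf)
    adh_col = apportion(m.n_adherent_colonization, weights)
    adh_inf = apportion(m.n_adherent_infection, weights)
    n_background = m.n_hygiene - m.n_adherent_colonization - m.n_adherent_infection
    background = apportion(n_background, weights)
    for i in range(n_sessions):
        if adh_col[i] > col[i] or adh_inf[i] > inf[i]:
            raise ValueError("adherent quota exceeds session risk quota")

    # global queues
    zone_leaves = lambda zone: {
        leaf: c
        for leaf, c in m.leaf_counts.items()
        if leaf_to_zone(leaf) is zone and c > 0
    }
    outside_q = _Queue(zone_leaves(Zone.OUTSIDE_PATIENT_ZONE))
    inside_q = _Queue(zone_leaves(Zone.INSIDE_PATIENT_ZONE))
    self_q = _Queue(dict(m.self_subtype_counts))
    glove_q = _Queue({True: m.n_gloved, False: n_total - m.n_gloved})

    # HSE durations: two-point family; the high-mass fraction reproduces the SD
    # (moment matching: p = sd^2/((high-low)... solved via the closed form below)
    low = 2.0
    r = m.hse_duration_sd_s**2 / (m.hse_duration_mean_s - low) ** 2
    p_high = 1.0 / (1.0 + r)
    n_high = max(1, round(p_high * n_total))
    dur_counts = _two_point_values(n_total, m.hse_duration_mean_s, low, n_high)
    duration_q = _Queue(dur_counts)

    h_low = 5.0
    rh = m.hygiene_duration_sd_s**2 / (m.hygiene_duration_mean_s - h_low) ** 2
    nh_high = max(1, round(m.n_hygiene / (1.0 + rh)))
    hyg_dur_q = _Queue(_two_point_values(m.n_hygiene, m.hygiene_duration_mean_s, h_low, nh_high))
    hyg_kind_q = _Queue(
        {
            HygieneKind.HANDRUB: m.handrub_count,
            HygieneKind.HANDWASH: m.n_hygiene - m.handrub_count,
        }
    )
    max_hse_dur = max(dur_counts)

    run_queue = _critical_runs(m)

    # per-stream event counts and risk quotas
    stream_meta: list[dict] = []
    for i in range(n_sessions):
        for hand in (Hand.RIGHT, Hand.LEFT):
            if hand is Hand.RIGHT:
                m_ev, c, f = right[i], col_r[i], inf_r[i]
            else:
                m_ev, c, f = weights[i] - right[i], col[i] - col_r[i], inf[i] - inf_r[i]
            stream_meta.append({"session": i, "hand": hand, "m": m_ev, "c": c, "f": f})

    # token bookkeeping: base tokens per stream, then deal the global zone extras
    runs_cursor = 0
    for s in stream_meta:
        k = max(s["c"], s["f"], 1 if s["m"] else 0)
        c_tokens = sum(r.length for r in run_queue[runs_cursor : runs_cursor + s["f"]])
        runs_cursor += s["f"]
        s["k"] = k
        s["c_tokens"] = c_tokens
        s["flex"] = s["m"] - k - s["c"] - c_tokens
        if s["flex"] < 0:
            raise AssertionError("stream too small for its risk quota")
    n_outside = sum(zone_leaves(Zone.OUTSIDE_PATIENT_ZONE).values())
    n_inside = sum(zone_leaves(Zone.INSIDE_PATIENT_ZONE).values())
    extra_o_total = n_outside - sum(s["k"] for s in stream_meta)
    extra_i_total = n_inside - m.n_colonization
    if extra_o_total < 0:
        raise AssertionError("outside-zone token budget exhausted by cycle heads")

    flexible = [s for s in stream_meta if s["c"] + s["f"] > 0]
    rigid = [s for s in stream_meta if s["c"] + s["f"] == 0]
    for s in rigid:  # all-outside streams
        s["i_extra"], s["o_extra"] = 0, s["flex"]
        extra_o_total -= s["flex"]
    shares = apportion(extra_i_total, [s["flex"] for s in flexible])
    carry = 0
    for s, share in zip(flexible, shares):
        take = min(share + carry, s["flex"])
        carry = share + carry - take
        s["i_extra"] = take
        s["o_extra"] = s["flex"] - take
    if carry:
        for s in flexible:
            room = s["o_extra"]
            move = min(room, carry)
            s["i_extra"] += move
            s["o_extra"] -= move
            carry -= move
            if carry == 0:
                break
    if carry:
        raise AssertionError("could not place all inside-zone tokens")
    if sum(s["o_extra"] for s in stream_meta) != extra_o_total:
        raise AssertionError("outside-zone token accounting mismatch")

    # build plans (consuming critical runs in the same order as the bookkeeping)
    run_cursor_list = list(run_queue)
    plans: list[_StreamPlan] = []
    for i_s, s in enumerate(stream_meta):
        plan = _plan_stream(
            s["hand"], s["m"], s["c"], s["f"], s["i_extra"], s["o_extra"], run_cursor_list
        )
        plans.append(plan)

    # adherent quota split across the session's two streams (right first)
    for i in range(n_sessions):
        p_r, p_l = plans[2 * i], plans[2 * i + 1]
        p_r.n_adherent_col = min(adh_col[i], len(p_r.colonization_at))
        p_l.n_adherent_col = adh_col[i] - p_r.n_adherent_col
        p_r.n_adherent_inf = min(adh_inf[i], len(p_r.infection_at))
        p_l.n_adherent_inf = adh_inf[i] - p_r.n_adherent_inf
        if p_l.n_adherent_col > len(p_l.colonization_at) or p_l.n_adherent_inf > len(
            p_l.infection_at
        ):
            raise AssertionError("adherent quota exceeds stream transitions")

    # emit sessions: [right block][background-hygiene buffer][left block]
    sessions: list[CodedSession] = []
    for i in range(n_sessions):
        d = durations_s[i]
        p_r, p_l = plans[2 * i], plans[2 * i + 1]
        bg_durs = [hyg_dur_q.take() for _ in range(background[i])]
        bg_kinds = [hyg_kind_q.take() for _ in range(background[i])]
        buffer_len = sum(bg_durs) + (len(bg_durs) + 1) * _SPACING
        usable = d - buffer_len
        m_r, m_l = len(p_r.tokens), len(p_l.tokens)
        span_r = usable * m_r / max(m_r + m_l, 1)
        span_l = usable - span_r

        ev_r, hy_r, block_end = _emit_block(
            p_r, 0.0, span_r, duration_q, glove_q, outside_q, inside_q, self_q,
            hyg_dur_q, hyg_kind_q, max_hse_dur,
        )
        t = span_r + _SPACING
        hy_bg: list[HygieneAction] = []
        for h_dur, h_kind in zip(bg_durs, bg_kinds):
            hy_bg.append(HygieneAction(kind=h_kind, start_s=round(t, 3), end_s=round(t + h_dur, 3)))
            t += h_dur + _SPACING
        ev_l, hy_l, _ = _emit_block(
            p_l, span_r + buffer_len, span_l, duration_q, glove_q, outside_q,
            inside_q, self_q, hyg_dur_q, hyg_kind_q, max_hse_dur,
        )
        sessions.append(
            CodedSession(
                session_id=f"bench-{i + 1:02d}",
                coded_duration_s=durations_s[i],
                profession=Profession.NURSE if i not in (7, 9) else Profession.PHYSICIAN,
                icu_specialty=("trauma", "trauma", "trauma", "trauma", "cardio-surgery",
                               "cardio-surgery", "cardio-surgery", "general surgery",
                               "cardio-surgery", "general surgery")[i],
                hse_events=ev_r + ev_l,
                hygiene_actions=hy_r + hy_bg + hy_l,
            )
        )

    for q, name in ((outside_q, "outside"), (inside_q, "inside"), (self_q, "self"),
                    (glove_q, "glove"), (duration_q, "duration"),
                    (hyg_dur_q, "hygiene duration"), (hyg_kind_q, "hygiene kind")):
        if q.remaining():
            raise AssertionError(f"{name} queue not fully consumed: {q.remaining()} left")
    if run_cursor_list:
        raise AssertionError("critical-run queue not fully consumed")
    return sessions
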