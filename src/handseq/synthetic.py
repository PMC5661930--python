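"""Seedable semi-Markov generator of coded HSE sessions.

Each hand is an alternating renewal process: surface categories follow a
Markov chain on the ten taxonomy leaves, contact (dwell) times are lognormal,
and inter-contact gaps are exponential. Hand-hygiene actions are inserted into
risk-transition gaps with configurable probability (the gap is widened so the
action fits, the way a worker pauses activity to rub), plus a background
Poisson stream of hygiene not adjacent to risk transitions. Glove state
alternates in episodes shared by both hands.

The default configuration is calibrated so the generator's *analytic*
marginals match a benchmark intensive-care observation campaign: ~14.2 HSE/min
over both hands, leaf shares giving 42/46/12% inside/outside/critical-site
zone occupancy, 21.4% gloved contacts, ~19.6 hygiene actions per hour, and
colonization/infection transition rates of ~58.9 and ~43.9 events per hour.
Dwell times carry mean 7.44 s with SD 14.1 s (strong right skew, hence the
lognormal), hygiene durations mean 13.2 s with SD 8.6 s (gamma).

The transition matrix default is the sticky rank-one family
``P = a*I + (1-a) * 1 pi^T``: its stationary law is exactly the observed leaf
share vector ``pi`` for any stickiness ``a``, and ``a`` (with the same-site
retention probability ``q``) is solved in closed form from the target
colonization and infection rates — see :func:`default_generator_config`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import networkx as nx
import numpy as np

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
from .risk_events import RiskKind

__all__ = [
    "LEAVES",
    "OBSERVED_LEAF_SHARES",
    "ConfigurationError",
    "LognormalDwell",
    "HygieneModel",
    "GloveModel",
    "HandCoupling",
    "GeneratorConfig",
    "ExpectedRates",
    "default_generator_config",
    "stationary_distribution",
    "expected_event_rates",
    "generate_session",
]

#: Canonical leaf order used for all vectors/matrices in this module.
LEAVES: tuple[SurfaceType, ...] = tuple(SurfaceType)

#: Leaf shares of the benchmark observation campaign (4222 contacts):
#: inside 1775 (skin 178, mobile 1383, immobile 214), outside 1953
#: (self 439, mobile 1194, immobile 320), critical 494 (sterile 207,
#: invasive 238, mucous 4, wound 45).
OBSERVED_LEAF_SHARES: dict[SurfaceType, float] = {
    SurfaceType.PATIENT_INTACT_SKIN: 178 / 4222,
    SurfaceType.MOBILE_OBJECT_INSIDE: 1383 / 4222,
    SurfaceType.IMMOBILE_SURFACE_INSIDE: 214 / 4222,
    SurfaceType.HCW_SELF: 439 / 4222,
    SurfaceType.MOBILE_OBJECT_OUTSIDE: 1194 / 4222,
    SurfaceType.IMMOBILE_SURFACE_OUTSIDE: 320 / 4222,
    SurfaceType.STERILE_EQUIPMENT: 207 / 4222,
    SurfaceType.INVASIVE_DEVICE_ACCESS: 238 / 4222,
    SurfaceType.MUCOUS_MEMBRANE: 4 / 4222,
    SurfaceType.WOUND: 45 / 4222,
}

_SELF_SUBTYPE_SHARES: dict[SelfSubtype, float] = {
    SelfSubtype.CLOTHES: 165 / 439,
    SelfSubtype.PPE: 21 / 439,
    SelfSubtype.FACE: 24 / 439,
    SelfSubtype.BARE_SKIN_OR_HAIR: 229 / 439,
}

_HYGIENE_MARGIN_S = 0.5  # clearance between a contact edge and an inserted action


class ConfigurationError(ValueError):
    """The generator configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class LognormalDwell:
    """Contact-duration model, parameterized on the natural scale.

    ``mu``/``sigma`` are the log-scale parameters obtained by moment matching:
    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.
    """

    mean_s: float = 7.44
    sd_s: float = 14.1

    def __post_init__(self) -> None:
        if self.mean_s <= 0 or self.sd_s < 0:
            raise ConfigurationError("dwell mean must be > 0 and sd >= 0")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p((self.sd_s / self.mean_s) ** 2))

    @property
    def mu(self) -> float:
        return math.log(self.mean_s) - self.sigma**2 / 2.0


@dataclass(frozen=True)
class HygieneModel:
    """Hygiene sub-model.

    ``p_colonization``/``p_infection``: probability that the gap of a risk
    transition of that kind receives an (adherent) hygiene action.
    ``background_per_hour``: Poisson rate of actions not tied to risk gaps —
    observed campaigns perform far more hygiene than their few adherent
    actions. Durations are gamma with the given mean/SD.
    """

    p_colonization: float = 0.048
    p_infection: float = 0.014
    background_per_hour: float = 16.2
    duration_mean_s: float = 13.2
    duration_sd_s: float = 8.6
    handrub_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name in ("p_colonization", "p_infection", "handrub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.background_per_hour < 0 or self.duration_mean_s <= 0 or self.duration_sd_s < 0:
            raise ConfigurationError("hygiene rates must be >= 0 and duration mean > 0")

    @property
    def gamma_shape(self) -> float:
        return (self.duration_mean_s / self.duration_sd_s) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.duration_sd_s**2 / self.duration_mean_s


@dataclass(frozen=True)
class GloveModel:
    """Alternating gloved/bare episodes shared by both hands.

    ``gloved_fraction`` is the long-run fraction of time (hence, of contacts)
    spent gloved; episode lengths are exponential with the given gloved-episode
    mean, the bare mean following from the target fraction.
    """

    gloved_fraction: float = 904 / 4222
    gloved_episode_mean_s: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gloved_fraction < 1.0:
            raise ConfigurationError("gloved_fraction must be in [0, 1)")
        if self.gloved_episode_mean_s <= 0:
            raise ConfigurationError("gloved_episode_mean_s must be > 0")

    @property
    def bare_episode_mean_s(self) -> float:
        f = self.gloved_fraction
        if f == 0.0:
            return math.inf
        return self.gloved_episode_mean_s * (1.0 - f) / f


class HandCoupling(str, Enum):
    INDEPENDENT = "INDEPENDENT"
    MIRRORED = "MIRRORED"


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the session generator. See module docstring."""

    transition_matrix: np.ndarray  # row-stochastic, LEAVES order
    initial_distribution: np.ndarray
    dwell: LognormalDwell = LognormalDwell()
    dwell_overrides: Mapping[SurfaceType, LognormalDwell] = field(default_factory=dict)
    gap_mean_s: Mapping[Hand, float] = field(
        default_factory=lambda: {Hand.LEFT: 1.7, Hand.RIGHT: 0.2}
    )
    session_duration_s: float = 1800.0
    hygiene: HygieneModel = HygieneModel()
    glove: GloveModel = GloveModel()
    same_site_retention: float = 0.68  # P(same surface_id | repeated critical leaf)
    site_pool_size: int = 2
    hand_coupling: HandCoupling = HandCoupling.INDEPENDENT
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_distribution", pi0)
        n = len(LEAVES)
        if P.shape != (n, n):
            raise ConfigurationError(f"transition matrix must be {n}x{n}")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigurationError("transition matrix rows must be simplex vectors")
        if pi0.shape != (n,) or np.any(pi0 < 0) or abs(pi0.sum() - 1.0) > 1e-12:
            raise ConfigurationError("initial distribution must be a length-10 simplex vector")
        if not 0.0 <= self.same_site_retention <= 1.0:
            raise ConfigurationError("same_site_retention must be in [0, 1]")
        if self.site_pool_size < 1:
            raise ConfigurationError("site_pool_size must be >= 1")
        for hand in Hand:
            if self.gap_mean_s[hand] < 0:
                raise ConfigurationError("gap means must be >= 0")
        if self.session_duration_s <= 0:
            raise ConfigurationError("session_duration_s must be > 0")
        if self.dwell.mean_s >= self.session_duration_s:
            raise ConfigurationError(
                "infeasible: mean dwell time exceeds the session duration"
            )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "leaves": [leaf.value for leaf in LEAVES],
            "transition_matrix": np.asarray(self.transition_matrix).tolist(),
            "initial_distribution": np.asarray(self.initial_distribution).tolist(),
            "dwell": {"mean_s": self.dwell.mean_s, "sd_s": self.dwell.sd_s},
            "gap_mean_s": {h.value: self.gap_mean_s[h] for h in Hand},
            "session_duration_s": self.session_duration_s,
            "hygiene": {
                "p_colonization": self.hygiene.p_colonization,
                "p_infection": self.hygiene.p_infection,
                "background_per_hour": self.hygiene.background_per_hour,
                "duration_mean_s": self.hygiene.duration_mean_s,
                "duration_sd_s": self.hygiene.duration_sd_s,
                "handrub_fraction": self.hygiene.handrub_fraction,
            },
            "glove": {
                "gloved_fraction": self.glove.gloved_fraction,
                "gloved_episode_mean_s": self.glove.gloved_episode_mean_s,
            },
            "same_site_retention": self.same_site_retention,
            "site_pool_size": self.site_pool_size,
            "hand_coupling": self.hand_coupling.value,
            "seed": self.seed,
        }


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary law of an irreducible aperiodic row-stochastic matrix.

    Solved as the null space of (P^T - I) with the normalization row appended;
    raises a diagnostic error for reducible or periodic chains (for which the
    usual power-iteration cross-check would not converge).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("P must be row-stochastic")
    g = nx.DiGraph((np.asarray(P) > 0).astype(int))
    if not nx.is_strongly_connected(g):
        raise ValueError("P is reducible: no unique stationary distribution")
    if not nx.is_aperiodic(g):
        raise ValueError("P is periodic: power iteration would not converge")
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


_ZONE_OF = np.array([leaf_to_zone(leaf).value for leaf in LEAVES])
_IS_INSIDE = _ZONE_OF == Zone.INSIDE_PATIENT_ZONE.value
_IS_OUTSIDE = _ZONE_OF == Zone.OUTSIDE_PATIENT_ZONE.value
_IS_CRITICAL = _ZONE_OF == Zone.CRITICAL_SITE.value


@dataclass(frozen=True)
class ExpectedRates:
    """Analytic event rates implied by a configuration (both hands combined)."""

    colonization_per_transition: float
    infection_per_transition: float
    hse_per_hour: float
    colonization_per_hour: float
    infection_per_hour: float


def _per_hand_contact_rate(config: GeneratorConfig, hand: Hand, p_insert: float) -> float:
    """Contacts per second for one hand, accounting for hygiene-widened gaps."""
    inserted_gap = 2 * _HYGIENE_MARGIN_S + config.hygiene.duration_mean_s
    eff_gap = (1.0 - p_insert) * config.gap_mean_s[hand] + p_insert * inserted_gap
    return 1.0 / (config.dwell.mean_s + eff_gap)


def expected_event_rates(config: GeneratorConfig) -> ExpectedRates:
    """Colonization/infection rates per transition and per hour under the config.

    Per-transition rates follow from the stationary law pi of the leaf chain:
    colonization = sum over outside origins i, non-critical inside
    destinations j of pi_i P_ij; infection sums transitions into critical
    leaves, excluding the same-site fraction of self-transitions (retention q
    plus a 1/pool chance of redrawing the same site). Per-hour rates scale by
    the expected contact throughput of both hands.
    """
    P = config.transition_matrix
    pi = stationary_distribution(P)
    col = float(pi[_IS_OUTSIDE] @ P[np.ix_(_IS_OUTSIDE, _IS_INSIDE)].sum(axis=1))

    q = config.same_site_retention
    k = config.site_pool_size
    p_same_given_repeat = q + (1.0 - q) / k
    inf = 0.0
    for j in np.flatnonzero(_IS_CRITICAL):
        into_j = float(pi @ P[:, j])
        diag = float(pi[j] * P[j, j])
        inf += (into_j - diag) + diag * (1.0 - p_same_given_repeat)
    p_insert = col * config.hygiene.p_colonization + inf * config.hygiene.p_infection
    transitions_per_hour = sum(
        3600.0 * _per_hand_contact_rate(config, hand, p_insert) for hand in Hand
    )
    return ExpectedRates(
        colonization_per_transition=col,
        infection_per_transition=inf,
        hse_per_hour=transitions_per_hour,
        colonization_per_hour=col * transitions_per_hour,
        infection_per_hour=inf * transitions_per_hour,
    )


def default_generator_config(
    seed: int = 0,
    *,
    session_duration_s: float = 1800.0,
    target_density_per_min: float = 4222 / 296.5,
    target_colonization_per_hour: float = 291 / 296.5 * 60.0,
    target_infection_per_hour: float = 217 / 296.5 * 60.0,
    target_hygiene_per_hour: float = 97 / 296.5 * 60.0,
    right_hand_share: float = 2299 / 4222,
) -> GeneratorConfig:
    """Build the calibrated default configuration.

    The sticky rank-one chain ``P = a*I + (1-a) 1 pi^T`` has stationary law
    ``pi`` (the observed leaf shares) for any ``a``. Stickiness ``a`` is solved
    so the colonization rate per transition times the target throughput hits
    the target colonization rate; the same-site retention ``q`` is then solved
    from the infection-rate target. Per-hand gap means are solved from the
    density target, subtracting the expected widening of hygiene-inserted
    gaps.
    """
    pi = np.array([OBSERVED_LEAF_SHARES[leaf] for leaf in LEAVES])
    pi = pi / pi.sum()

    transitions_per_hour = target_density_per_min * 60.0
    col_needed = target_colonization_per_hour / transitions_per_hour
    pi_out = float(pi[_IS_OUTSIDE].sum())
    pi_in = float(pi[_IS_INSIDE].sum())
    one_minus_a = col_needed / (pi_out * pi_in)
    if not 0.0 < one_minus_a <= 1.0:
        raise ConfigurationError("colonization target infeasible for the rank-one family")
    a = 1.0 - one_minus_a

    P = a * np.eye(len(LEAVES)) + one_minus_a * np.outer(np.ones(len(LEAVES)), pi)

    # infection: off-diagonal transitions into critical leaves are fixed by a;
    # the diagonal (repeated-leaf) part is tuned through the same-site
    # retention q with pool size k=2
    inf_needed = target_infection_per_hour / transitions_per_hour
    crit = np.flatnonzero(_IS_CRITICAL)
    diag_mass = float(sum(pi[j] * P[j, j] for j in crit))
    off_diag = float(sum(pi @ P[:, j] for j in crit)) - diag_mass
    k = 2
    # diag contribution = diag_mass * (1 - (q + (1-q)/k))
    residual = inf_needed - off_diag
    if residual < -1e-9 or (diag_mass == 0 and residual > 1e-9):
        raise ConfigurationError("infection target infeasible for the rank-one family")
    frac_different = min(max(residual / diag_mass, 0.0), 1.0) if diag_mass else 0.0
    # 1 - q - (1-q)/k = frac_different  =>  (1-q)(1 - 1/k) = frac_different
    q = 1.0 - frac_different / (1.0 - 1.0 / k)
    q = min(max(q, 0.0), 1.0)

    hygiene = HygieneModel(
        p_colonization=0.048,
        p_infection=0.014,
        background_per_hour=target_hygiene_per_hour
        - 0.048 * target_colonization_per_hour
        - 0.014 * target_infection_per_hour,
    )

    # per-hand gap means from the density target, correcting for inserted gaps
    dwell = LognormalDwell()
    col_rate = one_minus_a * pi_out * pi_in
    inf_rate = inf_needed
    p_insert = col_rate * hygiene.p_colonization + inf_rate * hygiene.p_infection
    inserted_gap = 2 * _HYGIENE_MARGIN_S + hygiene.duration_mean_s
    gap_means: dict[Hand, float] = {}
    for hand, share in ((Hand.RIGHT, right_hand_share), (Hand.LEFT, 1.0 - right_hand_share)):
        cycle = 3600.0 / (transitions_per_hour * share)
        gap = (cycle - dwell.mean_s - p_insert * inserted_gap) / (1.0 - p_insert)
        if gap <= 0:
            raise ConfigurationError(
                f"density target infeasible: {hand.value} hand cycle {cycle:.2f}s "
                f"shorter than the mean dwell {dwell.mean_s}s"
            )
        gap_means[hand] = gap

    return GeneratorConfig(
        transition_matrix=P,
        initial_distribution=pi,
        dwell=dwell,
        gap_mean_s=gap_means,
        session_duration_s=session_duration_s,
        hygiene=hygiene,
        glove=GloveModel(),
        same_site_retention=q,
        site_pool_size=k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _glove_intervals(rng: np.random.Generator, glove: GloveModel, duration: float) -> list[tuple[float, float]]:
    """Gloved time intervals covering [0, duration].

    The alternating process is started in its stationary state (gloved with
    probability ``gloved_fraction``, exponential residual episode), so the
    time fraction spent gloved is unbiased even for short sessions.
    """
    if glove.gloved_fraction == 0.0:
        return []
    out: list[tuple[float, float]] = []
    t = 0.0
    if rng.random() < glove.gloved_fraction:
        g_end = rng.exponential(glove.gloved_episode_mean_s)
        out.append((0.0, min(g_end, duration)))
        t = g_end
    while t < duration:
        t += rng.exponential(glove.bare_episode_mean_s)
        if t >= duration:
            break
        g_end = t + rng.exponential(glove.gloved_episode_mean_s)
        out.append((t, min(g_end, duration)))
        t = g_end
    return out


def _is_gloved(t: float, intervals: list[tuple[float, float]]) -> bool:
    for start, end in intervals:
        if start <= t < end:
            return True
        if start > t:
            break
    return False


def _site_pool(leaf: SurfaceType, k: int) -> list[str]:
    return [f"{leaf.value.lower()}_{i + 1}" for i in range(k)]


def _risk_kind_of(origin_leaf: SurfaceType, origin_site: str | None,
                  dest_leaf: SurfaceType, dest_site: str | None) -> RiskKind | None:
    """Risk classification used for hygiene insertion (same-site exclusion rule)."""
    oz, dz = leaf_to_zone(origin_leaf), leaf_to_zone(dest_leaf)
    if dz is Zone.CRITICAL_SITE:
        if oz is Zone.CRITICAL_SITE and origin_leaf is dest_leaf and origin_site == dest_site:
            return None
        return RiskKind.INFECTION
    if dz is Zone.INSIDE_PATIENT_ZONE and oz is Zone.OUTSIDE_PATIENT_ZONE:
        return RiskKind.COLONIZATION
    return None


def _hygiene_duration(rng: np.random.Generator, model: HygieneModel) -> float:
    return max(2.0, float(rng.gamma(model.gamma_shape, model.gamma_scale)))


def _hygiene_kind(rng: np.random.Generator, model: HygieneModel) -> HygieneKind:
    return HygieneKind.HANDRUB if rng.random() < model.handrub_fraction else HygieneKind.HANDWASH


def _simulate_hand(
    config: GeneratorConfig,
    hand: Hand,
    rng: np.random.Generator,
    glove_intervals: list[tuple[float, float]],
) -> tuple[list[HSEEvent], list[HygieneAction]]:
    P = np.asarray(config.transition_matrix)
    cum_rows = np.cumsum(P, axis=1)
    cum_init = np.cumsum(np.asarray(config.initial_distribution))
    duration = config.session_duration_s
    q3 = lambda t: round(t, 3)

    def draw_leaf(cum: np.ndarray) -> int:
        return int(np.searchsorted(cum, rng.random(), side="right"))

    def dwell_for(leaf: SurfaceType) -> float:
        model = config.dwell_overrides.get(leaf, config.dwell)
        return float(rng.lognormal(model.mu, model.sigma))

    def site_for(leaf: SurfaceType, prev_leaf: SurfaceType | None, prev_site: str | None) -> str | None:
        if leaf_to_zone(leaf) is not Zone.CRITICAL_SITE:
            return None
        pool = _site_pool(leaf, config.site_pool_size)
        if prev_leaf is leaf and prev_site is not None:
            if rng.random() < config.same_site_retention:
                return prev_site
        return pool[int(rng.integers(len(pool)))]

    events: list[HSEEvent] = []
    hygiene: list[HygieneAction] = []
    i = draw_leaf(cum_init)
    site = site_for(LEAVES[i], None, None)
    t = float(rng.exponential(config.gap_mean_s[hand]))
    while t < duration - 1e-3:
        leaf = LEAVES[i]
        end = min(t + dwell_for(leaf), duration)
        if end - t > 1e-3:
            start_q, end_q = q3(t), q3(end)
            if end_q > start_q:
                events.append(
                    HSEEvent(
                        hand=hand,
                        gloved=_is_gloved(start_q, glove_intervals),
                        category=SurfaceCategory(
                            leaf,
                            _self_subtype(rng) if leaf is SurfaceType.HCW_SELF else None,
                        ),
                        surface_id=site,
                        start_s=start_q,
                        end_s=end_q,
                    )
                )
        if end >= duration:
            break
        j = draw_leaf(cum_rows[i])
        next_site = site_for(LEAVES[j], leaf, site)
        kind = _risk_kind_of(leaf, site, LEAVES[j], next_site)
        p_ins = {
            RiskKind.COLONIZATION: config.hygiene.p_colonization,
            RiskKind.INFECTION: config.hygiene.p_infection,
            None: 0.0,
        }[kind]
        if p_ins > 0.0 and rng.random() < p_ins:
            h_dur = _hygiene_duration(rng, config.hygiene)
            h_start = end + _HYGIENE_MARGIN_S
            h_end = h_start + h_dur
            if h_end + _HYGIENE_MARGIN_S < duration:
                hygiene.append(
                    HygieneAction(kind=_hygiene_kind(rng, config.hygiene), start_s=q3(h_start), end_s=q3(h_end))
                )
                t = h_end + _HYGIENE_MARGIN_S
            else:
                t = duration
        else:
            t = end + float(rng.exponential(config.gap_mean_s[hand]))
        i, site = j, next_site
    return events, hygiene


_SELF_CUM = np.cumsum([_SELF_SUBTYPE_SHARES[s] for s in SelfSubtype])


def _self_subtype(rng: np.random.Generator) -> SelfSubtype:
    return list(SelfSubtype)[int(np.searchsorted(_SELF_CUM, rng.random(), side="right"))]


def generate_session(config: GeneratorConfig) -> CodedSession:
    """Simulate one coded session; identical seed, identical session.

    Sub-streams (left hand, right hand, background hygiene, gloves) use
    deterministically derived child RNGs, so toggling one sub-model does not
    perturb the draws of the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_left, rng_right, rng_bg, rng_glove = (np.random.default_rng(c) for c in ss.spawn(4))

    glove_iv = _glove_intervals(rng_glove, config.glove, config.session_duration_s)

    if config.hand_coupling is HandCoupling.MIRRORED:
        right_events, right_hyg = _simulate_hand(config, Hand.RIGHT, rng_right, glove_iv)
        left_events = [replace(e, hand=Hand.LEFT) for e in right_events]
        hands_events = right_events + left_events
        inserted_hygiene = right_hyg
    else:
        right_events, right_hyg = _simulate_hand(config, Hand.RIGHT, rng_right, glove_iv)
        left_events, left_hyg = _simulate_hand(config, Hand.LEFT, rng_left, glove_iv)
        hands_events = right_events + left_events
        inserted_hygiene = right_hyg + left_hyg

    # background hygiene stream (not tied to risk gaps)
    duration = config.session_duration_s
    n_bg = int(rng_bg.poisson(config.hygiene.background_per_hour * duration / 3600.0))
    bg: list[HygieneAction] = []
    for _ in range(n_bg):
        start = float(rng_bg.uniform(0.0, duration))
        dur = _hygiene_duration(rng_bg, config.hygiene)
        end = min(start + dur, duration)
        if end - start > 1e-3:
            bg.append(
                HygieneAction(kind=_hygiene_kind(rng_bg, config.hygiene), start_s=round(start, 3), end_s=round(end, 3))
            )

    return CodedSession(
        session_id=f"sim-{config.seed}",
        coded_duration_s=round(duration, 3),
        profession=Profession.NURSE,
        icu_specialty="trauma",
        hse_events=hands_events,
        hygiene_actions=inserted_hygiene + bg,
    )
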