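"""Generator calibration, stationary analysis, and simulation statistics."""

from __future__ import annotations

import io
import math

import numpy as np
import pytest

from handseq.event_model import Hand, Zone, leaf_to_zone, validate_session, write_session_log
from handseq.risk_events import RiskKind, attach_hygiene, detect_risk_events
from handseq.synthetic import (
    ConfigurationError,
    GloveModel,
    HygieneModel,
    LEAVES,
    LognormalDwell,
    default_generator_config,
    expected_event_rates,
    generate_session,
    stationary_distribution,
)
from dataclasses import replace


class TestStationaryDistribution:
    def test_uniform_rows_give_uniform_law(self):
        P = np.full((4, 4), 0.25)
        assert np.allclose(stationary_distribution(P), 0.25)

    def test_two_state_closed_form(self):
        a, b = 0.3, 0.1
        P = np.array([[1 - a, a], [b, 1 - b]])
        pi = stationary_distribution(P)
        assert np.allclose(pi, [b / (a + b), a / (a + b)], atol=1e-12)

    def test_agrees_with_power_iteration(self, default_config):
        P = default_config.transition_matrix
        pi = stationary_distribution(P)
        v = np.full(len(LEAVES), 1.0 / len(LEAVES))
        for _ in range(10_000):
            v = v @ P
        assert np.max(np.abs(v - pi)) < 1e-10

    def test_reducible_chain_is_diagnosed(self):
        P = np.eye(3)
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(P)

    def test_periodic_chain_is_diagnosed(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="periodic"):
            stationary_distribution(P)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            stationary_distribution(np.array([[0.5, 0.6], [0.5, 0.5]]))


class TestDefaultConfig:
    def test_rows_are_stochastic(self, default_config):
        P = default_config.transition_matrix
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_stationary_zone_shares_match_observed(self, default_config):
        pi = stationary_distribution(default_config.transition_matrix)
        shares = {zone: 0.0 for zone in Zone}
        for leaf, p in zip(LEAVES, pi):
            shares[leaf_to_zone(leaf)] += p
        assert abs(shares[Zone.INSIDE_PATIENT_ZONE] - 0.42) < 0.01
        assert abs(shares[Zone.OUTSIDE_PATIENT_ZONE] - 0.46) < 0.01
        assert abs(shares[Zone.CRITICAL_SITE] - 0.12) < 0.01

    def test_analytic_hygiene_rate_near_target(self, default_config):
        er = expected_event_rates(default_config)
        hygiene_per_hour = (
            default_config.hygiene.background_per_hour
            + default_config.hygiene.p_colonization * er.colonization_per_hour
            + default_config.hygiene.p_infection * er.infection_per_hour
        )
        assert abs(hygiene_per_hour - 19.6) < 0.5

    def test_analytic_event_rates_hit_calibration_targets(self, default_config):
        er = expected_event_rates(default_config)
        assert math.isclose(er.colonization_per_hour, 291 / 296.5 * 60, rel_tol=1e-9)
        assert math.isclose(er.infection_per_hour, 217 / 296.5 * 60, rel_tol=1e-9)
        assert math.isclose(er.hse_per_hour / 60.0, 4222 / 296.5, rel_tol=1e-9)

    def test_infeasible_dwell_rejected(self):
        with pytest.raises(ConfigurationError, match="infeasible"):
            default_generator_config(session_duration_s=5.0)

    def test_lognormal_moment_matching(self):
        d = LognormalDwell(mean_s=7.44, sd_s=14.1)
        mean = math.exp(d.mu + d.sigma**2 / 2)
        var = (math.exp(d.sigma**2) - 1) * math.exp(2 * d.mu + d.sigma**2)
        assert math.isclose(mean, 7.44, rel_tol=1e-12)
        assert math.isclose(math.sqrt(var), 14.1, rel_tol=1e-12)


class TestExpectedRates:
    def test_no_outside_to_inside_mass_means_no_colonization(self, default_config):
        # block every outside -> inside transition and renormalize
        P = default_config.transition_matrix.copy()
        outside = [i for i, leaf in enumerate(LEAVES) if leaf_to_zone(leaf) is Zone.OUTSIDE_PATIENT_ZONE]
        inside = [i for i, leaf in enumerate(LEAVES) if leaf_to_zone(leaf) is Zone.INSIDE_PATIENT_ZONE]
        for i in outside:
            P[i, inside] = 0.0
            P[i] /= P[i].sum()
        cfg = replace(default_config, transition_matrix=P)
        assert expected_event_rates(cfg).colonization_per_transition == 0.0

    def test_iid_chain_matches_hand_computed_closed_form(self, default_config):
        """For P = 1 pi^T the rates have elementary closed forms."""
        pi = np.array([1, 20, 3, 8, 25, 5, 6, 12, 2, 18], dtype=float)
        pi /= pi.sum()
        P = np.outer(np.ones(10), pi)
        q, k = 0.7, 2
        cfg = replace(default_config, transition_matrix=P, initial_distribution=pi,
                      same_site_retention=q, site_pool_size=k)
        er = expected_event_rates(cfg)
        z = np.array([leaf_to_zone(leaf).value for leaf in LEAVES])
        p_out = pi[z == Zone.OUTSIDE_PATIENT_ZONE.value].sum()
        p_in = pi[z == Zone.INSIDE_PATIENT_ZONE.value].sum()
        assert math.isclose(er.colonization_per_transition, p_out * p_in, abs_tol=1e-12)
        p_same = q + (1 - q) / k
        expected_inf = sum(
            pj - pj**2 * p_same for pj in pi[z == Zone.CRITICAL_SITE.value]
        )
        assert math.isclose(er.infection_per_transition, expected_inf, abs_tol=1e-12)

    def test_monte_carlo_frequencies_within_three_se(self, default_config):
        """Simulated per-transition event frequencies vs the analytic oracle."""
        cfg = replace(default_config, session_duration_s=3600.0)
        er = expected_event_rates(cfg)
        n_trans = n_col = n_inf = 0
        for i in range(8):
            s = generate_session(cfg.with_seed(900 + i))
            events = detect_risk_events(s)
            for hand in Hand:
                n_trans += max(0, sum(1 for e in s.hse_events if e.hand is hand) - 1)
            n_col += sum(1 for e in events if e.kind is RiskKind.COLONIZATION)
            n_inf += sum(1 for e in events if e.kind is RiskKind.INFECTION)
        for observed, p in ((n_col, er.colonization_per_transition), (n_inf, er.infection_per_transition)):
            se = math.sqrt(p * (1 - p) / n_trans)
            assert abs(observed / n_trans - p) < 3 * se


class TestGenerateSession:
    def test_identical_seed_identical_bytes(self, default_config):
        logs = []
        for _ in range(2):
            buf = io.StringIO()
            write_session_log(generate_session(default_config.with_seed(31)), buf)
            logs.append(buf.getvalue())
        assert logs[0] == logs[1]

    def test_distinct_seeds_differ(self, default_config):
        a = generate_session(default_config.with_seed(1))
        b = generate_session(default_config.with_seed(2))
        assert a != b

    def test_generated_sessions_are_valid(self, default_config):
        for seed in range(5):
            s = generate_session(default_config.with_seed(seed))
            report = validate_session(s)
            assert report.ok, report.errors[:3]

    def test_pooled_density_within_five_percent_of_target(self, default_config):
        n_ev = 0
        minutes = 0.0
        for i in range(20):
            s = generate_session(default_config.with_seed(100 + i))
            n_ev += len(s.hse_events)
            minutes += s.coded_duration_s / 60.0
        assert abs(n_ev / minutes - 4222 / 296.5) / (4222 / 296.5) < 0.05

    def test_gloved_fraction_near_target(self, default_config):
        n = gloved = 0
        for i in range(20):
            s = generate_session(default_config.with_seed(300 + i))
            n += len(s.hse_events)
            gloved += sum(1 for e in s.hse_events if e.gloved)
        assert abs(gloved / n - 904 / 4222) < 0.05

    def test_certain_hygiene_gives_full_adherence(self, default_config):
        cfg = replace(
            default_config,
            hygiene=HygieneModel(p_colonization=1.0, p_infection=1.0, background_per_hour=0.0),
        )
        s = generate_session(cfg.with_seed(77))
        events = detect_risk_events(s)
        attach_hygiene(events, s.hygiene_actions)
        assert events and all(e.preceded_by_hygiene for e in events)

    def test_no_hygiene_gives_zero_adherence(self, default_config):
        cfg = replace(
            default_config,
            hygiene=HygieneModel(p_colonization=0.0, p_infection=0.0, background_per_hour=0.0),
        )
        s = generate_session(cfg.with_seed(78))
        events = detect_risk_events(s)
        attach_hygiene(events, s.hygiene_actions)
        assert not s.hygiene_actions
        assert events and not any(e.preceded_by_hygiene for e in events)

    def test_mirrored_hands_share_the_trajectory(self, default_config):
        from handseq.synthetic import HandCoupling

        cfg = replace(default_config, hand_coupling=HandCoupling.MIRRORED)
        s = generate_session(cfg.with_seed(5))
        left = [(e.start_s, e.surface_type) for e in s.hse_events if e.hand is Hand.LEFT]
        right = [(e.start_s, e.surface_type) for e in s.hse_events if e.hand is Hand.RIGHT]
        assert left == right

    def test_transition_matrix_recovery_moderate_sample(self, default_config):
        """Empirical row-normalized transition counts approach P.

        At this sample size the entrywise binomial z-check is restricted to
        cells with expected count >= 10 (normal-approximation validity); the
        joint-frequency total-variation distance covers the rest.
        """
        cfg = replace(default_config, session_duration_s=3600.0)
        idx = {leaf: i for i, leaf in enumerate(LEAVES)}
        N = np.zeros((10, 10))
        for i in range(6):
            s = generate_session(cfg.with_seed(400 + i))
            for hand in Hand:
                seq = [idx[e.surface_type] for e in s.hse_events if e.hand is hand]
                for a, b in zip(seq, seq[1:]):
                    N[a, b] += 1
        rows = N.sum(axis=1, keepdims=True)
        P = cfg.transition_matrix
        expected = rows * P
        mask = expected >= 10
        se = np.sqrt(P * (1 - P) / rows)
        z = np.abs(N / rows - P) / se
        assert np.all(z[mask] < 3.0)
        pi = stationary_distribution(P)
        tv = 0.5 * np.abs(N / N.sum() - pi[:, None] * P).sum()
        assert tv < 0.05

    def test_glove_model_zero_fraction(self, default_config):
        cfg = replace(default_config, glove=GloveModel(gloved_fraction=0.0))
        s = generate_session(cfg.with_seed(9))
        assert not any(e.gloved for e in s.hse_events)
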