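import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsisim import (
    QCPolicy,
    QualityModel,
    ScannerProfile,
    SlideSpec,
    expected_relative_time,
    missed_fraction,
    run_slide,
    simulate_batch,
    simulate_fleet,
    simulate_relative_times,
)


def slide(q=None, sid="s"):
    return SlideSpec(sid, "biopsy", 100.0, true_quality=q)


def slides(n, q=None):
    return [slide(q, f"s{i}") for i in range(n)]


class TestRunSlide:
    def test_pass_through_path(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=0.0,
            quality=QualityModel(sigma=0.0, threshold=0.5),
            control_rate=0.0,
        )
        rec = run_slide(slide(q=0.9), poisson_profile, policy, np.random.default_rng(0))
        assert len(rec.events) == 1
        assert rec.disposition == "accepted"
        assert not (rec.flagged_external or rec.visually_reviewed or rec.control_sampled)

    def test_forced_auto_rescan_scales_original_duration(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=1.0,
            rescan_multiplier=2.0,
            quality=QualityModel(sigma=0.0, threshold=-math.inf),
            control_rate=0.0,
        )
        rec = run_slide(slide(q=0.9), poisson_profile, policy, np.random.default_rng(1))
        assert len(rec.events) == 2
        assert rec.events[1].stringent
        assert rec.events[1].duration_s == 2.0 * rec.events[0].duration_s

    def test_rescan_load_charging_flag(self, poisson_profile):
        base = dict(
            auto_rescan_rate=1.0,
            rescan_multiplier=1.5,
            quality=QualityModel(sigma=0.0, threshold=-math.inf),
            control_rate=0.0,
        )
        with_load = run_slide(
            slide(q=0.9), poisson_profile,
            QCPolicy(rescan_includes_load=True, **base), np.random.default_rng(2),
        )
        without = run_slide(
            slide(q=0.9), poisson_profile,
            QCPolicy(rescan_includes_load=False, **base), np.random.default_rng(2),
        )
        assert with_load.events[1].load_s == 10.0
        assert without.events[1].load_s == 0.0

    def test_already_rescanned_flagged_slide_is_rejected_not_rescanned(
        self, poisson_profile
    ):
        """A slide that used its one rescan (internal QC), then fails external
        QC and is declined at visual review, is rejected with no third scan."""
        policy = QCPolicy(
            auto_rescan_rate=1.0,
            quality=QualityModel(sigma=0.0, threshold=0.5),
            visual_accept_prob=0.0,
            control_rate=0.0,
            max_rescans=1,
        )
        rec = run_slide(slide(q=0.2), poisson_profile, policy, np.random.default_rng(3))
        assert len(rec.events) == 2
        assert rec.disposition == "rejected"
        assert rec.flagged_external and rec.visually_reviewed

    def test_visual_decline_triggers_qc_rescan_when_budget_remains(
        self, poisson_profile
    ):
        policy = QCPolicy(
            auto_rescan_rate=0.0,
            quality=QualityModel(sigma=0.0, threshold=0.5),
            visual_accept_prob=0.0,
            control_rate=0.0,
            max_rescans=1,
        )
        rec = run_slide(slide(q=0.2), poisson_profile, policy, np.random.default_rng(4))
        # rescan happens, second observation is still below threshold -> rejected
        assert len(rec.events) == 2 and rec.events[1].stringent
        assert rec.disposition == "rejected"

    def test_zero_rescan_budget_still_terminates(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=1.0,
            quality=QualityModel(sigma=0.0, threshold=0.5),
            visual_accept_prob=0.0,
            control_rate=0.0,
            max_rescans=0,
        )
        rec = run_slide(slide(q=0.2), poisson_profile, policy, np.random.default_rng(5))
        assert len(rec.events) == 1
        assert rec.disposition == "rejected"

    def test_control_review_catches_bad_slide(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=0.0,
            quality=QualityModel(sigma=0.0, threshold=0.0, bad_cutoff=0.05),
            control_rate=1.0,
        )
        rec = run_slide(slide(q=0.01), poisson_profile, policy, np.random.default_rng(6))
        assert rec.control_sampled
        assert rec.disposition == "rejected"
        assert not rec.missed_bad


policy_strategy = st.builds(
    QCPolicy,
    auto_rescan_rate=st.floats(0.0, 1.0),
    rescan_multiplier=st.floats(1.0, 4.0),
    rescan_includes_load=st.booleans(),
    rescan_time_mode=st.sampled_from(["scaled_original", "fresh_draw_scaled"]),
    quality=st.builds(
        QualityModel,
        sigma=st.floats(0.0, 0.3),
        threshold=st.floats(-0.2, 1.2),
        bad_cutoff=st.floats(0.0, 0.2),
    ),
    visual_accept_prob=st.floats(0.0, 1.0),
    control_rate=st.floats(0.0, 1.0),
    max_rescans=st.integers(0, 3),
)


class TestBatchInvariants:
    @given(policy=policy_strategy, seed=st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_conservation_and_event_bound(self, policy, seed):
        """Every slide terminates accepted or rejected with at most
        1 + max_rescans scan events, under arbitrary policies."""
        rng = np.random.default_rng(seed)
        profile = ScannerProfile()
        batch = simulate_batch(slides(10), profile, policy, rng)
        assert batch.n_accepted + batch.n_rejected == batch.n_slides
        for rec in batch.records:
            assert rec.disposition in ("accepted", "rejected")
            assert 1 <= len(rec.events) <= 1 + policy.max_rescans
            assert batch.total_time_s > 0

    def test_empty_batch_rejected(self, poisson_profile, silent_policy):
        with pytest.raises(ValueError):
            simulate_batch([], poisson_profile, silent_policy, np.random.default_rng(0))

    def test_total_time_is_sum_of_events(self, poisson_profile):
        policy = QCPolicy()
        batch = simulate_batch(slides(50), poisson_profile, policy, np.random.default_rng(9))
        assert batch.total_time_s == pytest.approx(
            sum(r.total_time_s for r in batch.records)
        )


class TestRelativeTime:
    def test_baseline_normalization(self, poisson_profile, silent_policy):
        rel, _ = simulate_relative_times(
            1000, 100, poisson_profile, silent_policy, np.random.default_rng(10)
        )
        se = rel.std(ddof=1) / math.sqrt(len(rel))
        assert abs(rel.mean() - 1.0) <= 3 * se

    def test_every_slide_rescanned_doubles_time(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=1.0,
            rescan_multiplier=1.0,
            rescan_includes_load=True,
            quality=QualityModel(sigma=0.0, threshold=-math.inf),
            control_rate=0.0,
        )
        rel, _ = simulate_relative_times(
            500, 100, poisson_profile, policy, np.random.default_rng(11)
        )
        se = rel.std(ddof=1) / math.sqrt(len(rel))
        assert abs(rel.mean() - 2.0) <= 3 * se

    @pytest.mark.parametrize(
        "r, m, expected",
        [(0.0, 2.0, 1.0), (1.0, 1.0, 2.0), (0.05, 2.0, 1.0929)],
    )
    def test_closed_form_examples(self, r, m, expected):
        assert expected_relative_time(r, m, 60.0, 10.0) == pytest.approx(
            expected, abs=5e-5
        )

    def test_closed_form_matches_per_slide_engine(self, poisson_profile):
        policy = QCPolicy(
            auto_rescan_rate=0.05,
            rescan_multiplier=2.0,
            quality=QualityModel(sigma=0.0, threshold=-math.inf),
            control_rate=0.0,
        )
        rng = np.random.default_rng(12)
        rels = np.array([
            simulate_batch(slides(100), poisson_profile, policy, rng,
                           keep_records=False).relative_time
            for _ in range(300)
        ])
        se = rels.std(ddof=1) / math.sqrt(len(rels))
        assert abs(rels.mean() - expected_relative_time(0.05, 2.0, 60, 10)) <= 3 * se

    def test_engines_agree_under_full_policy(self, poisson_profile):
        """Per-slide and vectorized engines implement the same workflow:
        their mean relative times and missed fractions coincide."""
        policy = QCPolicy(
            auto_rescan_rate=0.05,
            rescan_multiplier=2.0,
            quality=QualityModel(sigma=0.15, threshold=0.1, bad_cutoff=0.05),
            visual_accept_prob=0.5,
            control_rate=0.05,
        )
        rng = np.random.default_rng(13)
        per_slide = [
            simulate_batch(slides(50), poisson_profile, policy, rng, keep_records=False)
            for _ in range(200)
        ]
        rel_a = np.array([b.relative_time for b in per_slide])
        miss_a = np.array([b.missed_fraction_observed for b in per_slide])
        rel_b, miss_b = simulate_relative_times(
            2000, 50, poisson_profile, policy, np.random.default_rng(14)
        )
        for a, b in ((rel_a, rel_b), (miss_a, miss_b)):
            se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) <= 3 * se

    def test_observed_missed_fraction_matches_closed_form(self, poisson_profile):
        q = QualityModel(sigma=0.15, threshold=0.1, bad_cutoff=0.05)
        policy = QCPolicy(
            auto_rescan_rate=0.05,
            quality=q,
            visual_accept_prob=1.0,
            control_rate=0.0,
        )
        rng = np.random.default_rng(15)
        batch = simulate_batch(slides(20000), poisson_profile, policy, rng,
                               keep_records=False)
        p = missed_fraction(q)
        se = math.sqrt(p * (1 - p) / 20000)
        assert abs(batch.missed_fraction_observed - p) <= 3 * se


class TestFleet:
    def test_large_scanner_has_idle_capacity(self, rng):
        report = simulate_fleet(
            slides(400), [ScannerProfile(name="XL", capacity=1000)], rng
        )
        assert report.n_reloads == 0
        assert report.per_scanner[0]["unused_capacity"] == 600

    def test_small_scanner_needs_reloads(self, rng):
        report = simulate_fleet(
            slides(400), [ScannerProfile(name="S", capacity=100)], rng
        )
        assert report.n_reloads == 3  # ceil(400/100) - 1

    def test_parallel_fleet_divides_makespan(self):
        profiles = [ScannerProfile(name=f"s{i}", capacity=1000) for i in range(4)]
        solo = simulate_fleet(slides(400), profiles[:1], np.random.default_rng(20))
        quad = simulate_fleet(slides(400), profiles, np.random.default_rng(20))
        assert quad.makespan_s / solo.makespan_s == pytest.approx(0.25, rel=0.05)

    def test_daily_load_partitions_days(self, rng):
        report = simulate_fleet(
            slides(250), [ScannerProfile(name="S", capacity=1000)], rng, daily_load=100
        )
        assert report.n_days == 3
        assert report.n_reloads == 0

    def test_requires_a_profile(self, rng):
        with pytest.raises(ValueError):
            simulate_fleet(slides(5), [], rng)


def test_policy_validation():
    with pytest.raises(ValueError):
        QCPolicy(auto_rescan_rate=1.5)
    with pytest.raises(ValueError):
        QCPolicy(rescan_multiplier=0.5)
    with pytest.raises(ValueError):
        QCPolicy(max_rescans=-1)
    with pytest.raises(ValueError):
        QCPolicy(rescan_time_mode="other")
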