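"""Time and motion metrics against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surgskill.config import MetricConfig
from surgskill.datatypes import (
    Instrument,
    KinematicTrace,
    SegmentAnnotation,
    ValidationError,
)
from surgskill.kinematics import (
    bimanual_dexterity,
    bounding_volume,
    completion_time,
    compute_segment_metrics,
    economy_of_volume,
    idle_time,
    motion_smoothness,
    path_length,
)
from surgskill.preprocessing import estimate_kinematics
from surgskill.simulate import min_jerk_segment

RATE = 120.0

# closed forms for the 1-D minimum-jerk reach p(τ) = D(10τ³ - 15τ⁴ + 6τ⁵):
# peak speed 1.875·D/T and ∫j² dt = 720·D²/T⁵, so the log dimensionless
# jerk is -ln(720/1.875²), independent of D and T.
MIN_JERK_LDLJ = -math.log(720.0 / 1.875**2)


def _est(positions, rate=RATE):
    n = positions.shape[0]
    tr = KinematicTrace(Instrument.LEFT_TWEEZERS, rate, np.arange(n) / rate, positions)
    return estimate_kinematics(tr)


def _seg(k0, kf, sid="S1"):
    return SegmentAnnotation(sid, k0, kf, k0 / RATE, kf / RATE)


class TestCompletionTime:
    @pytest.mark.parametrize(
        "k0,kf,expected", [(0, 120, 1.0), (300, 372, 0.6), (0, 1, 1 / 120)]
    )
    def test_window_duration(self, k0, kf, expected):
        assert completion_time(_seg(k0, kf), RATE) == pytest.approx(expected)

    def test_empty_window_rejected_upstream(self):
        with pytest.raises(ValidationError):
            _seg(100, 100)


class TestIdleTime:
    def test_fully_idle_segment(self):
        assert idle_time(np.full(120, 0.1), RATE) == pytest.approx(1.0)

    def test_fully_moving_segment(self):
        assert idle_time(np.full(120, 1.0), RATE) == 0.0

    def test_both_scope_is_interval_intersection(self):
        n = 120
        left = np.r_[np.full(n // 2, 0.1), np.full(n // 2, 2.0)]
        right = np.r_[np.full(n // 2, 2.0), np.full(n // 2, 0.1)]
        assert idle_time([left, right], RATE) == 0.0
        # brute-force oracle: per-sample AND
        both = [(l <= 0.5) and (r <= 0.5) for l, r in zip(left, right)]
        assert idle_time([left, right], RATE) == sum(both) / RATE

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            idle_time([np.zeros(10), np.zeros(11)], RATE)

    def test_idle_decomposition(self, rng):
        """idle + above-threshold time = completion time, exactly."""
        speeds = rng.exponential(0.5, size=480)
        idle = idle_time(speeds, RATE)
        above = (speeds > 0.5).sum() / RATE
        assert idle + above == pytest.approx(480 / RATE, abs=1e-12)


class TestPathLength:
    def test_3_4_5_two_point_path(self):
        assert path_length(np.array([[0, 0, 0], [3, 4, 0.0]])) == 5.0

    def test_unit_circle_one_revolution(self):
        th = np.linspace(0, 2 * np.pi, 1001)
        circ = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        assert path_length(circ) == pytest.approx(2 * np.pi, abs=1e-4)

    def test_brute_force_oracle_random_walks(self, rng):
        for _ in range(100):
            pos = np.cumsum(rng.normal(size=(30, 3)), axis=0)
            looped = sum(
                math.dist(pos[k], pos[k + 1]) for k in range(len(pos) - 1)
            )
            assert path_length(pos) == pytest.approx(looped, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_at_least_net_displacement(self, seed):
        pos = np.cumsum(np.random.default_rng(seed).normal(size=(20, 3)), axis=0)
        assert path_length(pos) >= np.linalg.norm(pos[-1] - pos[0]) - 1e-12

    def test_additive_over_partitions(self, rng):
        pos = np.cumsum(rng.normal(size=(200, 3)), axis=0)
        cuts = [0, 37, 101, 150, 200]
        parts = sum(path_length(pos[a : b + 1]) for a, b in zip(cuts, cuts[1:]) )
        assert path_length(pos) == pytest.approx(parts, abs=1e-9)


class TestMotionSmoothness:
    def test_min_jerk_closed_form(self):
        pos = min_jerk_segment(np.array([10.0, 0, 0]), 1.0, RATE)
        est = _est(pos)
        ms = motion_smoothness(est, delta_t=pos.shape[0] / RATE)
        assert ms == pytest.approx(MIN_JERK_LDLJ, rel=0.02)

    def test_spatial_scale_invariance(self):
        pos = min_jerk_segment(np.array([10.0, 0, 0]), 1.0, RATE)
        dt = pos.shape[0] / RATE
        ms1 = motion_smoothness(_est(pos), dt)
        ms10 = motion_smoothness(_est(pos * 10.0), dt)
        assert ms10 == pytest.approx(ms1, abs=1e-9)

    def test_time_rescaling_near_invariant(self):
        """LDLJ is dimensionless: stretching time (and the sampling grid
        with it) leaves it unchanged up to discretization."""
        a = min_jerk_segment(np.array([10.0, 0, 0]), 1.0, RATE)
        b = min_jerk_segment(np.array([10.0, 0, 0]), 2.0, RATE / 2)
        ms_a = motion_smoothness(_est(a, RATE), a.shape[0] / RATE)
        ms_b = motion_smoothness(_est(b, RATE / 2), b.shape[0] / (RATE / 2))
        assert ms_b == pytest.approx(ms_a, abs=1e-3)

    def test_tremor_reduces_smoothness(self):
        clean = min_jerk_segment(np.array([10.0, 0, 0]), 1.0, RATE)
        t = np.arange(clean.shape[0]) / RATE
        noisy = clean.copy()
        noisy[:, 1] += 0.2 * np.sin(2 * np.pi * 10 * t)
        dt = clean.shape[0] / RATE
        assert motion_smoothness(_est(noisy), dt) < motion_smoothness(_est(clean), dt)

    def test_motionless_trajectory_degenerate(self):
        est = _est(np.zeros((120, 3)))
        assert motion_smoothness(est, 1.0) is None


class TestEconomyOfVolume:
    def test_unit_cube_diagonal(self):
        pos = np.array([[0, 0, 0], [1, 1, 1.0]])
        assert bounding_volume(pos) == 1.0
        assert economy_of_volume(pos) == pytest.approx(100 / math.sqrt(3), abs=1e-6)

    def test_axis_aligned_line_zero_policy(self):
        pos = np.array([[0, 0, 0], [5, 0, 0.0]])
        assert economy_of_volume(pos) == 0.0
        cfg = MetricConfig(eov_zero_volume_policy="not_a_value")
        assert economy_of_volume(pos, cfg) is None

    def test_identical_points_degenerate(self):
        assert economy_of_volume(np.zeros((5, 3))) is None

    def test_bounded_on_random_walks(self, rng):
        for _ in range(1000):
            pos = np.cumsum(rng.normal(size=(25, 3)), axis=0)
            eov = economy_of_volume(pos)
            assert 0.0 <= eov <= 100.0


class TestBimanualDexterity:
    def test_proportional_speeds_perfect_correlation(self, rng):
        s = rng.exponential(1.0, 50)
        assert bimanual_dexterity(s, 2 * s) == pytest.approx(1.0)

    def test_reversed_ramp_anticorrelated(self):
        assert bimanual_dexterity([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        # cov-sum 4, centered sums of squares 5 and 5 -> r = 4/5
        assert bimanual_dexterity([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(2, 40))
            r = bimanual_dexterity(a, b)
            assert r == bimanual_dexterity(b, a)
            assert abs(r) <= 1.0 + 1e-12

    def test_zero_variance_degenerate(self):
        assert bimanual_dexterity(np.ones(10), np.arange(10.0)) is None


class TestComputeSegmentMetrics:
    def test_emits_52_values_with_legal_scopes(self, novice_trial):
        values = compute_segment_metrics(novice_trial[0])
        assert len(values) == 52
        per_seg = {}
        for v in values:
            per_seg.setdefault(v.segment_id, []).append((v.metric, v.scope))
        assert all(len(rows) == 13 for rows in per_seg.values())

    def test_motionless_tool_yields_missing_smoothness(self, novice_trial):
        import dataclasses

        trial, _ = novice_trial
        seg4 = trial.segments[3]
        pos = trial.left_kin.positions.copy()
        # freeze the tweezers just before S4 so the derivative filter
        # window sees no motion anywhere inside the segment
        pos[seg4.k0 - 3 :] = pos[seg4.k0 - 3]
        frozen = dataclasses.replace(trial.left_kin, positions=pos)
        trial2 = dataclasses.replace(trial, left_kin=frozen)
        values = compute_segment_metrics(trial2)
        by_key = {(v.metric, v.scope, v.segment_id): v.value for v in values}
        assert math.isnan(by_key[("motion_smoothness", "tweezers", "S4")])
        assert math.isfinite(by_key[("motion_smoothness", "tweezers", "S1")])
        assert math.isfinite(by_key[("motion_smoothness", "needle_holder", "S4")])

    def test_missing_force_yields_missing_press_counts(self, novice_trial):
        import dataclasses

        trial, _ = novice_trial
        trial2 = dataclasses.replace(trial, left_force=None)
        values = compute_segment_metrics(trial2)
        nop = {v.segment_id: v.value for v in values
               if v.metric == "number_of_presses" and v.scope == "left_hand"}
        assert all(math.isnan(x) for x in nop.values())
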