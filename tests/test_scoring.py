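import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from precistep.protocol import target_lab_position
from precistep.scoring import (
    ConditionSummary,
    MissingDataError,
    condition_summary,
    foot_center_at,
    pool_over_ard,
    records_from_true_errors,
    score_trial,
    step_error,
    summarize_subject,
    target_center_at_midstance,
)
from precistep.signals import MarkerTrajectories


def _static_markers(left_pts, right_pts=None, n=5, rate=150.0):
    """Markers frozen at given (toe, malleolus, heel) positions."""
    if right_pts is None:
        right_pts = left_pts
    time = np.arange(n) / rate
    positions = {}
    for foot, pts in (("left", left_pts), ("right", right_pts)):
        positions[foot] = {
            m: np.tile(np.asarray(p, float), (n, 1))
            for m, p in zip(("toe", "malleolus", "heel"), pts)
        }
    return MarkerTrajectories(time=time, positions=positions, rate=rate)


class TestFootCenter:
    def test_centroid_of_marker_triangle(self):
        markers = _static_markers([(0, 0, 0), (0.2, 0, 0), (0.1, 0.05, 0)])
        c = foot_center_at(markers, 0.01, "left")
        assert np.allclose(c, [0.1, 0.0166667, 0.0], atol=1e-6)

    def test_coincident_markers(self):
        p = (0.3, -0.1, 0.05)
        markers = _static_markers([p, p, p])
        assert np.allclose(foot_center_at(markers, 0.02, "right"), p)

    def test_translation_equivariance(self):
        pts = [(0, 0, 0), (0.2, 0, 0), (0.1, 0.05, 0)]
        v = np.array([1.5, -0.3, 0.2])
        moved = [tuple(np.array(p) + v) for p in pts]
        c0 = foot_center_at(_static_markers(pts), 0.01, "left")
        c1 = foot_center_at(_static_markers(moved), 0.01, "left")
        assert np.allclose(c1 - c0, v)

    def test_gap_bridged_within_window(self):
        markers = _static_markers([(0.1, 0, 0), (0.2, 0, 0), (0.0, 0, 0)], n=10)
        markers.positions["left"]["toe"][4:6, :] = np.nan  # 13 ms hole
        c = foot_center_at(markers, 4.5 / 150.0, "left")
        assert np.allclose(c, [0.1, 0.0, 0.0])

    def test_wide_gap_raises(self):
        markers = _static_markers([(0.1, 0, 0), (0.2, 0, 0), (0.0, 0, 0)], n=30)
        markers.positions["left"]["toe"][3:25, :] = np.nan  # ~150 ms hole
        with pytest.raises(MissingDataError):
            foot_center_at(markers, 14.0 / 150.0, "left")


class TestStepError:
    @pytest.mark.parametrize(
        "foot_ap, target_ap, expected",
        [(0.105, 0.100, +0.005), (0.1, 0.1, 0.0), (0.090, 0.100, -0.010)],
    )
    def test_sign_convention(self, foot_ap, target_ap, expected):
        """Positive = overshoot (foot anterior to the target center)."""
        e = step_error((foot_ap, 0.0, 0.0), (target_ap, 0.0))
        assert e == pytest.approx(expected)


class TestConditionSummary:
    def test_constant_errors(self):
        s = condition_summary([0.02] * 8, 0.5)
        assert s.variability == pytest.approx(0.0, abs=1e-12)
        assert s.mean_error == pytest.approx(100 * 0.02 / 0.5)

    def test_worked_example(self):
        # errors 10, 20, 30 mm with L = 0.5 m: population SD = sqrt(200/3) mm
        s = condition_summary([0.010, 0.020, 0.030], 0.5)
        assert s.variability == pytest.approx(
            100 * math.sqrt(200 / 3) / 500, abs=1e-9
        )
        assert s.variability == pytest.approx(1.63299, abs=1e-5)

    def test_singleton_has_zero_variability(self):
        assert condition_summary([0.015], 0.5).variability == 0.0

    def test_empty_and_bad_length_raise(self):
        with pytest.raises(ValueError):
            condition_summary([], 0.5)
        with pytest.raises(ValueError):
            condition_summary([0.01], 0.0)

    def test_matches_population_sd_oracle(self):
        """Divide-by-k formula == brute-force population SD on random data."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(1, 40)
            e = rng.normal(0, 0.05, k)
            L = rng.uniform(0.3, 0.8)
            s = condition_summary(e, L)
            oracle = math.sqrt(np.mean((e - e.mean()) ** 2))
            assert s.variability == pytest.approx(100 * oracle / L, abs=1e-12)

    @given(
        st.lists(st.floats(-0.2, 0.2), min_size=2, max_size=30),
        st.floats(0.001, 0.05),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, errors, offset):
        """Adding a constant moves the mean exactly and leaves variability
        unchanged."""
        base = condition_summary(errors, 0.5)
        shifted = condition_summary([e + offset for e in errors], 0.5)
        # equality up to float cancellation in the sum-of-squares form
        assert shifted.variability == pytest.approx(base.variability, abs=1e-6)
        assert shifted.mean_error - base.mean_error == pytest.approx(
            100 * offset / 0.5, abs=1e-9
        )


class TestPoolOverArd:
    def _cs(self, m, v, k=8):
        return ConditionSummary(mean_error=m, variability=v, k=k)

    def test_equal_values_pool_to_themselves(self):
        per = {a: self._cs(2.0, 3.0) for a in (0.8, 1.0, 1.3, 2.0)}
        pooled = pool_over_ard(per)
        assert pooled.mean_error == 2.0 and pooled.variability == 3.0

    def test_arithmetic_mean(self):
        per = {
            a: self._cs(m, v)
            for a, m, v in zip((0.8, 1.0, 1.3, 2.0), (1, 2, 3, 4), (4, 3, 2, 1))
        }
        pooled = pool_over_ard(per)
        assert pooled.mean_error == pytest.approx(2.5)
        assert pooled.variability == pytest.approx(2.5)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ms, vs = rng.normal(size=(2, 4))
            per = {
                a: self._cs(m, abs(v))
                for a, m, v in zip((0.8, 1.0, 1.3, 2.0), ms, vs)
            }
            pooled = pool_over_ard(per)
            assert pooled.mean_error == pytest.approx(np.mean(ms))

    def test_missing_ard_named(self):
        per = {a: self._cs(1, 1) for a in (0.8, 1.0, 1.3)}
        with pytest.raises(KeyError, match="2.0"):
            pool_over_ard(per)


class TestTargetCenterAtMidstance:
    def test_unshifted_delegates_to_lab_position(self, params, unperturbed_block):
        tg = unperturbed_block.targets[3]
        got = target_center_at_midstance(tg, 12.0, 10.0, params)
        assert got == target_lab_position(tg, 12.0, 10.0, params)

    def test_displaced_center_after_onset(self, params, perturbed_block):
        tg = perturbed_block.shifted[0]
        nominal = target_center_at_midstance(tg, 12.0, 10.0, params, None)
        before = target_center_at_midstance(tg, 12.0, 10.0, params, 12.5)
        after = target_center_at_midstance(tg, 12.0, 10.0, params, 11.0)
        assert before == nominal
        delta = tg.shift.displaced_ap_center - tg.nominal_ap_center
        assert after[0] - nominal[0] == pytest.approx(delta)

    def test_not_yet_visible_raises(self, params, unperturbed_block):
        with pytest.raises(Exception, match="before"):
            target_center_at_midstance(unperturbed_block.targets[0], 9.0, 10.0, params)

    def test_consistent_with_simulator_truth(
        self, clean_perturbed_trial, perturbed_block, params
    ):
        """Recomputed target center == simulator's landing center minus the
        injected error, at the true midstance, to numerical precision."""
        truth = clean_perturbed_trial.truth
        v = params.belt_speed
        for i, tg in enumerate(perturbed_block.targets):
            t_mid = truth.target_midstance_times[i]
            ap, _ = target_center_at_midstance(
                tg, t_mid, truth.appearance_times[i], params,
                float(truth.shift_onset_times[i]),
            )
            expected = (
                truth.target_landing_ap[i]
                - truth.true_errors[i]
                - v * (t_mid - truth.target_strike_times[i])
            )
            assert ap == pytest.approx(expected, abs=1e-9)


class TestEndToEnd:
    def test_noiseless_scores_match_truth_sub_half_mm(
        self, clean_perturbed_trial, perturbed_block, params
    ):
        trial = clean_perturbed_trial
        records = score_trial(
            trial.markers, trial.cop, perturbed_block,
            trial.truth.appearance_times, trial.truth.shift_onset_times, params,
        )
        assert len(records) == len(perturbed_block.targets)
        got = np.array([r.raw_error for r in records])
        want = trial.truth.true_errors[[r.target_index for r in records]]
        assert np.max(np.abs(got - want)) < 0.0005

    def test_backward_steps_scored_but_excluded_from_summaries(
        self, clean_perturbed_trial, perturbed_block, params, clean_trial,
        unperturbed_block,
    ):
        precs = score_trial(
            clean_perturbed_trial.markers, clean_perturbed_trial.cop,
            perturbed_block, clean_perturbed_trial.truth.appearance_times,
            clean_perturbed_trial.truth.shift_onset_times, params,
        )
        assert sum(r.condition == "backward" for r in precs) == 8
        urecs = score_trial(
            clean_trial.markers, clean_trial.cop, unperturbed_block,
            clean_trial.truth.appearance_times,
            clean_trial.truth.shift_onset_times, params,
        )
        summary = summarize_subject("S1", urecs, precs, 0.5)
        # 8 forward shifts per ARD in one block; backward not counted anywhere
        assert all(cs.k == 8 for cs in summary.per_ard.values())
        assert summary.pooled.k == 32

    def test_records_from_true_errors_normalization(self, perturbed_block):
        errors = np.full(len(perturbed_block.targets), 0.01)
        recs = records_from_true_errors(perturbed_block, errors, 0.5)
        assert all(r.normalized_error == pytest.approx(2.0) for r in recs)
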