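import dataclasses

import numpy as np
import pytest

from precistep.protocol import BACKWARD, ProtocolParams, generate_perturbed_block
from precistep.synthetic import (
    PopulationModel,
    SubjectParams,
    make_cohort,
    respond_to_shift,
    simulate_step_errors,
    simulate_trial,
)


class TestMakeCohort:
    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_cohort(1)

    def test_same_seed_identical(self):
        assert make_cohort(10, seed=3) == make_cohort(10, seed=3)

    def test_noise_free_age_sigma_correlation_is_minus_one(self):
        model = PopulationModel(sigma_between_sd=0.0)
        cohort = make_cohort(30, model=model, seed=0)
        ages = [s.age for s in cohort]
        sigmas = [s.sigma for s in cohort]
        r = np.corrcoef(ages, sigmas)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_flat_age_slope_gives_null_correlation(self):
        model = PopulationModel(age_slope=0.0)
        rs = []
        for seed in range(200):
            cohort = make_cohort(30, model=model, seed=seed)
            rs.append(
                np.corrcoef([s.age for s in cohort], [s.sigma for s in cohort])[0, 1]
            )
        assert abs(np.mean(rs)) < 0.05

    def test_ages_within_range(self):
        cohort = make_cohort(50, age_range=(9.0, 18.5), seed=1)
        assert all(9.0 <= s.age <= 18.5 for s in cohort)
        assert all(s.sigma > 0 for s in cohort)


class TestRespondToShift:
    def test_no_inflation_at_longest_ard(self, clean_subject):
        dist = respond_to_shift(clean_subject, 2.0)
        assert dist.sd == pytest.approx(clean_subject.sigma * clean_subject.step_length)
        assert dist.mean == pytest.approx(
            clean_subject.error_bias * clean_subject.step_length
        )

    def test_variability_ordering_matches_kappa(self, clean_subject):
        """Monte-Carlo landing spreads must be ordered like kappa."""
        rng = np.random.default_rng(0)
        sds = []
        for ard in (0.8, 1.0, 1.3, 2.0):
            d = respond_to_shift(clean_subject, ard)
            sds.append(rng.normal(d.mean, d.sd, 10_000).std())
        assert sds[0] > sds[1] > sds[2] > sds[3]

    def test_invalid_ard(self, clean_subject):
        with pytest.raises(ValueError):
            respond_to_shift(clean_subject, 0.0)


class TestSimulateTrial:
    def test_degenerate_noise_gives_zero_errors(self, params, unperturbed_block):
        subject = SubjectParams(
            "S0", 14, "F", 0.5, error_bias=0.0, sigma=0.0,
            marker_noise_sd=0.0, cop_noise_sd=0.0,
        )
        trial = simulate_trial(subject, unperturbed_block, params, seed=1)
        assert np.allclose(trial.truth.true_errors, 0.0, atol=1e-12)

    def test_bias_recovered_in_mean_error(self, params, perturbed_block):
        subject = SubjectParams(
            "S0", 14, "F", 0.5, error_bias=0.02, sigma=0.05,
            marker_noise_sd=0.0, cop_noise_sd=0.0,
        )
        errs = []
        for seed in range(5):
            trial = simulate_trial(subject, perturbed_block, params, seed=seed)
            errs.append(trial.truth.true_errors)
        mean_frac = np.concatenate(errs).mean() / subject.step_length
        assert mean_frac == pytest.approx(0.02, abs=0.005)

    def test_one_landing_per_target_plus_lead_in(self, clean_trial, unperturbed_block):
        n_strikes = sum(len(v) for v in clean_trial.truth.strike_times.values())
        assert n_strikes >= len(unperturbed_block.targets)
        assert clean_trial.truth.true_errors.size == len(unperturbed_block.targets)

    def test_events_strictly_alternate(self, clean_trial):
        truth = clean_trial.truth
        for foot in ("left", "right"):
            s, o = truth.strike_times[foot], truth.toe_off_times[foot]
            assert np.all(o > s)  # strike < toe-off within each stance
            assert np.all(s[1:] > o[:-1] - 1e-12)

    def test_protocol_mismatch_raises(self, clean_subject, unperturbed_block):
        wrong = ProtocolParams(preferred_step_length=0.6)
        with pytest.raises(ValueError, match="does not match"):
            simulate_trial(clean_subject, unperturbed_block, wrong, seed=0)

    def test_marker_geometry_rigid_during_stance(self, clean_trial):
        """Inter-marker distances are constant (rigid foot) without noise."""
        m = clean_trial.markers.positions["left"]
        d = np.linalg.norm(m["toe"] - m["heel"], axis=1)
        assert np.ptp(d) < 1e-9

    def test_stance_foot_rides_belt_with_target(
        self, clean_trial, unperturbed_block, params
    ):
        """During stance the foot-to-target AP distance is constant: both are
        belt-fixed, so the signed error is well defined at any stance time."""
        truth = clean_trial.truth
        v = params.belt_speed
        markers = clean_trial.markers
        for i in range(0, len(unperturbed_block.targets), 7):
            t_strike = truth.target_strike_times[i]
            foot = truth.target_feet[i]
            sel = (markers.time >= t_strike) & (markers.time <= t_strike + 0.5)
            center_ap = np.mean(
                [markers.positions[foot][m][sel, 0] for m in ("toe", "malleolus", "heel")],
                axis=0,
            )
            target_ap = (
                params.appearance_distance
                - v * (markers.time[sel] - truth.appearance_times[i])
            )
            assert np.ptp(center_ap - target_ap) < 1e-9

    def test_backward_shift_lands_posterior(self, params):
        """With zero landing noise, landings on backward-shifted targets sit
        exactly 40% L behind the unshifted landing position."""
        subject = SubjectParams(
            "S0", 14, "F", 0.5, error_bias=0.0, sigma=0.0,
            marker_noise_sd=0.0, cop_noise_sd=0.0,
        )
        block = generate_perturbed_block(params, rng=11)
        trial = simulate_trial(subject, block, params, seed=0)
        landing = trial.truth.target_landing_ap
        base = np.median(landing)
        for i, tg in enumerate(block.targets):
            if tg.shift is not None and tg.shift.direction == BACKWARD:
                assert landing[i] - base == pytest.approx(-0.4 * 0.5, abs=1e-9)

    def test_shift_onsets_realized_before_midstance(self, clean_perturbed_trial):
        truth = clean_perturbed_trial.truth
        shifted = ~np.isnan(truth.shift_onset_times)
        assert shifted.sum() == 40
        assert np.all(
            truth.shift_onset_times[shifted] < truth.target_midstance_times[shifted]
        )

    def test_shift_onset_distance_matches_ard(
        self, clean_perturbed_trial, perturbed_block, params
    ):
        """At the realized onset the nominal target sits at most ard*L from
        the COP, and one sample earlier it was farther (first-hit rule)."""
        truth = clean_perturbed_trial.truth
        cop = clean_perturbed_trial.cop
        L = params.preferred_step_length
        v = params.belt_speed
        for i, tg in enumerate(perturbed_block.targets):
            if tg.shift is None:
                continue
            onset = truth.shift_onset_times[i]
            j = np.searchsorted(cop.time, onset)
            nominal = params.appearance_distance - v * (
                cop.time[j] - truth.appearance_times[i]
            )
            assert nominal - cop.ap[j] <= tg.shift.ard * L + 1e-9

    def test_same_seed_identical_signals(
        self, noisy_subject, unperturbed_block, params
    ):
        t1 = simulate_trial(noisy_subject, unperturbed_block, params, seed=9)
        t2 = simulate_trial(noisy_subject, unperturbed_block, params, seed=9)
        assert np.array_equal(t1.cop.ap, t2.cop.ap)
        assert np.array_equal(
            t1.markers.positions["left"]["toe"], t2.markers.positions["left"]["toe"]
        )


class TestSimulateStepErrors:
    def test_distribution_matches_full_simulator_model(
        self, clean_subject, perturbed_block, params
    ):
        """The error-level path draws from the same landing model: per-ARD
        spreads scale with kappa."""
        rng = np.random.default_rng(0)
        errs = np.concatenate(
            [
                simulate_step_errors(clean_subject, perturbed_block, params, rng)
                for _ in range(100)
            ]
        )
        mask = np.tile(
            [t.shift is not None and t.shift.ard == 0.8 for t in perturbed_block.targets],
            100,
        )
        unpert = np.tile([t.shift is None for t in perturbed_block.targets], 100)
        ratio = errs[mask].std() / errs[unpert].std()
        assert ratio == pytest.approx(clean_subject.kappa_at(0.8), rel=0.05)


def test_kappa_interpolation_non_increasing(clean_subject):
    ards = np.linspace(0.5, 2.5, 50)
    vals = [clean_subject.kappa_at(a) for a in ards]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    assert min(vals) >= 1.0
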