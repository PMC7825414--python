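import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from backload.anthropometry import G, HEEL_X_FRAC, HIP_HALF_WIDTH_FRAC
from backload.battery import ShelfSpec
from backload.simulate import (
    NoiseConfig,
    degrade_to_real,
    quiet_standing_trial,
    simulate_trial,
    static_hold_trial,
)


def total_vertical_grf(trial):
    return trial.grf["r"][:, 1] + trial.grf["l"][:, 1]


def trunk_flexion(trial):
    q = trial.segments["trunk"].quat
    # forward flexion is a negative rotation about global Z
    return -Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_euler("ZXY")[:, 0]


def test_quiet_standing_supports_exactly_body_weight(anthro):
    trial = quiet_standing_trial(anthro, duration=1.0)
    assert np.allclose(total_vertical_grf(trial), anthro.body_mass * G, atol=1e-6)
    assert np.allclose(trial.ground_truth.extension, 0.0, atol=2.0)  # near-upright


def test_static_hold_supports_body_plus_box(anthro):
    trial = static_hold_trial(anthro, 10.0, duration=1.0)
    assert np.allclose(total_vertical_grf(trial), (anthro.body_mass + 10.0) * G, atol=1e-6)


def test_stoop_flexes_the_trunk_more_than_squat(cohort3, mini_tasks):
    by_style = {}
    for task in mini_tasks:
        if task.origin_shelf.name == "low" and task.style in ("squat", "stoop"):
            trial = simulate_trial(cohort3[0], task, seed=1)
            by_style[task.style] = trunk_flexion(trial).max()
    assert by_style["stoop"] > by_style["squat"]


def test_quaternions_stay_unit_norm(mini_trials):
    for trial in mini_trials[:4]:
        for seg in trial.segments.values():
            norms = np.linalg.norm(seg.quat, axis=-1)
            assert np.allclose(norms, 1.0, atol=1e-9)


def test_simulation_is_bit_deterministic(anthro, mini_tasks):
    a = simulate_trial(anthro, mini_tasks[0], seed=77)
    b = simulate_trial(anthro, mini_tasks[0], seed=77)
    assert np.array_equal(a.grf["r"], b.grf["r"])
    assert np.array_equal(a.segments["trunk"].quat, b.segments["trunk"].quat)
    assert np.array_equal(a.ground_truth.extension, b.ground_truth.extension)
    c = simulate_trial(anthro, mini_tasks[0], seed=78)
    assert not np.array_equal(a.grf["r"], c.grf["r"])


def test_object_mass_timeline_matches_pick_and_place(anthro, mini_tasks):
    task = mini_tasks[0]
    trial = simulate_trial(anthro, task, seed=3)
    t = trial.time
    held = (t > task.pick_time + 0.06) & (t < task.place_time - 0.06)
    free = (t < task.pick_time - 0.06) | (t > task.place_time + 0.06)
    assert np.allclose(trial.object_mass[held], task.box_mass)
    assert np.allclose(trial.object_mass[free], 0.0)
    assert trial.object_mass.min() >= 0.0
    assert trial.object_mass.max() <= task.box_mass + 1e-12


def test_peak_moment_is_monotone_in_box_mass(anthro, mini_tasks):
    """With kinematics held fixed, a heavier box can only raise the peak moment."""
    from dataclasses import replace

    base = mini_tasks[0]
    peaks = []
    for mass in (0.0, 10.0, 23.0):
        task = replace(base, box_mass=mass)
        trial = simulate_trial(anthro, task, seed=9, balance_load=10.0)
        peaks.append(trial.ground_truth.extension.max())
    assert peaks[0] < peaks[1] < peaks[2]


def test_cop_stays_inside_the_support_polygon(mini_trials):
    for trial in mini_trials:
        assert trial.meta["cop_clipped_samples"] == 0
        H = trial.anthro.body_height
        heel = HEEL_X_FRAC * H
        toe = heel + trial.anthro.segment_length("foot_r")
        for s, sign in (("r", 1.0), ("l", -1.0)):
            cop = trial.cop[s]
            assert cop[:, 0].min() >= heel - 1e-9
            assert cop[:, 0].max() <= toe + 1e-9
            z0 = sign * HIP_HALF_WIDTH_FRAC * H
            assert np.all(np.abs(cop[:, 2] - z0) <= 0.035 * H + 1e-9)


def test_low_rate_and_unreachable_shelf_raise(anthro, mini_tasks):
    with pytest.raises(ValueError, match="rate"):
        simulate_trial(anthro, mini_tasks[0], rate=10.0)
    from dataclasses import replace

    bad = replace(mini_tasks[0], origin_shelf=ShelfSpec("high", 3.0))
    with pytest.raises(ValueError, match="unreachable"):
        simulate_trial(anthro, bad, seed=0)


class TestDegradeToReal:
    def test_zero_noise_is_the_identity(self, mini_trials):
        trial = mini_trials[0]
        out = degrade_to_real(trial, NoiseConfig.zero(), seed=5)
        assert np.array_equal(out.grf["r"], trial.grf["r"])
        assert np.array_equal(out.segments["trunk"].quat, trial.segments["trunk"].quat)
        assert np.array_equal(out.cop["l"], trial.cop["l"])

    def test_selective_perturbation(self, mini_trials):
        trial = mini_trials[0]
        noise = NoiseConfig(insole_gain_sd=0.1, insole_additive_sd=5.0,
                            cop_sd=0.0, imu_angle_bias_sd=0.0, imu_angle_white_sd=0.0)
        out = degrade_to_real(trial, noise, seed=5)
        for seg in trial.segments:
            assert np.array_equal(out.segments[seg].quat, trial.segments[seg].quat)
        assert not np.array_equal(out.grf["r"], trial.grf["r"])
        assert np.array_equal(out.ground_truth.extension, trial.ground_truth.extension)

    def test_gain_noise_has_the_configured_spread(self, mini_trials):
        trial = mini_trials[0]
        noise = NoiseConfig(insole_gain_sd=0.1, insole_additive_sd=0.0, cop_sd=0.0,
                            imu_angle_bias_sd=0.0, imu_angle_white_sd=0.0)
        truth = trial.grf["r"][:, 1].mean()
        ratios = [
            degrade_to_real(trial, noise, seed=s).grf["r"][:, 1].mean() / truth
            for s in range(400)
        ]
        assert abs(np.std(ratios) - 0.1) < 0.015
        assert abs(np.mean(ratios) - 1.0) < 0.02

    def test_imu_noise_magnitude_and_ground_truth_untouched(self, mini_trials):
        trial = mini_trials[0]
        noise = NoiseConfig(insole_gain_sd=0.0, insole_additive_sd=0.0, cop_sd=0.0,
                            imu_angle_bias_sd=1.0, imu_angle_white_sd=0.0)
        out = degrade_to_real(trial, noise, seed=8)
        q0 = trial.segments["trunk"].quat
        q1 = out.segments["trunk"].quat
        # rotation distance between clean and degraded orientations
        dots = np.abs(np.sum(q0 * q1, axis=-1)).clip(None, 1.0)
        angles = np.degrees(2 * np.arccos(dots))
        assert 0 < angles.mean() < 5.0
        assert np.array_equal(out.ground_truth.extension, trial.ground_truth.extension)

    def test_negative_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            NoiseConfig(insole_saturation=-1.0)

    def test_degrading_twice_is_rejected(self, mini_trials):
        out = degrade_to_real(mini_trials[0], NoiseConfig(), seed=1)
        with pytest.raises(ValueError, match="noise-free"):
            degrade_to_real(out, NoiseConfig(), seed=2)
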