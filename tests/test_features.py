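from collections import Counter

import numpy as np
import pytest

from backload.features import (
    CANONICAL_LOCATIONS,
    FeatureMatrix,
    apply_normalizer,
    build_idealized_features,
    build_real_features,
    fit_normalizer,
    subset_features,
)
from backload.simulate import NoiseConfig, degrade_to_real, quiet_standing_trial, simulate_trial


@pytest.fixture(scope="module")
def ideal_fm(mini_trials):
    return build_idealized_features(mini_trials[0])


@pytest.fixture(scope="module")
def real_fm(mini_trials):
    degraded = degrade_to_real(mini_trials[0], NoiseConfig(), seed=3)
    return build_real_features(degraded)


class TestChannelInventories:
    def test_idealized_counts(self, ideal_fm):
        kinds = Counter(c.kind for c in ideal_fm.channels)
        assert len(ideal_fm.channels) == 51
        assert kinds["euler_angle"] == 24
        assert kinds["joint_angle"] == 21
        assert kinds["normal_force"] == 2
        assert kinds["cop_x"] + kinds["cop_y"] == 4

    def test_real_counts(self, real_fm):
        kinds = Counter(c.kind for c in real_fm.channels)
        assert len(real_fm.channels) == 179
        assert kinds["euler_angle"] == 33
        assert kinds["quaternion"] == 44
        assert kinds["angular_velocity"] == 33
        assert kinds["linear_acceleration"] == 33
        assert kinds["joint_angle"] == 30
        assert kinds["normal_force"] == 2
        assert kinds["cop_x"] + kinds["cop_y"] == 4

    def test_channel_order_is_deterministic(self, mini_trials):
        a = build_idealized_features(mini_trials[0]).channel_names
        b = build_idealized_features(mini_trials[1]).channel_names
        assert a == b

    def test_real_quaternion_channels_are_unit_norm(self, real_fm):
        for seg in ("pelvis", "l5", "l3", "t12", "t8"):
            cols = [i for i, c in enumerate(real_fm.channels)
                    if c.name.startswith(f"quat_{seg}_")]
            norms = np.linalg.norm(real_fm.values[:, cols], axis=1)
            assert np.allclose(norms, 1.0, atol=1e-6)

    def test_zero_noise_real_channels_match_idealized(self, mini_trials):
        trial = mini_trials[0]
        clean = degrade_to_real(trial, NoiseConfig.zero(), seed=0)
        ideal = build_idealized_features(trial)
        real = build_real_features(clean)
        shared = [n for n in ideal.channel_names
                  if n in real.channel_names and not n.startswith("joint_")]
        assert shared  # pelvis/thigh/shank/foot eulers and insole channels
        for name in shared:
            a = ideal.values[:, ideal.channel_names.index(name)]
            b = real.values[:, real.channel_names.index(name)]
            assert np.allclose(a, b, atol=1e-9), name


class TestSubsetting:
    def test_trunk_only_is_three_euler_channels(self, ideal_fm):
        sub = subset_features(ideal_fm, ("trunk",))
        assert sub.channel_names == ["euler_trunk_z", "euler_trunk_x", "euler_trunk_y"]

    def test_insole_only_is_six_channels(self, ideal_fm):
        sub = subset_features(ideal_fm, ("insole",))
        assert len(sub.channels) == 6
        assert all(c.location == "insole" for c in sub.channels)

    def test_full_set_is_the_identity(self, ideal_fm):
        sub = subset_features(ideal_fm, CANONICAL_LOCATIONS)
        assert sub.channel_names == ideal_fm.channel_names

    def test_joint_channels_need_both_adjacent_sensors(self, ideal_fm):
        both = subset_features(ideal_fm, ("pelvis", "trunk"))
        assert any(c.name.startswith("joint_lumbar") for c in both.channels)
        alone = subset_features(ideal_fm, ("pelvis",))
        assert not any(c.name.startswith("joint_") for c in alone.channels)

    def test_union_property(self, ideal_fm):
        a, b = ("trunk",), ("insole",)
        union = set(subset_features(ideal_fm, a + b).channel_names)
        parts = set(subset_features(ideal_fm, a).channel_names) | set(
            subset_features(ideal_fm, b).channel_names)
        assert union == parts

    def test_invalid_subsets_rejected(self, ideal_fm):
        with pytest.raises(ValueError, match="empty"):
            subset_features(ideal_fm, ())
        with pytest.raises(ValueError, match="unknown"):
            subset_features(ideal_fm, ("head",))


class TestPosturalChannels:
    def test_quiet_standing_has_constant_joint_angles(self, anthro):
        trial = quiet_standing_trial(anthro, duration=1.0)
        fm = build_idealized_features(trial)
        for i, c in enumerate(fm.channels):
            if c.kind == "joint_angle":
                assert np.ptp(fm.values[:, i]) < 1e-9

    def test_trunk_sagittal_channel_tracks_flexion_monotonically(self, anthro, mini_tasks):
        stoop = next(t for t in mini_tasks if t.style == "stoop")
        trial = simulate_trial(anthro, stoop, seed=2, posture_jitter_deg=0.0,
                               arm_jitter_frac=0.0, grip_jitter_frac=0.0)
        fm = build_idealized_features(trial)
        col = fm.channel_names.index("euler_trunk_z")
        reach = fm.values[trial.time < stoop.pick_time - 0.3, col]
        # forward flexion is a negative Z rotation: the channel falls monotonically
        assert np.all(np.diff(reach) <= 1e-12)
        assert reach[-1] < reach[0] - 0.3


class TestNormalizer:
    def test_training_data_becomes_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(500, 4))
        norm = fit_normalizer(X)
        Z = apply_normalizer(norm, X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channels_flagged_and_passed_through(self):
        X = np.column_stack([np.full(100, 7.0), np.random.default_rng(1).normal(size=100)])
        norm = fit_normalizer(X)
        assert norm.constant_mask.tolist() == [True, False]
        Z = apply_normalizer(norm, X)
        assert np.allclose(Z[:, 0], 7.0)

    def test_no_leakage_into_a_shifted_test_fold(self):
        rng = np.random.default_rng(2)
        train = rng.normal(0.0, 1.0, size=(1000, 2))
        test = rng.normal(5.0, 1.0, size=(200, 2))
        norm = fit_normalizer(train)
        Z = apply_normalizer(norm, test)
        assert Z.mean() > 3.0  # shift preserved: statistics came from train only

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2"):
            fit_normalizer(np.zeros((1, 3)))


def test_feature_matrix_rejects_nonfinite_values(ideal_fm):
    bad = ideal_fm.values.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        FeatureMatrix(bad, ideal_fm.channels, ideal_fm.index, "idealized")
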