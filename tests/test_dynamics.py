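import numpy as np
import pytest

from backload.anthropometry import G, Anthropometry
from backload.dynamics import (
    bottom_up_lumbar,
    denormalize_bwbh,
    normalize_bwbh,
    top_down_lumbar,
    whole_body_grf,
)
from conftest import make_static_trial, rotate_trial_about_y


def rel_rms(a, b, floor=1e-12):
    return np.sqrt(np.mean((a - b) ** 2)) / max(np.sqrt(np.mean(b**2)), floor)


class TestStaticClosedForms:
    def test_aligned_posture_has_zero_moments(self):
        trial = make_static_trial(trunk_com_offset=(0.0, 0.2, 0.0), object_mass=0.0)
        assert np.allclose(trial.ground_truth.extension, 0.0, atol=1e-9)
        assert np.allclose(trial.ground_truth.lateral_bending, 0.0, atol=1e-9)

    def test_anterior_offsets_give_the_textbook_extension_moment(self):
        # 40 kg upper body 0.1 m anterior + 10 kg object 0.4 m anterior
        trial = make_static_trial(trunk_com_offset=(0.1, 0.2, 0.0),
                                  object_mass=10.0, object_offset=(0.4, -0.1, 0.0))
        expected = 40.0 * G * 0.1 + 10.0 * G * 0.4  # 78.48 Nm
        assert expected == pytest.approx(78.48)
        assert np.allclose(trial.ground_truth.extension, expected, atol=1e-9)
        assert np.allclose(trial.ground_truth.lateral_bending, 0.0, atol=1e-9)

    def test_lateral_offset_gives_the_textbook_bending_magnitude(self):
        trial = make_static_trial(trunk_com_offset=(0.0, 0.2, 0.0),
                                  object_mass=10.0, object_offset=(0.0, -0.1, 0.3))
        expected = 10.0 * G * 0.3  # 29.43 Nm; sign follows the +Z-right convention
        assert np.allclose(np.abs(trial.ground_truth.lateral_bending), expected, atol=1e-9)
        assert np.allclose(trial.ground_truth.extension, 0.0, atol=1e-9)

    def test_object_superposition(self):
        bare = make_static_trial(trunk_com_offset=(0.1, 0.2, 0.0), object_mass=0.0)
        loaded = make_static_trial(trunk_com_offset=(0.1, 0.2, 0.0),
                                   object_mass=23.0, object_offset=(0.35, -0.1, 0.0))
        delta = loaded.ground_truth.extension - bare.ground_truth.extension
        assert np.allclose(delta, 23.0 * G * 0.35, atol=1e-6)


class TestWholeBodyGrf:
    def test_quiet_standing_splits_weight_evenly(self):
        trial = make_static_trial(trunk_com_offset=(0.0, 0.2, 0.0), object_mass=10.0)
        expected = (80.0 + 10.0) * G / 2
        assert np.allclose(trial.grf["r"][:, 1], expected, atol=1e-9)
        assert np.allclose(trial.grf["l"][:, 1], expected, atol=1e-9)

    def test_upward_acceleration_raises_total_force(self):
        trial = make_static_trial(trunk_com_offset=(0.0, 0.2, 0.0))
        for seg in trial.segments.values():
            seg.com_acc[:, 1] = 1.5
        grf, _, _ = whole_body_grf(trial)
        total = grf["r"][:, 1] + grf["l"][:, 1]
        assert np.allclose(total, 80.0 * (G + 1.5), atol=1e-9)

    def test_airborne_configuration_raises(self):
        trial = make_static_trial(trunk_com_offset=(0.0, 0.2, 0.0))
        for seg in trial.segments.values():
            seg.com_acc[:, 1] = -2 * G
        with pytest.raises(ValueError, match="airborne"):
            whole_body_grf(trial)


class TestClosure:
    def test_bottom_up_equals_top_down_on_simulated_trials(self, mini_trials):
        for trial in mini_trials:
            bu = bottom_up_lumbar(trial)
            td = top_down_lumbar(trial)
            scale = np.sqrt(np.mean(td.extension**2 + td.lateral_bending**2))
            assert np.sqrt(np.mean((bu.extension - td.extension) ** 2)) <= 1e-9 * scale
            assert np.sqrt(np.mean((bu.lateral_bending - td.lateral_bending) ** 2)) <= 1e-9 * scale

    def test_grf_conservation_at_every_sample(self, mini_trials):
        from backload.dynamics import G_VEC

        for trial in mini_trials:
            need = trial.object_mass[:, None] * (trial.object_acc - G_VEC)
            for name, seg in trial.segments.items():
                need += trial.anthro.segment_mass(name) * (seg.com_acc - G_VEC)
            total = trial.grf["r"] + trial.grf["l"]
            assert np.abs(total - need).max() < 1e-6

    def test_extension_profile_is_frame_independent(self, mini_trials):
        trial = mini_trials[0]
        rotated = rotate_trial_about_y(trial, np.pi / 5)
        bu0 = trial.ground_truth
        bu1 = bottom_up_lumbar(rotated)
        mag0 = np.hypot(bu0.extension, bu0.lateral_bending)
        mag1 = np.hypot(bu1.extension, bu1.lateral_bending)
        assert np.allclose(mag0, mag1, atol=1e-9 * max(1.0, mag0.max()))


class TestNormalization:
    def test_worked_example(self):
        from backload.dynamics import MomentSeries

        a = Anthropometry("X", 79.0, 1.8)
        s = MomentSeries(100.0, np.array([77.5]), np.array([0.0]))
        out = normalize_bwbh(s, a)
        assert out.units == "BWBH"
        assert out.extension[0] == pytest.approx(77.5 / (79.0 * G * 1.8))
        assert round(out.extension[0], 4) == 0.0556
        assert out.lateral_bending[0] == 0.0

    def test_round_trip_is_the_identity(self, mini_trials):
        trial = mini_trials[0]
        back = denormalize_bwbh(normalize_bwbh(trial.ground_truth, trial.anthro),
                                trial.anthro)
        assert np.allclose(back.extension, trial.ground_truth.extension, atol=1e-12)
        assert back.units == "Nm"

    def test_double_normalization_rejected(self, mini_trials):
        trial = mini_trials[0]
        once = normalize_bwbh(trial.ground_truth, trial.anthro)
        with pytest.raises(ValueError):
            normalize_bwbh(once, trial.anthro)


def test_missing_forces_and_nonfinite_inputs_raise(mini_trials):
    trial = mini_trials[0].copy()
    trial.grf = None
    with pytest.raises(ValueError, match="forces"):
        bottom_up_lumbar(trial)
    trial2 = mini_trials[0].copy()
    trial2.grf["r"][0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        bottom_up_lumbar(trial2)
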