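import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from backload.anthropometry import Anthropometry, SegmentParams, sample_cohort
from backload.battery import BatteryConfig, build_task_battery
from backload.dynamics import MomentSeries, bottom_up_lumbar, whole_body_grf
from backload.features import assemble_dataset
from backload.simulate import SegmentKinematics, Trial, simulate_trial

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anthro():
    return Anthropometry(participant_id="REF", body_mass=79.0, body_height=1.8)


@pytest.fixture(scope="session")
def cohort3():
    return sample_cohort(3, seed=11)


@pytest.fixture(scope="session")
def mini_tasks():
    cfg = BatteryConfig(
        box_masses=(5.0, 23.0),
        shelf_pairs=(("low", "mid"), ("mid", "high")),
        styles=("squat", "stoop", "lateral", "diagonal"),
        repetitions=1,
    )
    return build_task_battery(cfg, seed=5)


@pytest.fixture(scope="session")
def mini_trials(cohort3, mini_tasks):
    trials = []
    for a in cohort3:
        for k, task in enumerate(mini_tasks):
            trials.append(simulate_trial(a, task, seed=400 + k))
    return trials


@pytest.fixture(scope="session")
def mini_dataset(mini_trials):
    return assemble_dataset(mini_trials, provenance="idealized", stride=5)


# ---------------------------------------------------------------------------
# hand-built static trial for closed-form inverse-dynamics checks


_STATIC_TABLE = {
    "pelvis": SegmentParams(0.10, 0.090, 0.50, 0.31),
    "trunk": SegmentParams(0.50, 0.330, 0.55, 0.42),
    "thigh_r": SegmentParams(0.09, 0.245, 0.567, 0.323),
    "thigh_l": SegmentParams(0.09, 0.245, 0.567, 0.323),
    "shank_r": SegmentParams(0.07, 0.246, 0.567, 0.302),
    "shank_l": SegmentParams(0.07, 0.246, 0.567, 0.302),
    "foot_r": SegmentParams(0.04, 0.152, 0.50, 0.475),
    "foot_l": SegmentParams(0.04, 0.152, 0.50, 0.475),
}


def make_static_trial(
    trunk_com_offset=(0.0, 0.2, 0.0),
    object_mass=0.0,
    object_offset=(0.4, -0.1, 0.0),
    body_mass=80.0,
    n_samples=5,
) -> Trial:
    """A motionless posture with configurable trunk-CoM and object offsets.

    Body mass 80 kg with a 0.5 trunk mass fraction gives a 40 kg upper body;
    all lower-body CoMs sit on the vertical through the ankles.  The GRF is
    synthesized, so the trial is exactly consistent.
    """
    anthro = Anthropometry("STATIC", body_mass=body_mass, body_height=1.8,
                           segment_params=dict(_STATIC_TABLE))
    T = n_samples
    zeros3 = np.zeros((T, 3))
    identity = np.zeros((T, 4))
    identity[:, 0] = 1.0

    l5s1 = np.array([0.0, 1.0, 0.0])
    positions = {
        "foot_r": [0.0, 0.03, 0.17], "foot_l": [0.0, 0.03, -0.17],
        "shank_r": [0.0, 0.25, 0.17], "shank_l": [0.0, 0.25, -0.17],
        "thigh_r": [0.0, 0.65, 0.17], "thigh_l": [0.0, 0.65, -0.17],
        "pelvis": [0.0, 0.95, 0.0],
        "trunk": list(l5s1 + np.asarray(trunk_com_offset)),
    }
    segments = {
        name: SegmentKinematics(
            quat=identity.copy(), angvel=zeros3.copy(), angacc=zeros3.copy(),
            com=np.broadcast_to(pos, (T, 3)).copy(),
            com_vel=zeros3.copy(), com_acc=zeros3.copy())
        for name, pos in positions.items()
    }
    joints = {
        "ankle_r": np.broadcast_to([0.0, 0.07, 0.17], (T, 3)).copy(),
        "ankle_l": np.broadcast_to([0.0, 0.07, -0.17], (T, 3)).copy(),
        "knee_r": np.broadcast_to([0.0, 0.5, 0.17], (T, 3)).copy(),
        "knee_l": np.broadcast_to([0.0, 0.5, -0.17], (T, 3)).copy(),
        "hip_r": np.broadcast_to([0.0, 0.9, 0.17], (T, 3)).copy(),
        "hip_l": np.broadcast_to([0.0, 0.9, -0.17], (T, 3)).copy(),
        "l5s1": np.broadcast_to(l5s1, (T, 3)).copy(),
    }
    trial = Trial(
        participant_id="STATIC", task_id="static", rate=100.0,
        time=np.arange(T) / 100.0, anthro=anthro,
        segments=segments, joint_centers=joints, grf=None, cop=None,
        object_mass=np.full(T, object_mass),
        object_position=np.broadcast_to(l5s1 + np.asarray(object_offset), (T, 3)).copy(),
        object_acc=zeros3.copy(),
        box_mass=object_mass, style="squat",
    )
    grf, cop, _ = whole_body_grf(trial)
    trial.grf = grf
    trial.cop = cop
    trial.ground_truth = bottom_up_lumbar(trial)
    return trial


def rotate_trial_about_y(trial: Trial, angle: float) -> Trial:
    """Rigidly rotate a whole trial about the vertical axis."""
    from backload._rotation import quat_about, quat_mul, quat_rotate

    q = quat_about(1, np.full(1, angle))[0]
    out = trial.copy()
    for seg in out.segments.values():
        seg.quat[:] = quat_mul(np.broadcast_to(q, seg.quat.shape), seg.quat)
        for arr in (seg.angvel, seg.angacc, seg.com, seg.com_vel, seg.com_acc):
            arr[:] = quat_rotate(q, arr)
    for arr in out.joint_centers.values():
        arr[:] = quat_rotate(q, arr)
    for s in ("r", "l"):
        out.grf[s][:] = quat_rotate(q, out.grf[s])
        out.cop[s][:] = quat_rotate(q, out.cop[s])
    out.object_position[:] = quat_rotate(q, out.object_position)
    out.object_acc[:] = quat_rotate(q, out.object_acc)
    return out
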