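"""Synthetic lifting-trial simulator.

Each trial is a pick-and-place task: the participant moves from upright
standing into a style-specific reaching posture at the origin shelf, picks
up the box, carries it upright, places it at the destination shelf, and
returns to standing.  Postures are keyframes in a 9-coordinate generalized
space (absolute sagittal segment angles for shank/thigh/pelvis, a Z-X-Y
trunk orientation, and a global-frame arm offset of the hand from the
chest); keyframes are connected by rest-to-rest minimum-jerk interpolation,
so velocities and accelerations are analytic.

Ground reaction forces are synthesized from the whole-body inertial and
gravitational requirement (see :mod:`backload.dynamics`), which makes every
noise-free trial dynamically consistent by construction.  The handheld load
transfers on/off the body through a 0.1 s linear ramp centered on the pick
and place instants, both of which fall inside stationary dwell phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import dynamics
from ._rotation import quat_about, quat_mul, quat_rotate
from .anthropometry import (
    ANKLE_HEIGHT_FRAC,
    CHEST_FRAC,
    G,
    HEEL_X_FRAC,
    HIP_HALF_WIDTH_FRAC,
    Anthropometry,
)
from .battery import ShelfSpec, TaskSpec

__all__ = [
    "Trial",
    "SegmentKinematics",
    "NoiseConfig",
    "simulate_trial",
    "degrade_to_real",
    "quiet_standing_trial",
    "static_hold_trial",
]

# generalized coordinates: angles in rad, arm offsets in units of body height
COORD_NAMES = (
    "shank",
    "thigh",
    "pelvis",
    "trunk_flex",
    "trunk_lat",
    "trunk_ax",
    "arm_x",
    "arm_y",
    "arm_z",
)
_IDX = {name: i for i, name in enumerate(COORD_NAMES)}

_D2R = math.pi / 180.0

# Posture at full depth (d = 1), expressed as deltas from upright standing.
# Angles in degrees; arm offsets in fractions of body height.
_STYLE_GAINS = {
    "squat": (24, -88, 46, 38, 0, 0, 0.05, 0.34, 0.0),
    "stoop": (-4, -18, 58, 85, 0, 0, 0.02, 0.42, 0.0),
    "lateral": (2, -35, 45, 55, 20, 10, 0.00, 0.42, 0.20),
    "diagonal": (8, -55, 48, 50, 10, 35, 0.02, 0.40, 0.12),
}

_UPRIGHT = np.array([0, 0, 0, 0, 0, 0, 0.10, 0.06, 0.0])

_LOAD_RAMP = 0.1  # s, linear load transfer at pick/place
_CARRY_LEAN_RAD_PER_KG = 0.006  # compensatory trunk extension while carrying
_BALANCE_X_M = 0.040  # m, nominal anterior balance point over the ankles
# holding a load shifts the stance point forward (postural under-compensation)
_LOAD_COP_SHIFT_M_PER_KG = 0.0013

# trunk flexion is forward-positive; the rotation about global Z is -flexion
_EY = np.array([0.0, 1.0, 0.0])
_EX = np.array([1.0, 0.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


@dataclass
class SegmentKinematics:
    """Per-segment rigid-body kinematics, all in the global frame."""

    quat: np.ndarray  # (T, 4) scalar-first unit quaternions
    angvel: np.ndarray  # (T, 3) rad/s
    angacc: np.ndarray  # (T, 3) rad/s^2
    com: np.ndarray  # (T, 3) m
    com_vel: np.ndarray  # (T, 3) m/s
    com_acc: np.ndarray  # (T, 3) m/s^2

    def copy(self) -> "SegmentKinematics":
        return SegmentKinematics(*(np.array(getattr(self, f), copy=True) for f in
                                   ("quat", "angvel", "angacc", "com", "com_vel", "com_acc")))


@dataclass
class Trial:
    """One synchronized pick-and-place recording."""

    participant_id: str
    task_id: str
    rate: float
    time: np.ndarray  # (T,)
    anthro: Anthropometry
    segments: dict[str, SegmentKinematics]
    joint_centers: dict[str, np.ndarray]  # ankle/knee/hip (r/l) and l5s1, (T, 3)
    grf: dict[str, np.ndarray] | None  # per-foot ground reaction force, N
    cop: dict[str, np.ndarray] | None  # per-foot center of pressure, m
    object_mass: np.ndarray  # (T,), effective supported mass, kg
    object_position: np.ndarray  # (T, 3)
    object_acc: np.ndarray  # (T, 3), hand-point acceleration used for the load
    box_mass: float
    style: str
    ground_truth: "dynamics.MomentSeries | None" = None
    noise_free: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def copy(self) -> "Trial":
        return Trial(
            participant_id=self.participant_id,
            task_id=self.task_id,
            rate=self.rate,
            time=self.time.copy(),
            anthro=self.anthro,
            segments={k: v.copy() for k, v in self.segments.items()},
            joint_centers={k: v.copy() for k, v in self.joint_centers.items()},
            grf=None if self.grf is None else {k: v.copy() for k, v in self.grf.items()},
            cop=None if self.cop is None else {k: v.copy() for k, v in self.cop.items()},
            object_mass=self.object_mass.copy(),
            object_position=self.object_position.copy(),
            object_acc=self.object_acc.copy(),
            box_mass=self.box_mass,
            style=self.style,
            ground_truth=self.ground_truth,
            noise_free=self.noise_free,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Real-wearable degradation magnitudes.

    The defaults make insole force variability the dominant degradation;
    a zero config is the identity.
    """

    insole_gain_sd: float = 0.15  # per-trial multiplicative error per insole
    insole_additive_sd: float = 20.0  # N, white noise on the vertical force
    insole_saturation: float | None = None  # N, clip on vertical force
    cop_sd: float = 0.01  # m, white noise on CoP (x and z)
    imu_angle_bias_sd: float = 0.5  # deg, constant per-segment orientation bias
    imu_angle_white_sd: float = 0.3  # deg, per-sample orientation noise
    seed_policy: str = "per_trial"

    def __post_init__(self) -> None:
        for name in ("insole_gain_sd", "insole_additive_sd", "cop_sd",
                     "imu_angle_bias_sd", "imu_angle_white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.insole_saturation is not None and self.insole_saturation < 0:
            raise ValueError("saturation below zero")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, None, 0.0, 0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (
            self.insole_gain_sd == 0
            and self.insole_additive_sd == 0
            and self.insole_saturation is None
            and self.cop_sd == 0
            and self.imu_angle_bias_sd == 0
            and self.imu_angle_white_sd == 0
        )


# ---------------------------------------------------------------------------
# minimum-jerk keyframe paths


class KeyframePath:
    """Rest-to-rest minimum-jerk interpolation through posture keyframes.

    Each between-keyframe segment may carry a "balance bump" on one
    coordinate: a smooth correction ``c * (4 s (1 - s))**2`` of the
    minimum-jerk phase ``s`` that vanishes (with zero velocity and
    acceleration) at both keyframes.  It is used to keep mid-transition
    postures statically balanced over the feet.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray,
                 bumps: np.ndarray | None = None, bump_coord: int = 0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("keyframe times must increase")
        self.bumps = np.zeros(len(self.times) - 1) if bumps is None else np.asarray(bumps, float)
        self.bump_coord = bump_coord

    def __call__(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.times) - 2)
        t0 = self.times[idx]
        dt = self.times[idx + 1] - t0
        tau = np.clip((t - t0) / dt, 0.0, 1.0)
        s = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
        ds = (30.0 * tau**2 - 60.0 * tau**3 + 30.0 * tau**4) / dt
        dds = (60.0 * tau - 180.0 * tau**2 + 120.0 * tau**3) / dt**2
        a = self.values[idx]
        delta = self.values[idx + 1] - a
        pos = a + delta * s[:, None]
        vel = delta * ds[:, None]
        acc = delta * dds[:, None]

        c = self.bumps[idx]
        if np.any(c != 0.0):
            b = (4.0 * s * (1.0 - s)) ** 2
            db_ds = 32.0 * s * (1.0 - s) * (1.0 - 2.0 * s)
            ddb_ds2 = 32.0 * (1.0 - 6.0 * s + 6.0 * s**2)
            k = self.bump_coord
            pos[:, k] += c * b
            vel[:, k] += c * db_ds * ds
            acc[:, k] += c * (ddb_ds2 * ds**2 + db_ds * dds)
        return pos, vel, acc


# ---------------------------------------------------------------------------
# chain kinematics


def _seg_dir(theta, dtheta, ddtheta):
    """Unit direction of a sagittal segment (forward-lean positive) + derivatives."""
    s, c = np.sin(theta), np.cos(theta)
    zero = np.zeros_like(theta)
    u = np.stack([s, c, zero], axis=-1)
    du = dtheta[..., None] * np.stack([c, -s, zero], axis=-1)
    ddu = ddtheta[..., None] * np.stack([c, -s, zero], axis=-1) - (
        dtheta**2
    )[..., None] * np.stack([s, c, zero], axis=-1)
    return u, du, ddu


def _trunk_orientation(alpha, beta, gamma, d1, d2):
    """Trunk quaternion R = Rz(-alpha) Rx(beta) Ry(gamma) with analytic omega.

    ``alpha`` is forward flexion (positive), ``beta`` lateral lean, ``gamma``
    axial rotation.  d1/d2 are dicts of first/second derivatives.
    """
    qz = quat_about(2, -alpha)
    qzx = quat_mul(qz, quat_about(0, beta))
    q = quat_mul(qzx, quat_about(1, gamma))

    t1 = -d1["a"][:, None] * _EZ
    t2 = quat_rotate(qz, d1["b"][:, None] * _EX)
    t3 = quat_rotate(qzx, d1["g"][:, None] * _EY)
    omega = t1 + t2 + t3

    omega_z = t1
    omega_zx = t1 + t2
    dt1 = -d2["a"][:, None] * _EZ
    dt2 = np.cross(omega_z, t2) + quat_rotate(qz, d2["b"][:, None] * _EX)
    dt3 = np.cross(omega_zx, t3) + quat_rotate(qzx, d2["g"][:, None] * _EY)
    omega_dot = dt1 + dt2 + dt3
    return q, omega, omega_dot


def _attach(q, omega, omega_dot, base, base_v, base_a, v_local):
    """Kinematics of a point fixed in a rotating frame, offset v_local from base."""
    r = quat_rotate(q, np.broadcast_to(v_local, q.shape[:-1] + (3,)))
    p = base + r
    v = base_v + np.cross(omega, r)
    a = base_a + np.cross(omega_dot, r) + np.cross(omega, np.cross(omega, r))
    return p, v, a


def _chain_kinematics(anthro: Anthropometry, Q, Qd, Qdd):
    """Full-body kinematics from generalized-coordinate time series (T, 9)."""
    H = anthro.body_height
    T = Q.shape[0]
    zeros3 = np.zeros((T, 3))

    def col(name):
        i = _IDX[name]
        return Q[:, i], Qd[:, i], Qdd[:, i]

    L_sh = anthro.segment_length("shank_r")
    L_th = anthro.segment_length("thigh_r")
    L_pv = anthro.segment_length("pelvis")
    L_tr = anthro.segment_length("trunk")
    hw = HIP_HALF_WIDTH_FRAC * H
    ankle_y = ANKLE_HEIGHT_FRAC * H

    th_s, dth_s, ddth_s = col("shank")
    th_t, dth_t, ddth_t = col("thigh")
    th_p, dth_p, ddth_p = col("pelvis")

    u_s, du_s, ddu_s = _seg_dir(th_s, dth_s, ddth_s)
    u_t, du_t, ddu_t = _seg_dir(th_t, dth_t, ddth_t)
    u_p, du_p, ddu_p = _seg_dir(th_p, dth_p, ddth_p)

    ankle = {s: np.broadcast_to([0.0, ankle_y, sign * hw], (T, 3)).copy()
             for s, sign in (("r", 1.0), ("l", -1.0))}
    knee = {s: ankle[s] + L_sh * u_s for s in "rl"}
    knee_v = L_sh * du_s
    knee_a = L_sh * ddu_s
    hip = {s: knee[s] + L_th * u_t for s in "rl"}
    hip_v = knee_v + L_th * du_t
    hip_a = knee_a + L_th * ddu_t

    hip_mid = hip["r"].copy()
    hip_mid[:, 2] = 0.0
    l5s1 = hip_mid + L_pv * u_p
    l5s1_v = hip_v + L_pv * du_p
    l5s1_a = hip_a + L_pv * ddu_p

    a, da, dda = col("trunk_flex")
    b, db, ddb = col("trunk_lat")
    g_, dg, ddg = col("trunk_ax")
    q_tr, w_tr, dw_tr = _trunk_orientation(a, b, g_, {"a": da, "b": db, "g": dg},
                                           {"a": dda, "b": ddb, "g": ddg})

    f_tr = anthro.segment_params["trunk"].com_frac
    trunk_com, trunk_com_v, trunk_com_a = _attach(
        q_tr, w_tr, dw_tr, l5s1, l5s1_v, l5s1_a, np.array([0.0, f_tr * L_tr, 0.0]))
    chest, chest_v, chest_a = _attach(
        q_tr, w_tr, dw_tr, l5s1, l5s1_v, l5s1_a, np.array([0.0, CHEST_FRAC * H, 0.0]))

    ax, dax, ddax = col("arm_x")
    ay, day, dday = col("arm_y")
    az, daz, ddaz = col("arm_z")
    arm = H * np.stack([ax, -ay, az], axis=-1)
    hand = chest + arm
    hand_v = chest_v + H * np.stack([dax, -day, daz], axis=-1)
    hand_a = chest_a + H * np.stack([ddax, -dday, ddaz], axis=-1)

    # per-segment kinematics
    def uniax_seg(theta, dtheta, ddtheta, base, base_v, base_a, length, com_frac):
        u, du, ddu = _seg_dir(theta, dtheta, ddtheta)
        w = np.zeros((T, 3))
        w[:, 2] = -dtheta
        dw = np.zeros((T, 3))
        dw[:, 2] = -ddtheta
        return SegmentKinematics(
            quat=quat_about(2, -theta),
            angvel=w,
            angacc=dw,
            com=base + com_frac * length * u,
            com_vel=base_v + com_frac * length * du,
            com_acc=base_a + com_frac * length * ddu,
        )

    segments: dict[str, SegmentKinematics] = {}
    heel_x = HEEL_X_FRAC * H
    foot_len = anthro.segment_length("foot_r")
    for s, sign in (("r", 1.0), ("l", -1.0)):
        foot_com = np.broadcast_to(
            [heel_x + 0.5 * foot_len, 0.5 * ankle_y, sign * hw], (T, 3)).copy()
        identity = np.zeros((T, 4))
        identity[:, 0] = 1.0
        segments[f"foot_{s}"] = SegmentKinematics(
            quat=identity, angvel=zeros3.copy(), angacc=zeros3.copy(),
            com=foot_com, com_vel=zeros3.copy(), com_acc=zeros3.copy())
        segments[f"shank_{s}"] = uniax_seg(
            th_s, dth_s, ddth_s, ankle[s], zeros3, zeros3, L_sh,
            anthro.segment_params["shank_r"].com_frac)
        segments[f"thigh_{s}"] = uniax_seg(
            th_t, dth_t, ddth_t, knee[s], knee_v, knee_a, L_th,
            anthro.segment_params["thigh_r"].com_frac)

    segments["pelvis"] = uniax_seg(
        th_p, dth_p, ddth_p, hip_mid, hip_v, hip_a, L_pv,
        anthro.segment_params["pelvis"].com_frac)
    segments["trunk"] = SegmentKinematics(
        quat=q_tr, angvel=w_tr, angacc=dw_tr,
        com=trunk_com, com_vel=trunk_com_v, com_acc=trunk_com_a)

    joints = {
        "ankle_r": ankle["r"], "ankle_l": ankle["l"],
        "knee_r": knee["r"], "knee_l": knee["l"],
        "hip_r": hip["r"], "hip_l": hip["l"],
        "l5s1": l5s1,
    }
    return segments, joints, (hand, hand_v, hand_a)


# ---------------------------------------------------------------------------
# posture solver


def _participant_habit(anthro: Anthropometry) -> dict:
    """Stable per-participant movement-habit offsets.

    Individuals differ in how much they bend knees vs hips vs trunk for the
    same reach, and in how far from the body they hold a load; the trunk
    orientation alone therefore does not determine the lumbar moment.  The
    habit is a deterministic function of the participant identity.
    """
    import zlib

    key = zlib.crc32(anthro.participant_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(key)
    return {
        "trunk_gain": float(np.clip(rng.normal(1.0, 0.08), 0.85, 1.15)),
        "arm_x_offset": float(np.clip(rng.normal(0.0, 0.02), -0.04, 0.04)),
    }


def _coords_at_depth(style: str, d: float, habit: dict | None = None) -> np.ndarray:
    gains = np.asarray(_STYLE_GAINS[style], dtype=float).copy()
    gains[:6] *= _D2R
    if habit is not None:
        # trunk-dominant vs knee-dominant lifting style
        gains[_IDX["trunk_flex"]] *= habit["trunk_gain"]
    coords = _UPRIGHT.copy()
    coords[:6] += max(d, 0.0) * gains[:6]  # angles never extend past upright
    coords[6:] += d * gains[6:]
    if habit is not None:
        coords[_IDX["arm_x"]] += habit["arm_x_offset"]
    return coords


def _static_state(anthro: Anthropometry, coords: np.ndarray):
    Q = coords[None, :]
    Z = np.zeros_like(Q)
    return _chain_kinematics(anthro, Q, Z, Z)


def _com_x_with_load(anthro: Anthropometry, coords: np.ndarray, load_mass: float) -> float:
    """Anterior CoM of the body plus a point load at the hand."""
    segments, _, (hand, _, _) = _static_state(anthro, coords)
    m_total = load_mass
    mx = load_mass * hand[0, 0]
    for name, seg in segments.items():
        m = anthro.segment_mass(name)
        m_total += m
        mx += m * seg.com[0, 0]
    return mx / m_total


def _balance_target(anthro: Anthropometry, load_mass: float) -> float:
    """Anterior balance point over the feet; shifts forward under load."""
    return _BALANCE_X_M + _LOAD_COP_SHIFT_M_PER_KG * load_mass


def _balanced(anthro: Anthropometry, coords: np.ndarray, load_mass: float) -> np.ndarray:
    """Adjust the shank lean so the (body + load) CoM sits over the balance point."""
    target = _balance_target(anthro, load_mass)

    def f(delta):
        c = coords.copy()
        c[_IDX["shank"]] += delta
        return _com_x_with_load(anthro, c, load_mass) - target

    delta = brentq(f, -1.0, 1.0, xtol=1e-6)
    out = coords.copy()
    out[_IDX["shank"]] += delta
    return out


def _hand_height(anthro: Anthropometry, coords: np.ndarray, load_mass: float) -> float:
    _, _, (hand, _, _) = _static_state(anthro, _balanced(anthro, coords, load_mass))
    return float(hand[0, 1])


_keyframe_cache: dict[tuple, np.ndarray] = {}
_bump_cache: dict[tuple, float] = {}


def _balance_bump(anthro: Anthropometry, mid_coords: np.ndarray, load_mass: float) -> float:
    """Shank-angle correction that balances a mid-transition posture."""
    key = (anthro.participant_id, tuple(np.round(mid_coords, 5)), round(load_mass, 3))
    if key not in _bump_cache:
        balanced = _balanced(anthro, mid_coords, load_mass)
        _bump_cache[key] = float(balanced[_IDX["shank"]] - mid_coords[_IDX["shank"]])
    return _bump_cache[key]


def solve_keyframe(
    anthro: Anthropometry,
    style: str,
    shelf: ShelfSpec | None,
    load_mass: float = 0.0,
) -> np.ndarray:
    """Balanced posture coordinates reaching the given shelf (None = carry posture).

    ``load_mass`` is the point load at the hand assumed when balancing; the
    shelf keyframes use half the box mass (the participant holds the box for
    roughly half of the time spent at the shelf).
    """
    key = (
        anthro.participant_id, round(anthro.body_height, 6), round(anthro.body_mass, 6),
        style, round(load_mass, 3),
        None if shelf is None else (shelf.name, round(shelf.height, 4),
                                    round(shelf.lateral_offset, 4)),
    )
    if key in _keyframe_cache:
        return _keyframe_cache[key].copy()

    habit = _participant_habit(anthro)
    if shelf is None:
        upright = _UPRIGHT.copy()
        upright[_IDX["arm_x"]] += habit["arm_x_offset"]
        # carrying a load in front induces a compensatory trunk lean-back
        upright[_IDX["trunk_flex"]] -= _CARRY_LEAN_RAD_PER_KG * load_mass
        coords = _balanced(anthro, upright, load_mass)
    else:
        side = 1.0 if shelf.lateral_offset >= 0 else -1.0

        def posture(d):
            c = _coords_at_depth(style, d, habit)
            c[_IDX["trunk_lat"]] *= side
            c[_IDX["trunk_ax"]] *= side
            c[_IDX["arm_z"]] *= side
            return c

        def f(d):
            return _hand_height(anthro, posture(d), load_mass) - shelf.height

        try:
            d = brentq(f, -0.35, 1.2, xtol=1e-6)
        except ValueError as err:
            raise ValueError(
                f"shelf {shelf.name!r} unreachable for participant "
                f"{anthro.participant_id} with style {style!r}") from err
        coords = _balanced(anthro, posture(d), load_mass)

    _keyframe_cache[key] = coords.copy()
    return coords


# ---------------------------------------------------------------------------
# trial assembly


def _load_fraction(t: np.ndarray, pick: float, place: float) -> np.ndarray:
    half = _LOAD_RAMP / 2.0
    up = np.clip((t - (pick - half)) / _LOAD_RAMP, 0.0, 1.0)
    down = np.clip((t - (place - half)) / _LOAD_RAMP, 0.0, 1.0)
    return up - down


def _jitter(coords: np.ndarray, rng: np.random.Generator, angle_sd: float, arm_sd: float) -> np.ndarray:
    out = coords.copy()
    out[:6] += np.clip(rng.normal(0.0, angle_sd * _D2R, 6), -2 * angle_sd * _D2R, 2 * angle_sd * _D2R)
    out[6:] += np.clip(rng.normal(0.0, arm_sd, 3), -2 * arm_sd, 2 * arm_sd)
    return out


def simulate_trial(
    anthro: Anthropometry,
    task: TaskSpec,
    rate: float = 100.0,
    seed: int = 0,
    posture_jitter_deg: float = 2.5,
    arm_jitter_frac: float = 0.015,
    grip_jitter_frac: float = 0.025,
    balance_load: float | None = None,
) -> Trial:
    """Simulate one dynamically consistent pick-and-place trial.

    ``balance_load`` overrides the hand load assumed when balancing postures
    (default: half the box mass at the shelves, the full box while carrying);
    fixing it across trials of different box mass yields matched kinematics.
    """
    if rate < 20.0:
        raise ValueError("rate too low to resolve the motion (need >= 20 Hz)")
    rng = np.random.default_rng(seed)

    shelf_load = 0.5 * task.box_mass if balance_load is None else balance_load
    carry_load = task.box_mass if balance_load is None else balance_load
    k_stand = solve_keyframe(anthro, task.style, None, 0.0)
    k_carry = solve_keyframe(anthro, task.style, None, carry_load)
    k_origin_c = solve_keyframe(anthro, task.style, task.origin_shelf, shelf_load)
    k_dest_c = solve_keyframe(anthro, task.style, task.destination_shelf, shelf_load)

    jit = lambda c: _jitter(c, rng, posture_jitter_deg, arm_jitter_frac)
    k_start, k_origin, k_carry_mid, k_dest, k_end = (
        jit(k_stand), jit(k_origin_c), jit(k_carry), jit(k_dest_c), jit(k_stand))
    # the grip distance for this trial's box, shared across the loaded keyframes;
    # invisible to body-worn IMUs but a direct lever on the lumbar moment
    grip = float(np.clip(rng.normal(0.0, grip_jitter_frac),
                         -2 * grip_jitter_frac, 2 * grip_jitter_frac))
    for kf in (k_origin, k_carry_mid, k_dest):
        kf[_IDX["arm_x"]] += grip

    dwell = min(0.3, 0.8 * (task.place_time - task.pick_time) / 2.0,
                0.8 * task.pick_time)
    d2 = dwell / 2.0
    mid = (task.pick_time + task.place_time) / 2.0
    times = np.array([
        0.0,
        task.pick_time - d2, task.pick_time + d2,
        mid,
        task.place_time - d2, task.place_time + d2,
        task.duration,
    ])
    values = np.stack([k_start, k_origin, k_origin, k_carry_mid, k_dest, k_dest, k_end])
    # balance bumps keep mid-transition postures over the feet; solved on the
    # unjittered keyframes so they are cacheable across repetitions
    clean = np.stack([k_stand, k_origin_c, k_origin_c, k_carry, k_dest_c, k_dest_c, k_stand])
    seg_loads = (0.0, 0.0, carry_load, carry_load, 0.0, 0.0)
    bumps = np.zeros(6)
    for i in (0, 2, 3, 5):
        mid = 0.5 * (clean[i] + clean[i + 1])
        bumps[i] = _balance_bump(anthro, mid, seg_loads[i])
    path = KeyframePath(times, values, bumps=bumps, bump_coord=_IDX["shank"])

    t = np.arange(int(round(task.duration * rate))) / rate
    Q, Qd, Qdd = path(t)
    segments, joints, (hand, _, hand_a) = _chain_kinematics(anthro, Q, Qd, Qdd)

    lam = _load_fraction(t, task.pick_time, task.place_time)
    object_mass = lam * task.box_mass

    # object rests at the shelf outside the carry window
    i_pick = int(np.searchsorted(t, task.pick_time))
    i_place = min(int(np.searchsorted(t, task.place_time)), len(t) - 1)
    object_position = hand.copy()
    object_position[: i_pick][lam[:i_pick] == 0] = hand[i_pick]
    object_position[i_place:][lam[i_place:] == 0] = hand[i_place]

    trial = Trial(
        participant_id=anthro.participant_id,
        task_id=task.task_id,
        rate=rate,
        time=t,
        anthro=anthro,
        segments=segments,
        joint_centers=joints,
        grf=None,
        cop=None,
        object_mass=object_mass,
        object_position=object_position,
        object_acc=hand_a,
        box_mass=task.box_mass,
        style=task.style,
        meta={"origin": task.origin_shelf.name, "destination": task.destination_shelf.name,
              "pick_time": task.pick_time, "place_time": task.place_time, "seed": seed},
    )
    grf, cop, n_clipped = dynamics.whole_body_grf(trial)
    trial.grf = grf
    trial.cop = cop
    trial.meta["cop_clipped_samples"] = n_clipped
    trial.ground_truth = dynamics.bottom_up_lumbar(trial)
    return trial


def _constant_posture_trial(
    anthro: Anthropometry,
    coords: np.ndarray,
    held_mass: float,
    duration: float,
    rate: float,
    task_id: str,
    style: str,
) -> Trial:
    t = np.arange(int(round(duration * rate))) / rate
    Q = np.broadcast_to(coords, (len(t), len(coords))).copy()
    Z = np.zeros_like(Q)
    segments, joints, (hand, _, hand_a) = _chain_kinematics(anthro, Q, Z, Z)
    trial = Trial(
        participant_id=anthro.participant_id,
        task_id=task_id,
        rate=rate,
        time=t,
        anthro=anthro,
        segments=segments,
        joint_centers=joints,
        grf=None,
        cop=None,
        object_mass=np.full(len(t), held_mass),
        object_position=hand,
        object_acc=hand_a,
        box_mass=held_mass,
        style=style,
        meta={"static": True},
    )
    grf, cop, n_clipped = dynamics.whole_body_grf(trial)
    trial.grf = grf
    trial.cop = cop
    trial.meta["cop_clipped_samples"] = n_clipped
    trial.ground_truth = dynamics.bottom_up_lumbar(trial)
    return trial


def quiet_standing_trial(anthro: Anthropometry, duration: float = 2.0, rate: float = 100.0) -> Trial:
    """Upright quiet standing, no load: a static-equilibrium reference trial."""
    coords = solve_keyframe(anthro, "squat", None, 0.0)
    return _constant_posture_trial(anthro, coords, 0.0, duration, rate, "quiet", "squat")


def static_hold_trial(
    anthro: Anthropometry, held_mass: float, duration: float = 2.0, rate: float = 100.0
) -> Trial:
    """Static upright carry of a box of ``held_mass`` kg."""
    coords = solve_keyframe(anthro, "squat", None, held_mass)
    return _constant_posture_trial(anthro, coords, held_mass, duration, rate, "hold", "squat")


# ---------------------------------------------------------------------------
# real-sensor degradation


_IMU_SEGMENTS = ("pelvis", "trunk", "thigh_r", "thigh_l", "shank_r", "shank_l",
                 "foot_r", "foot_l")


def _random_rotvec(rng: np.random.Generator, angle_sd_rad: float, shape) -> np.ndarray:
    axes = rng.normal(size=shape + (3,))
    axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
    angles = rng.normal(0.0, angle_sd_rad, shape)
    return axes * angles[..., None]


def degrade_to_real(trial: Trial, noise: NoiseConfig, seed: int = 0) -> Trial:
    """Emulate real wearable sensing on a noise-free trial.

    Insole-facing channels (per-foot GRF and CoP) receive a per-trial
    multiplicative gain error, additive white noise and optional saturation;
    IMU-facing orientation channels receive a constant per-segment bias
    rotation plus per-sample white rotation noise.  The lab ground truth is
    left untouched.
    """
    if not trial.noise_free:
        raise ValueError("degrade_to_real expects a noise-free trial")
    out = trial.copy()
    if noise.is_identity:
        return out
    rng = np.random.default_rng(seed)
    T = trial.n_samples

    for s in ("r", "l"):
        gain = 1.0 + rng.normal(0.0, noise.insole_gain_sd)
        f = out.grf[s]
        f *= gain
        f[:, 1] += rng.normal(0.0, noise.insole_additive_sd, T)
        if noise.insole_saturation is not None:
            np.clip(f[:, 1], None, noise.insole_saturation, out=f[:, 1])
        c = out.cop[s]
        c[:, 0] += rng.normal(0.0, noise.cop_sd, T)
        c[:, 2] += rng.normal(0.0, noise.cop_sd, T)

    from ._rotation import quat_from_rotvec

    bias_rad = noise.imu_angle_bias_sd * _D2R
    white_rad = noise.imu_angle_white_sd * _D2R
    for name in _IMU_SEGMENTS:
        q = out.segments[name].quat
        perturbed = False
        if bias_rad > 0:
            qb = quat_from_rotvec(_random_rotvec(rng, bias_rad, ()))
            q[:] = quat_mul(np.broadcast_to(qb, q.shape), q)
            perturbed = True
        if white_rad > 0:
            qw = quat_from_rotvec(_random_rotvec(rng, white_rad, (T,)))
            q[:] = quat_mul(qw, q)
            perturbed = True
        if perturbed:
            q /= np.linalg.norm(q, axis=-1, keepdims=True)

    out.noise_free = False
    return out
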