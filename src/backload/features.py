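"""Wearable channel sets, sensor-location subsetting and z-scoring.

Two channel inventories are built from a trial:

* the *idealized* set (51 channels): segment orientations (8 segments x 3
  Euler angles), joint angles (7 joints x 3) and idealized insole signals
  (2 normal forces + 4 CoP components) — lab-quality signals recast in the
  form a wearable could report;
* the *real-emulated* set (179 channels): a denser model-based export with
  11 segments (the Xsens-style spine chain L5/L3/T12/T8 interpolated between
  pelvis and trunk) x (3 Euler + 4 quaternion + 3 angular velocity + 3
  linear acceleration), 10 joints x 3, and the insole signals, normally
  computed from a noise-degraded trial.

Each channel knows which of the six candidate sensor locations (trunk,
pelvis, thigh, shank, foot, insole) must be worn for it to exist; a joint
angle requires the sensors on both adjacent segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._rotation import quat_slerp
from .anthropometry import HEEL_X_FRAC, HIP_HALF_WIDTH_FRAC
from .dynamics import normalize_bwbh
from .signals import idealize_insole
from .simulate import Trial

__all__ = [
    "ChannelInfo",
    "FeatureMatrix",
    "Normalizer",
    "CANONICAL_LOCATIONS",
    "build_idealized_features",
    "build_real_features",
    "subset_features",
    "fit_normalizer",
    "apply_normalizer",
    "assemble_dataset",
]

CANONICAL_LOCATIONS = ("trunk", "pelvis", "thigh", "shank", "foot", "insole")

_EULER_SEQ = "ZXY"
_EULER_SUFFIX = ("z", "x", "y")

_IDEAL_SEGMENTS = ("pelvis", "trunk", "thigh_r", "thigh_l", "shank_r", "shank_l",
                   "foot_r", "foot_l")

_SEG_LOCATION = {
    "pelvis": "pelvis", "trunk": "trunk",
    "thigh_r": "thigh", "thigh_l": "thigh",
    "shank_r": "shank", "shank_l": "shank",
    "foot_r": "foot", "foot_l": "foot",
    # model-exported spine segments are owned by the nearest physical IMU
    "l5": "pelvis", "l3": "pelvis", "t12": "trunk", "t8": "trunk",
}

_IDEAL_JOINTS = (
    ("lumbar", "pelvis", "trunk"),
    ("hip_r", "pelvis", "thigh_r"), ("hip_l", "pelvis", "thigh_l"),
    ("knee_r", "thigh_r", "shank_r"), ("knee_l", "thigh_l", "shank_l"),
    ("ankle_r", "shank_r", "foot_r"), ("ankle_l", "shank_l", "foot_l"),
)

#: spherical-interpolation fractions between pelvis and trunk orientation
_SPINE_FRACTIONS = {"l5": 0.2, "l3": 0.45, "t12": 0.7, "t8": 0.9}

_REAL_SEGMENTS = ("pelvis", "l5", "l3", "t12", "t8",
                  "thigh_r", "thigh_l", "shank_r", "shank_l", "foot_r", "foot_l")

_REAL_JOINTS = (
    ("l5s1", "pelvis", "l5"), ("l4l3", "l5", "l3"),
    ("l1t12", "l3", "t12"), ("t9t8", "t12", "t8"),
    ("hip_r", "pelvis", "thigh_r"), ("hip_l", "pelvis", "thigh_l"),
    ("knee_r", "thigh_r", "shank_r"), ("knee_l", "thigh_l", "shank_l"),
    ("ankle_r", "shank_r", "foot_r"), ("ankle_l", "shank_l", "foot_l"),
)


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one feature column."""

    name: str
    location: str
    kind: str
    units: str
    requires: tuple[str, ...]  # sensor locations needed for this channel


@dataclass
class FeatureMatrix:
    """Per-sample wearable channel values plus channel metadata."""

    values: np.ndarray  # (n_samples, n_channels)
    channels: list[ChannelInfo]
    index: pd.DataFrame  # participant_id, task_id, time per sample
    provenance: str  # "idealized" | "real"

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel metadata / value shape mismatch")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite feature values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        return pd.concat([self.index.reset_index(drop=True), df], axis=1)

    def rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[mask], self.channels,
                             self.index.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
                             .reset_index(drop=True),
                             self.provenance)

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        first = parts[0]
        for p in parts[1:]:
            if [c.name for c in p.channels] != first.channel_names:
                raise ValueError("channel schema mismatch")
        return FeatureMatrix(
            np.concatenate([p.values for p in parts], axis=0),
            first.channels,
            pd.concat([p.index for p in parts], ignore_index=True),
            first.provenance,
        )


def _euler(quat_wxyz: np.ndarray) -> np.ndarray:
    r = Rotation.from_quat(quat_wxyz[:, [1, 2, 3, 0]])
    return r.as_euler(_EULER_SEQ)


def _relative_euler(q_parent: np.ndarray, q_child: np.ndarray) -> np.ndarray:
    rp = Rotation.from_quat(q_parent[:, [1, 2, 3, 0]])
    rc = Rotation.from_quat(q_child[:, [1, 2, 3, 0]])
    return (rp.inv() * rc).as_euler(_EULER_SEQ)


def _insole_blocks(trial: Trial) -> tuple[list[np.ndarray], list[ChannelInfo]]:
    H = trial.anthro.body_height
    cols: list[np.ndarray] = []
    infos: list[ChannelInfo] = []
    force_cols = []
    cop_cols = []
    for s, sign in (("r", 1.0), ("l", -1.0)):
        heel = np.array([HEEL_X_FRAC * H, 0.0, sign * HIP_HALF_WIDTH_FRAC * H])
        nf, cx, cy = idealize_insole(trial.grf[s], trial.cop[s],
                                     trial.segments[f"foot_{s}"].quat, heel)
        force_cols.append((f"insole_force_{s}", nf))
        cop_cols.append((f"insole_cop_{s}_x", cx))
        cop_cols.append((f"insole_cop_{s}_y", cy))
    for name, v in force_cols:
        cols.append(v)
        infos.append(ChannelInfo(name, "insole", "normal_force", "N", ("insole",)))
    for name, v in cop_cols:
        kind = "cop_x" if name.endswith("_x") else "cop_y"
        cols.append(v)
        infos.append(ChannelInfo(name, "insole", kind, "m", ("insole",)))
    return cols, infos


def build_idealized_features(trial: Trial) -> FeatureMatrix:
    """Table-style idealized channel set: 24 + 21 + 2 + 4 = 51 channels."""
    for seg in _IDEAL_SEGMENTS:
        if seg not in trial.segments:
            raise ValueError(f"trial missing segment {seg!r}")
    if trial.grf is None:
        raise ValueError("trial missing foot force data")

    cols: list[np.ndarray] = []
    infos: list[ChannelInfo] = []
    for seg in _IDEAL_SEGMENTS:
        ang = _euler(trial.segments[seg].quat)
        loc = _SEG_LOCATION[seg]
        for k, suffix in enumerate(_EULER_SUFFIX):
            cols.append(ang[:, k])
            infos.append(ChannelInfo(f"euler_{seg}_{suffix}", loc, "euler_angle", "rad", (loc,)))
    for joint, parent, child in _IDEAL_JOINTS:
        ang = _relative_euler(trial.segments[parent].quat, trial.segments[child].quat)
        req = tuple(dict.fromkeys((_SEG_LOCATION[parent], _SEG_LOCATION[child])))
        for k, suffix in enumerate(_EULER_SUFFIX):
            cols.append(ang[:, k])
            infos.append(ChannelInfo(f"joint_{joint}_{suffix}", f"joint:{joint}",
                                     "joint_angle", "rad", req))
    icols, iinfos = _insole_blocks(trial)
    cols.extend(icols)
    infos.extend(iinfos)

    index = pd.DataFrame({
        "participant_id": trial.participant_id,
        "task_id": trial.task_id,
        "time": trial.time,
    })
    return FeatureMatrix(np.stack(cols, axis=-1), infos, index, "idealized")


def _spine_kinematics(trial: Trial) -> dict[str, dict[str, np.ndarray]]:
    """Model-based spine segment export: slerp between pelvis and trunk."""
    qp = trial.segments["pelvis"].quat
    qt = trial.segments["trunk"].quat
    out = {}
    for name, u in _SPINE_FRACTIONS.items():
        out[name] = {
            "quat": quat_slerp(qp, qt, u),
            "angvel": (1 - u) * trial.segments["pelvis"].angvel + u * trial.segments["trunk"].angvel,
            "linacc": (1 - u) * trial.segments["pelvis"].com_acc + u * trial.segments["trunk"].com_acc,
        }
    return out


def build_real_features(trial: Trial) -> FeatureMatrix:
    """Real-emulated channel set: 33 + 44 + 33 + 33 + 30 + 2 + 4 = 179 channels.

    Normally called on a trial degraded by
    :func:`backload.simulate.degrade_to_real`; with a zero noise
    configuration the shared channels equal their idealized counterparts.
    """
    spine = _spine_kinematics(trial)

    def seg_quat(name):
        return spine[name]["quat"] if name in spine else trial.segments[name].quat

    def seg_angvel(name):
        return spine[name]["angvel"] if name in spine else trial.segments[name].angvel

    def seg_linacc(name):
        return spine[name]["linacc"] if name in spine else trial.segments[name].com_acc

    cols: list[np.ndarray] = []
    infos: list[ChannelInfo] = []
    for seg in _REAL_SEGMENTS:
        loc = _SEG_LOCATION[seg]
        ang = _euler(seg_quat(seg))
        for k, suffix in enumerate(_EULER_SUFFIX):
            cols.append(ang[:, k])
            infos.append(ChannelInfo(f"euler_{seg}_{suffix}", loc, "euler_angle", "rad", (loc,)))
    for seg in _REAL_SEGMENTS:
        loc = _SEG_LOCATION[seg]
        q = seg_quat(seg)
        for k, suffix in enumerate("wxyz"):
            cols.append(q[:, k])
            infos.append(ChannelInfo(f"quat_{seg}_{suffix}", loc, "quaternion", "1", (loc,)))
    for seg in _REAL_SEGMENTS:
        loc = _SEG_LOCATION[seg]
        w = seg_angvel(seg)
        for k, suffix in enumerate("xyz"):
            cols.append(w[:, k])
            infos.append(ChannelInfo(f"angvel_{seg}_{suffix}", loc, "angular_velocity",
                                     "rad/s", (loc,)))
    for seg in _REAL_SEGMENTS:
        loc = _SEG_LOCATION[seg]
        a = seg_linacc(seg)
        for k, suffix in enumerate("xyz"):
            cols.append(a[:, k])
            infos.append(ChannelInfo(f"linacc_{seg}_{suffix}", loc, "linear_acceleration",
                                     "m/s^2", (loc,)))
    for joint, parent, child in _REAL_JOINTS:
        ang = _relative_euler(seg_quat(parent), seg_quat(child))
        req = tuple(dict.fromkeys((_SEG_LOCATION[parent], _SEG_LOCATION[child])))
        for k, suffix in enumerate(_EULER_SUFFIX):
            cols.append(ang[:, k])
            infos.append(ChannelInfo(f"joint_{joint}_{suffix}", f"joint:{joint}",
                                     "joint_angle", "rad", req))
    icols, iinfos = _insole_blocks(trial)
    cols.extend(icols)
    infos.extend(iinfos)

    index = pd.DataFrame({
        "participant_id": trial.participant_id,
        "task_id": trial.task_id,
        "time": trial.time,
    })
    return FeatureMatrix(np.stack(cols, axis=-1), infos, index, "real")


def subset_features(fm: FeatureMatrix, locations) -> FeatureMatrix:
    """Retain channels whose required sensor locations are all worn."""
    locations = tuple(locations)
    if not locations:
        raise ValueError("empty sensor-location subset")
    for loc in locations:
        if loc not in CANONICAL_LOCATIONS:
            raise ValueError(f"unknown sensor location {loc!r}")
    keep = [i for i, c in enumerate(fm.channels) if set(c.requires) <= set(locations)]
    return FeatureMatrix(fm.values[:, keep], [fm.channels[i] for i in keep],
                         fm.index, fm.provenance)


@dataclass
class Normalizer:
    """Per-channel z-score statistics fitted on training samples only."""

    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray
    channel_names: list[str] = field(default_factory=list)


def fit_normalizer(X, channel_names: list[str] | None = None) -> Normalizer:
    if isinstance(X, FeatureMatrix):
        channel_names = X.channel_names
        X = X.values
    X = np.asarray(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    # constant channels pass through unscaled (and are flagged)
    scale = np.where(constant, 1.0, sd)
    mean = np.where(constant, 0.0, mean)
    return Normalizer(mean=mean, scale=scale, constant_mask=constant,
                      channel_names=list(channel_names or []))


def apply_normalizer(norm: Normalizer, X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.values
    return (np.asarray(X) - norm.mean) / norm.scale


def assemble_dataset(
    trials,
    provenance: str = "idealized",
    target: str = "extension",
    stride: int = 1,
    dtype=np.float32,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Stack per-trial features and BW x BH normalized targets.

    ``stride`` decimates samples in time (the per-sample estimator needs no
    temporal context, so decimation only reduces the training-set size).
    """
    build = build_idealized_features if provenance == "idealized" else build_real_features
    parts = []
    targets = []
    for trial in trials:
        fm = build(trial)
        gt = normalize_bwbh(trial.ground_truth, trial.anthro)
        y = gt.extension if target == "extension" else gt.lateral_bending
        if stride > 1:
            fm = fm.rows(np.arange(0, fm.n_samples, stride))
            y = y[::stride]
        parts.append(fm)
        targets.append(y)
    out = FeatureMatrix.concat(parts)
    out.values = out.values.astype(dtype)
    return out, np.concatenate(targets).astype(dtype)
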