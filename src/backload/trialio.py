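"""Trial serialization: wide columnar time-series files plus a JSON sidecar.

One file per trial (CSV or Parquet, chosen by suffix), one row per sample,
with a documented column-name contract:

``time`` |
``quat_<seg>_{w,x,y,z}`` | ``angvel_<seg>_{x,y,z}`` | ``angacc_<seg>_{x,y,z}`` |
``com_<seg>_{x,y,z}`` | ``comvel_<seg>_{x,y,z}`` | ``comacc_<seg>_{x,y,z}`` |
``joint_<name>_{x,y,z}`` | ``grf_{r,l}_{x,y,z}`` | ``cop_{r,l}_{x,y,z}`` |
``object_mass`` | ``objpos_{x,y,z}`` | ``objacc_{x,y,z}`` |
``lumbar_ext_Nm`` | ``lumbar_lat_Nm``

Scalar metadata (participant, task, rate, anthropometry, provenance flags)
lives in a ``<stem>.meta.json`` sidecar so externally produced trials can be
ingested with the same schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry, SegmentParams
from .dynamics import MomentSeries
from .simulate import SegmentKinematics, Trial

_XYZ = "xyz"
_WXYZ = "wxyz"

_SEG_FIELDS = (
    ("quat", "quat", _WXYZ),
    ("angvel", "angvel", _XYZ),
    ("angacc", "angacc", _XYZ),
    ("com", "com", _XYZ),
    ("comvel", "com_vel", _XYZ),
    ("comacc", "com_acc", _XYZ),
)


def trial_to_frame(trial: Trial) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"time": trial.time}
    for seg in sorted(trial.segments):
        kin = trial.segments[seg]
        for prefix, attr, axes in _SEG_FIELDS:
            arr = getattr(kin, attr)
            for k, ax in enumerate(axes):
                cols[f"{prefix}_{seg}_{ax}"] = arr[:, k]
    for joint in sorted(trial.joint_centers):
        for k, ax in enumerate(_XYZ):
            cols[f"joint_{joint}_{ax}"] = trial.joint_centers[joint][:, k]
    for s in ("r", "l"):
        for k, ax in enumerate(_XYZ):
            cols[f"grf_{s}_{ax}"] = trial.grf[s][:, k]
            cols[f"cop_{s}_{ax}"] = trial.cop[s][:, k]
    cols["object_mass"] = trial.object_mass
    for k, ax in enumerate(_XYZ):
        cols[f"objpos_{ax}"] = trial.object_position[:, k]
        cols[f"objacc_{ax}"] = trial.object_acc[:, k]
    if trial.ground_truth is not None:
        cols["lumbar_ext_Nm"] = trial.ground_truth.extension
        cols["lumbar_lat_Nm"] = trial.ground_truth.lateral_bending
    return pd.DataFrame(cols)


def _trial_meta(trial: Trial) -> dict:
    return {
        "participant_id": trial.participant_id,
        "task_id": trial.task_id,
        "rate": trial.rate,
        "box_mass": trial.box_mass,
        "style": trial.style,
        "noise_free": trial.noise_free,
        "meta": trial.meta,
        "anthropometry": {
            "participant_id": trial.anthro.participant_id,
            "body_mass": trial.anthro.body_mass,
            "body_height": trial.anthro.body_height,
            "sex": trial.anthro.sex,
            "segment_params": {
                name: [p.mass_frac, p.length_frac, p.com_frac, p.rog_frac]
                for name, p in trial.anthro.segment_params.items()
            },
        },
    }


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write one trial; format chosen by suffix (.csv or .parquet)."""
    path = Path(path)
    frame = trial_to_frame(trial)
    if path.suffix == ".csv":
        frame.to_csv(path, index=False)
    elif path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported trial format {path.suffix!r}")
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(_trial_meta(trial), indent=1))
    return path


def frame_to_trial(frame: pd.DataFrame, meta: dict) -> Trial:
    am = meta["anthropometry"]
    anthro = Anthropometry(
        participant_id=am["participant_id"],
        body_mass=am["body_mass"],
        body_height=am["body_height"],
        sex=am.get("sex", "na"),
        segment_params={
            name: SegmentParams(*vals) for name, vals in am["segment_params"].items()
        },
    )
    seg_names = sorted({c.split("_", 1)[1][:-2] for c in frame.columns if c.startswith("quat_")})

    def block(prefix, name, axes):
        return np.stack([frame[f"{prefix}_{name}_{ax}"].to_numpy() for ax in axes], axis=-1)

    segments = {
        seg: SegmentKinematics(*(block(prefix, seg, axes) for prefix, _, axes in _SEG_FIELDS))
        for seg in seg_names
    }
    joint_names = sorted({c[len("joint_"):-2] for c in frame.columns if c.startswith("joint_")})
    joints = {j: block("joint", j, _XYZ) for j in joint_names}
    grf = {s: block("grf", s, _XYZ) for s in ("r", "l")}
    cop = {s: block("cop", s, _XYZ) for s in ("r", "l")}
    gt = None
    if "lumbar_ext_Nm" in frame.columns:
        gt = MomentSeries(
            rate=meta["rate"],
            extension=frame["lumbar_ext_Nm"].to_numpy(),
            lateral_bending=frame["lumbar_lat_Nm"].to_numpy(),
            units="Nm",
            source="lab_truth",
        )
    return Trial(
        participant_id=meta["participant_id"],
        task_id=meta["task_id"],
        rate=meta["rate"],
        time=frame["time"].to_numpy(),
        anthro=anthro,
        segments=segments,
        joint_centers=joints,
        grf=grf,
        cop=cop,
        object_mass=frame["object_mass"].to_numpy(),
        object_position=np.stack([frame[f"objpos_{ax}"].to_numpy() for ax in _XYZ], axis=-1),
        object_acc=np.stack([frame[f"objacc_{ax}"].to_numpy() for ax in _XYZ], axis=-1),
        box_mass=meta["box_mass"],
        style=meta["style"],
        ground_truth=gt,
        noise_free=meta.get("noise_free", True),
        meta=meta.get("meta", {}),
    )


def read_trial(path: str | Path) -> Trial:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    if path.suffix == ".csv":
        frame = pd.read_csv(path)
    elif path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        raise ValueError(f"unsupported trial format {path.suffix!r}")
    return frame_to_trial(frame, meta)
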