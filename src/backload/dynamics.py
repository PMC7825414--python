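"""Lumbar moments by rigid-body inverse dynamics.

Two independent routes to the L5/S1 net internal moment are provided:

* :func:`bottom_up_lumbar` — a recursive Newton–Euler pass starting from the
  measured (or synthesized) external wrench under each foot, up through
  shank, thigh and pelvis; this mirrors how lab gold standards are computed
  from force plates.
* :func:`top_down_lumbar` — the gravitational and inertial wrench of the
  trunk (with head and arms lumped) plus the handheld load about L5/S1.

For any dynamically consistent trial the two agree exactly, which serves as
the package's central numerical oracle.  Sign convention (global X anterior,
Y up, Z right): the internal moment resisting forward flexion — lumbar
extension — is the +Z component; lateral bending is the +X component.

:func:`whole_body_grf` synthesizes per-foot ground reaction forces and
centers of pressure from whole-body kinematics so that force balance holds
exactly and the X/Z moment balance is satisfied through the CoP placement.
The vertical-axis free moment under the feet is not modeled; it provably
cannot affect the extension or lateral-bending components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from ._rotation import quat_conj, quat_rotate
from .anthropometry import G, HEEL_X_FRAC, HIP_HALF_WIDTH_FRAC, Anthropometry

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Trial

logger = logging.getLogger(__name__)

G_VEC = np.array([0.0, -G, 0.0])

#: fraction of the transverse moment of inertia used about the long axis
_LONG_AXIS_INERTIA_RATIO = 0.3


@dataclass
class MomentSeries:
    """L5/S1 extension and lateral-bending moment time series."""

    rate: float
    extension: np.ndarray
    lateral_bending: np.ndarray
    units: str = "Nm"  # "Nm" | "BWBH"
    source: str = "lab_truth"  # "lab_truth" | "wearable_estimate"

    def __post_init__(self) -> None:
        if self.units not in ("Nm", "BWBH"):
            raise ValueError("units must be 'Nm' or 'BWBH'")
        if len(self.extension) != len(self.lateral_bending):
            raise ValueError("component length mismatch")
        if not (np.all(np.isfinite(self.extension)) and np.all(np.isfinite(self.lateral_bending))):
            raise ValueError("non-finite moment values")


def _segment_inertia_dh(trial: "Trial", name: str) -> np.ndarray:
    """Rate of change of angular momentum about the segment CoM, global frame."""
    seg = trial.segments[name]
    p = trial.anthro.segment_params[name]
    m = trial.anthro.segment_mass(name)
    L = trial.anthro.segment_length(name)
    i_t = m * (p.rog_frac * L) ** 2
    inertia = np.array([i_t, _LONG_AXIS_INERTIA_RATIO * i_t, i_t])

    qc = quat_conj(seg.quat)
    w_body = quat_rotate(qc, seg.angvel)
    dw_body = quat_rotate(qc, seg.angacc)
    h = quat_rotate(seg.quat, inertia * w_body)
    dh = quat_rotate(seg.quat, inertia * dw_body) + np.cross(seg.angvel, h)
    return dh


def whole_body_grf(trial: "Trial") -> tuple[dict, dict, int]:
    """Synthesize per-foot GRF and CoP from whole-body dynamics.

    Force balance is exact; sagittal and frontal moment balance are
    satisfied by CoP placement (frontal-plane lever rule between the feet).
    Returns ``(grf, cop, n_clipped)`` where ``n_clipped`` counts samples
    whose CoP had to be clipped into the support polygon (clipping is logged
    and breaks exact consistency for those samples).
    """
    anthro = trial.anthro
    T = trial.n_samples
    f_req = np.zeros((T, 3))
    m_req = np.zeros((T, 3))
    for name, seg in trial.segments.items():
        m = anthro.segment_mass(name)
        f_i = m * (seg.com_acc - G_VEC)
        f_req += f_i
        m_req += np.cross(seg.com, f_i) + _segment_inertia_dh(trial, name)
    f_obj = trial.object_mass[:, None] * (trial.object_acc - G_VEC)
    f_req += f_obj
    m_req += np.cross(trial.object_position, f_obj)

    fy = f_req[:, 1]
    if np.any(fy <= 0):
        raise ValueError("airborne configuration: required vertical force <= 0")

    x_star = m_req[:, 2] / fy
    z_star = -m_req[:, 0] / fy

    H = anthro.body_height
    z_r = HIP_HALF_WIDTH_FRAC * H
    z_l = -z_r
    w_r = np.clip((z_star - z_l) / (z_r - z_l), 0.0, 1.0)
    w_l = 1.0 - w_r
    # restore exact frontal balance after weight clipping by a common CoP shift
    delta_z = z_star - (w_r * z_r + w_l * z_l)

    heel_x = HEEL_X_FRAC * H
    toe_x = heel_x + anthro.segment_length("foot_r")
    half_width = 0.035 * H
    x_cop = x_star
    n_clipped = int(np.sum((x_cop < heel_x) | (x_cop > toe_x)))
    if n_clipped:
        logger.warning("CoP clipped to the support polygon on %d samples", n_clipped)
        x_cop = np.clip(x_cop, heel_x, toe_x)

    grf = {}
    cop = {}
    for s, w, z_foot in (("r", w_r, z_r), ("l", w_l, z_l)):
        grf[s] = w[:, None] * f_req
        z_c = z_foot + delta_z
        clip_lo, clip_hi = z_foot - half_width, z_foot + half_width
        extra = int(np.sum((z_c < clip_lo) | (z_c > clip_hi)))
        if extra:
            logger.warning("lateral CoP clipped on %d samples (foot %s)", extra, s)
            z_c = np.clip(z_c, clip_lo, clip_hi)
            n_clipped += extra
        cop[s] = np.stack([x_cop, np.zeros(T), z_c], axis=-1)
    return grf, cop, n_clipped


def _newton_euler_step(trial, name, prox_point, ext_forces):
    """One segment of the recursion.

    ``ext_forces`` is a list of ``(force, point, couple)`` external wrenches
    on the segment.  Returns the force/couple the parent applies at the
    proximal joint.
    """
    seg = trial.segments[name]
    m = trial.anthro.segment_mass(name)
    f_inert = m * (seg.com_acc - G_VEC)
    f_prox = f_inert.copy()
    m_prox = _segment_inertia_dh(trial, name) + np.cross(seg.com - prox_point, f_inert)
    for force, point, couple in ext_forces:
        f_prox -= force
        m_prox -= np.cross(point - prox_point, force)
        if couple is not None:
            m_prox -= couple
    return f_prox, m_prox


def bottom_up_lumbar(trial: "Trial") -> MomentSeries:
    """L5/S1 internal moment by bottom-up recursive Newton–Euler.

    Starts from each foot's external wrench (GRF at its CoP), proceeds
    through shank and thigh to the pelvis, and reports the net internal
    moment the lower body exerts on the trunk at L5/S1.
    """
    if trial.grf is None or trial.cop is None:
        raise ValueError("trial lacks ground reaction forces")
    j = trial.joint_centers
    for arr in (trial.grf["r"], trial.grf["l"], j["l5s1"]):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input")

    hip_wrenches = []
    for s in ("r", "l"):
        f, mm = _newton_euler_step(
            trial, f"foot_{s}", j[f"ankle_{s}"],
            [(trial.grf[s], trial.cop[s], None)])
        f, mm = _newton_euler_step(
            trial, f"shank_{s}", j[f"knee_{s}"],
            [(-f, j[f"ankle_{s}"], -mm)])
        f, mm = _newton_euler_step(
            trial, f"thigh_{s}", j[f"hip_{s}"],
            [(-f, j[f"knee_{s}"], -mm)])
        hip_wrenches.append((-f, j[f"hip_{s}"], -mm))

    f_l5, m_l5 = _newton_euler_step(trial, "pelvis", j["l5s1"], hip_wrenches)
    # m_l5 is the moment the trunk applies on the pelvis; the internal
    # lumbar moment acting on the trunk is its reaction.
    m_lumbar = -m_l5
    return MomentSeries(
        rate=trial.rate,
        extension=m_lumbar[:, 2].copy(),
        lateral_bending=m_lumbar[:, 0].copy(),
        units="Nm",
        source="lab_truth",
    )


def top_down_lumbar(trial: "Trial") -> MomentSeries:
    """L5/S1 internal moment from the trunk + handheld-load wrench (oracle route)."""
    j = trial.joint_centers["l5s1"]
    seg = trial.segments["trunk"]
    m_t = trial.anthro.segment_mass("trunk")
    mom = _segment_inertia_dh(trial, "trunk")
    mom = mom + np.cross(seg.com - j, m_t * (seg.com_acc - G_VEC))
    f_obj = trial.object_mass[:, None] * (trial.object_acc - G_VEC)
    mom = mom + np.cross(trial.object_position - j, f_obj)
    return MomentSeries(
        rate=trial.rate,
        extension=mom[:, 2].copy(),
        lateral_bending=mom[:, 0].copy(),
        units="Nm",
        source="lab_truth",
    )


def normalize_bwbh(series: MomentSeries, anthro: Anthropometry) -> MomentSeries:
    """Convert a moment series from Nm to body weight x body height units."""
    if series.units != "Nm":
        raise ValueError("series already normalized")
    scale = anthro.bwbh
    if scale <= 0:
        raise ValueError("zero or negative body mass/height")
    return replace(
        series,
        extension=series.extension / scale,
        lateral_bending=series.lateral_bending / scale,
        units="BWBH",
    )


def denormalize_bwbh(series: MomentSeries, anthro: Anthropometry) -> MomentSeries:
    """Inverse of :func:`normalize_bwbh`."""
    if series.units != "BWBH":
        raise ValueError("series is not in BW x BH units")
    scale = anthro.bwbh
    return replace(
        series,
        extension=series.extension * scale,
        lateral_bending=series.lateral_bending * scale,
        units="Nm",
    )
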