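"""Signal conditioning and the idealized-insole projection.

Lab-style signals are conditioned the way the measurement pipeline
prescribes: zero-lag (forward-backward) Butterworth low-pass filtering
(6 Hz for kinematics, 10 Hz for forces) and band-limited resampling to a
common 100 Hz rate.  :func:`idealize_insole` converts a 3D ground reaction
force and global-frame center of pressure into the signals a pressure
insole reports: the force component normal to the sole and the CoP in the
foot's own coordinate frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from ._rotation import quat_conj, quat_rotate

logger = logging.getLogger(__name__)

KINEMATICS_CUTOFF_HZ = 6.0
FORCE_CUTOFF_HZ = 10.0
FILTER_ORDER = 3

#: channel kinds recognized by the feature registry
CHANNEL_KINDS = (
    "euler_angle",
    "quaternion",
    "angular_velocity",
    "linear_acceleration",
    "joint_angle",
    "normal_force",
    "cop_x",
    "cop_y",
)


@dataclass(frozen=True)
class ChannelSeries:
    """One named wearable channel."""

    name: str
    location: str
    kind: str
    units: str
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in channel {self.name!r}")


def lowpass_zero_lag(values: np.ndarray, cutoff: float, order: int, rate: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, so order is doubled)."""
    if not 0 < cutoff < rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float), axis=0)


def resample(values: np.ndarray, rate: float, new_rate: float) -> np.ndarray:
    """Band-limited resampling; polyphase for rational rate ratios."""
    if rate <= 0 or new_rate <= 0:
        raise ValueError("rates must be positive")
    if new_rate == rate:
        return np.asarray(values, dtype=float).copy()
    frac = Fraction(new_rate / rate).limit_denominator(1000)
    values = np.asarray(values, dtype=float)
    if abs(float(frac) - new_rate / rate) < 1e-12:
        return sps.resample_poly(values, frac.numerator, frac.denominator, axis=0,
                                 padtype="line", window=("kaiser", 14.0))
    t_old = np.arange(values.shape[0]) / rate
    t_new = np.arange(int(round(values.shape[0] * new_rate / rate))) / new_rate
    if values.ndim == 1:
        return np.interp(t_new, t_old, values)
    return np.stack([np.interp(t_new, t_old, values[:, i]) for i in range(values.shape[1])], axis=-1)


def idealize_insole(
    grf: np.ndarray,
    cop_global: np.ndarray,
    foot_quat: np.ndarray,
    foot_origin: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project a 3D GRF + global CoP into pressure-insole style signals.

    The foot frame has X toe-ward, Y along the sole normal and Z lateral,
    with its origin at the heel.  Returns ``(normal_force, cop_x, cop_y)``
    where ``cop_x``/``cop_y`` are the toe-ward and lateral CoP coordinates
    in the foot frame.  Negative normal forces are floored at zero (an
    insole cannot pull) with a logged count.
    """
    foot_quat = np.asarray(foot_quat, dtype=float)
    norms = np.linalg.norm(foot_quat, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("non-unit foot quaternion")
    grf = np.asarray(grf, dtype=float)
    cop_global = np.asarray(cop_global, dtype=float)

    sole_normal = quat_rotate(foot_quat, np.broadcast_to([0.0, 1.0, 0.0], grf.shape))
    normal_force = np.sum(grf * sole_normal, axis=-1)
    n_floored = int(np.sum(normal_force < 0))
    if n_floored:
        logger.info("floored %d negative insole normal-force samples", n_floored)
        normal_force = np.maximum(normal_force, 0.0)

    rel = cop_global - (0.0 if foot_origin is None else foot_origin)
    cop_local = quat_rotate(quat_conj(foot_quat), rel)
    return normal_force, cop_local[..., 0], cop_local[..., 2]
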