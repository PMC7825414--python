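"""Vectorized quaternion helpers.

Quaternions are stored scalar-first ``(w, x, y, z)`` in arrays of shape
``(..., 4)``.  All rotations are active: ``rotate(q, v)`` maps a body-frame
vector into the global frame.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_about",
    "quat_mul",
    "quat_conj",
    "quat_rotate",
    "quat_to_matrix",
    "quat_from_rotvec",
    "quat_slerp",
    "quat_norm",
]


def quat_about(axis: int, angle: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation of ``angle`` (rad) about a principal axis (0=x, 1=y, 2=z)."""
    angle = np.asarray(angle, dtype=float)
    q = np.zeros(angle.shape + (4,))
    q[..., 0] = np.cos(angle / 2.0)
    q[..., 1 + axis] = np.sin(angle / 2.0)
    return q


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b, broadcasting over leading dimensions."""
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    out = np.array(q, copy=True)
    out[..., 1:] *= -1.0
    return out


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (..., 3) by quaternions ``q`` (..., 4)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., 1:]
    qw = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + qw * t + np.cross(qv, t)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) from quaternions (..., 4)."""
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Quaternion from rotation vectors (..., 3)."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1)
    q = np.zeros(rv.shape[:-1] + (4,))
    q[..., 0] = np.cos(angle / 2.0)
    small = angle < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(small, 0.5, np.sin(angle / 2.0) / np.where(small, 1.0, angle))
    q[..., 1:] = rv * scale[..., None]
    return q


def quat_slerp(q0: np.ndarray, q1: np.ndarray, u: float) -> np.ndarray:
    """Spherical interpolation at fixed fraction ``u`` between per-sample quats."""
    q0 = np.asarray(q0, dtype=float)
    q1 = np.array(q1, dtype=float, copy=True)
    dot = np.sum(q0 * q1, axis=-1)
    q1[dot < 0] *= -1.0
    dot = np.abs(dot).clip(-1.0, 1.0)
    theta = np.arccos(dot)
    sin_theta = np.sin(theta)
    near = sin_theta < 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = np.where(near, 1.0 - u, np.sin((1.0 - u) * theta) / np.where(near, 1.0, sin_theta))
        w1 = np.where(near, u, np.sin(u * theta) / np.where(near, 1.0, sin_theta))
    out = w0[..., None] * q0 + w1[..., None] * q1
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def quat_norm(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
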