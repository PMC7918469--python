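"""Quaternion algebra for rigid-body orientations.

Quaternions are stored as ``(w, x, y, z)`` arrays of shape ``(..., 4)`` and
kept unit-norm by the integrator.  All routines are vectorized over leading
axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_normalize",
    "quat_multiply",
    "quat_to_matrix",
    "rotvec_to_quat",
    "rotate_vectors",
    "random_unit_quaternions",
]


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (composition: rotate by b, then by a)."""
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices of shape (..., 3, 3) for unit quaternions."""
    w, x, y, z = np.moveaxis(q, -1, 0)
    xx, yy, zz = x * x, y * y, z * z
    wx, wy, wz = w * x, w * y, w * z
    xy, xz, yz = x * y, x * z, y * z
    m = np.empty(q.shape[:-1] + (3, 3), dtype=q.dtype)
    m[..., 0, 0] = 1.0 - 2.0 * (yy + zz)
    m[..., 0, 1] = 2.0 * (xy - wz)
    m[..., 0, 2] = 2.0 * (xz + wy)
    m[..., 1, 0] = 2.0 * (xy + wz)
    m[..., 1, 1] = 1.0 - 2.0 * (xx + zz)
    m[..., 1, 2] = 2.0 * (yz - wx)
    m[..., 2, 0] = 2.0 * (xz - wy)
    m[..., 2, 1] = 2.0 * (yz + wx)
    m[..., 2, 2] = 1.0 - 2.0 * (xx + yy)
    return m


def rotvec_to_quat(phi: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation vector (axis * angle), shape (..., 3)."""
    phi = np.asarray(phi, dtype=float)
    angle = np.linalg.norm(phi, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sin(a/2)/a, series-expanded near zero to stay exact for tiny rotations
    small = angle < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(small, 0.5 - angle * angle / 48.0, np.sin(half) / np.where(angle == 0.0, 1.0, angle))
    w = np.cos(half)
    xyz = factor * phi
    return np.concatenate([w, xyz], axis=-1)


def rotate_vectors(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vectors into the lab frame.

    q: (..., 4), v: (..., 3) or broadcastable; returns R(q) @ v.
    """
    return np.einsum("...ij,...j->...i", quat_to_matrix(q), v)


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random orientations (Shoemake's method)."""
    u1 = rng.random(n)
    u2 = rng.random(n) * 2.0 * np.pi
    u3 = rng.random(n) * 2.0 * np.pi
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.stack([a * np.sin(u2), a * np.cos(u2), b * np.sin(u3), b * np.cos(u3)], axis=-1)
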