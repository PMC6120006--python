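"""Minimal unit-quaternion helpers for rigid-body orientations.

Quaternions are stored scalar-first, ``(w, x, y, z)``; all functions accept
trailing-axis batches of shape ``(..., 4)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "quat_to_matrix",
    "quat_multiply",
    "quat_from_axis_angle",
    "random_quaternion",
    "identity",
]


def identity(n: int | None = None) -> np.ndarray:
    q = np.array([1.0, 0.0, 0.0, 0.0])
    return q if n is None else np.tile(q, (n, 1))


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with v_lab = R @ v_body; shape (..., 3, 3)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    w2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_from_axis_angle(axis_angle: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle, rad) -> quaternion."""
    v = np.asarray(axis_angle, dtype=float)
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * angle
    # series-safe sinc for small angles
    small = angle < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(small, 0.5, np.sin(half) / np.where(small, 1.0, angle))
    return np.concatenate([np.cos(half), s * v], axis=-1)


def random_quaternion(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform random rotation(s) (Shoemake's method)."""
    size = (n, 3) if n is not None else (3,)
    u = rng.random(size)
    u1, u2, u3 = u[..., 0], u[..., 1], u[..., 2]
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=-1,
    )
    return q
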