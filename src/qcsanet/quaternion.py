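"""Exact quaternion algebra.

A quaternion ``Q = r + x i + y j + z k`` is stored as an array of four real
components in the fixed order ``(r, x, y, z)``.  All functions accept
array-likes whose last axis has length 4 and broadcast over leading axes;
double precision is used throughout so that the layer code (single
precision) can treat this module as its numerical reference.

The imaginary units obey ``i^2 = j^2 = k^2 = ijk = -1``, which makes the
product non-commutative (``ij = k`` but ``ji = -k``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Quaternion",
    "PolarQuaternion",
    "RotationSpec",
    "hamilton_product",
    "conjugate",
    "norm",
    "inverse",
    "to_polar",
    "from_polar",
    "rotate_vector",
    "normalize_axis",
]

_IDENT = np.array([1.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class Quaternion:
    """A single quaternion ``r + x i + y j + z k``."""

    r: float
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: np.ndarray) -> "Quaternion":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected shape (4,), got {a.shape}")
        return Quaternion(*a.tolist())


@dataclass(frozen=True)
class PolarQuaternion:
    """Polar form ``rho * (cos(theta) + s sin(theta))``.

    ``rho`` is the magnitude, ``theta`` an angle in radians and ``s`` a pure
    unit quaternion giving the imaginary axis.
    """

    rho: float
    theta: float
    s: np.ndarray  # shape (4,), pure unit quaternion

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if s.shape != (4,):
            raise ValueError("axis s must be a quaternion of shape (4,)")
        if abs(s[0]) > 1e-9:
            raise ValueError("axis s must be a pure quaternion (zero real part)")
        if abs(np.linalg.norm(s) - 1.0) > 1e-9:
            raise ValueError("axis s must have unit norm")


@dataclass(frozen=True)
class RotationSpec:
    """A 3-D rotation: unit ``axis`` and ``angle`` in radians."""

    axis: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis)
        if axis.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError(
                "rotation axis must be unit length; use normalize_axis() first"
            )


def _as_q(q) -> np.ndarray:
    a = np.asarray(q, dtype=float)
    if a.shape[-1] != 4:
        raise ValueError(f"quaternion arrays need a trailing axis of 4, got {a.shape}")
    return a


def hamilton_product(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b``; broadcasts over leading axes.

    Couples all four components of each operand:

    ``(r1 r2 - x1 x2 - y1 y2 - z1 z2)
    + (r1 x2 + x1 r2 + y1 z2 - z1 y2) i
    + (r1 y2 - x1 z2 + y1 r2 + z1 x2) j
    + (r1 z2 + x1 y2 - y1 x2 + z1 r2) k``
    """
    a, b = _as_q(a), _as_q(b)
    r1, x1, y1, z1 = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    r2, x2, y2, z2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            r1 * r2 - x1 * x2 - y1 * y2 - z1 * z2,
            r1 * x2 + x1 * r2 + y1 * z2 - z1 * y2,
            r1 * y2 - x1 * z2 + y1 * r2 + z1 * x2,
            r1 * z2 + x1 * y2 - y1 * x2 + z1 * r2,
        ],
        axis=-1,
    )


def conjugate(q) -> np.ndarray:
    """``Q* = r - x i - y j - z k``."""
    q = _as_q(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def norm(q) -> np.ndarray | float:
    """``||Q|| = sqrt(r^2 + x^2 + y^2 + z^2)``."""
    q = _as_q(q)
    n = np.sqrt(np.sum(q * q, axis=-1))
    return float(n) if n.ndim == 0 else n


def inverse(q) -> np.ndarray:
    """``Q^{-1} = Q* / ||Q||^2``; raises on the zero quaternion."""
    q = _as_q(q)
    n2 = np.sum(q * q, axis=-1, keepdims=True)
    if np.any(n2 == 0.0):
        raise ZeroDivisionError("the zero quaternion has no inverse")
    return conjugate(q) / n2


def to_polar(q) -> PolarQuaternion:
    """Decompose one quaternion as ``rho (cos(theta) + s sin(theta))``.

    For a real quaternion the axis is undefined; the convention here is
    ``theta = 0`` (or ``pi`` for negative reals) with ``s = i``.
    """
    q = _as_q(q)
    if q.shape != (4,):
        raise ValueError("to_polar operates on a single quaternion")
    rho = float(np.linalg.norm(q))
    if rho == 0.0:
        raise ZeroDivisionError("the zero quaternion has no polar form")
    v = q[1:]
    vnorm = float(np.linalg.norm(v))
    theta = float(np.arctan2(vnorm, q[0]))
    if vnorm == 0.0:
        s = np.array([0.0, 1.0, 0.0, 0.0])
    else:
        s = np.concatenate([[0.0], v / vnorm])
    return PolarQuaternion(rho=rho, theta=theta, s=s)


def from_polar(p: PolarQuaternion) -> np.ndarray:
    """Inverse of :func:`to_polar`."""
    return p.rho * (np.cos(p.theta) * _IDENT + np.sin(p.theta) * p.s)


def normalize_axis(axis) -> np.ndarray:
    """Scale a non-zero 3-vector to unit length."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ZeroDivisionError("cannot normalize the zero vector")
    return axis / n


def rotate_vector(v, spec: RotationSpec) -> np.ndarray:
    """Rotate 3-vector ``v`` by ``spec.angle`` about ``spec.axis``.

    Uses the half-angle sandwich product ``p = w ⊗ v ⊗ w*`` with
    ``w = cos(theta/2) + sin(theta/2)(w1 i + w2 j + w3 k)``; embeds ``v``
    as a pure quaternion. Norm-preserving by construction.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("v must be a 3-vector")
    half = spec.angle / 2.0
    w = np.concatenate([[np.cos(half)], np.sin(half) * spec.axis])
    vq = np.concatenate([[0.0], v])
    out = hamilton_product(hamilton_product(w, vq), conjugate(w))
    return out[1:]
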