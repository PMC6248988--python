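"""Rigid-body algebra: transforms, points, composition, inversion.

All lengths are millimeters throughout the package.  Streams recorded by
real hardware in meters must be converted at ingestion (factor 1000).

A :class:`RigidTransform` maps device-local coordinates into a global
frame: ``x_global = R @ x_local + t``.  Rotations are stored as 3x3
matrices; orientation averaging is never needed anywhere in the package,
only endpoint positions are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import RigidityError

__all__ = [
    "RigidTransform",
    "EndpointOffset",
    "apply_transform",
    "compose",
    "invert",
    "nearest_rotation",
    "random_rotation",
]

logger = logging.getLogger(__name__)

#: Strict rigidity tolerance: inputs within this pass unchanged.
RIGID_TOL = 1e-9
#: Inputs failing RIGID_TOL but within this are re-orthonormalized (logged).
REPAIR_TOL = 1e-6

#: Default physical bound on an endpoint offset magnitude (mm).
DEFAULT_ENDPOINT_BOUND_MM = 200.0


def nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto the nearest proper rotation (Frobenius)."""
    u, _, vt = np.linalg.svd(np.asarray(m, dtype=float))
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] = -u[:, -1]
        r = u @ vt
    return r


def _rigidity_defect(r: np.ndarray) -> float:
    return max(
        float(np.abs(r.T @ r - np.eye(3)).max()),
        abs(float(np.linalg.det(r)) - 1.0),
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform (rotation + translation, no scale).

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1.
    translation
        3-vector, millimeters.

    Construction validates rigidity to 1e-9; matrices off by at most
    1e-6 are projected onto the nearest rotation and a warning is
    logged; anything worse raises :class:`~digikit.errors.RigidityError`.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise RigidityError(f"rotation must be 3x3, got {r.shape}")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise RigidityError("non-finite entries in transform")
        defect = _rigidity_defect(r)
        if defect > RIGID_TOL:
            if defect <= REPAIR_TOL:
                logger.warning(
                    "re-orthonormalizing near-rigid rotation (defect %.3g)", defect
                )
                r = nearest_rotation(r)
            else:
                raise RigidityError(
                    f"matrix is not rigid (orthonormality/det defect {defect:.3g})"
                )
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        self.rotation.setflags(write=False)
        self.translation.setflags(write=False)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix; bottom row must be 0,0,0,1."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise RigidityError(f"expected 4x4 matrix, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise RigidityError(f"bottom row must be [0,0,0,1], got {m[3].tolist()}")
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    # -- algebra ------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Apply to a point (3,) or a stack of points (N, 3)."""
        p = np.asarray(p, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform that applies `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class EndpointOffset:
    """Calibrated stylus-tip offset in the device-local frame (mm)."""

    offset: np.ndarray
    bound_mm: float = field(default=DEFAULT_ENDPOINT_BOUND_MM, compare=False)

    def __post_init__(self):
        v = np.asarray(self.offset, dtype=float).reshape(3)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite endpoint offset")
        norm = float(np.linalg.norm(v))
        if norm > self.bound_mm:
            raise ValueError(
                f"endpoint offset magnitude {norm:.3f} mm exceeds bound "
                f"{self.bound_mm:.1f} mm"
            )
        object.__setattr__(self, "offset", v)
        self.offset.setflags(write=False)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.offset))


def apply_transform(t: RigidTransform, p: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    if not isinstance(t, RigidTransform):
        raise RigidityError("apply_transform requires a RigidTransform")
    return t.apply(p)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` first, then ``a``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure) from `rng`."""
    from scipy.spatial.transform import Rotation

    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()
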