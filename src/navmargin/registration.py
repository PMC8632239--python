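"""Paired-point rigid registration with fiducial-error gating.

Image-to-tracker registration in the navigated simulations used
paired-point matching of predrilled divots, with a fiducial registration
error (FRE) of at most 1 mm considered acceptable.  The closed-form
least-squares rigid fit is the Kabsch/Umeyama SVD solution; FRE is the
root-mean-square residual over the fiducial pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "register_paired_points",
    "apply_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> R x + t (rotation det = +1, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> str:
        return json.dumps(
            {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        obj = json.loads(text)
        return cls(np.array(obj["rotation"]), np.array(obj["translation"]))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    fre: float  # mm, RMS residual over fiducials
    threshold: float  # mm acceptance gate

    @property
    def accepted(self) -> bool:
        return self.fre <= self.threshold


def apply_transform(transform: RigidTransform, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ transform.rotation.T + transform.translation


def register_paired_points(source, target, threshold: float = 1.0) -> RegistrationResult:
    """Closed-form least-squares rigid fit of paired points.

    Finds the proper rigid transform minimizing
    ``sum ||R s_i + t - g_i||^2`` via SVD of the cross-covariance, with
    the standard reflection guard (smallest singular direction flipped
    when the unconstrained optimum is a reflection).  This is the global
    optimum of the least-squares objective.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, mismatched lengths, or (near-)collinear
        source points, all of which leave the rotation underdetermined.
    """
    s = np.atleast_2d(np.asarray(source, dtype=float))
    g = np.atleast_2d(np.asarray(target, dtype=float))
    if s.shape != g.shape or s.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if s.shape[0] < 3:
        raise ValueError("paired-point registration needs at least 3 pairs")
    sc = s - s.mean(axis=0)
    gc = g - g.mean(axis=0)
    if np.linalg.matrix_rank(sc, tol=1e-9 * max(1.0, np.abs(sc).max())) < 2:
        raise ValueError("source fiducials are collinear: rotation is underdetermined")

    H = sc.T @ gc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = g.mean(axis=0) - R @ s.mean(axis=0)
    transform = RigidTransform(R, t)
    resid = apply_transform(transform, s) - g
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationResult(transform=transform, fre=fre, threshold=threshold)
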