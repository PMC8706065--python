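"""Head-pose estimation from 2D facial landmarks and rotation-error metrics.

Euler convention (documented, since per-axis comparisons depend on it):
intrinsic yaw-pitch-roll applied in that order — yaw about the vertical
(y) axis, pitch about the lateral (x) axis, roll about the frontal (z)
axis; angles in degrees.  Positive yaw turns the head to the subject's
left, positive pitch looks up.  Rotation-recovery and geodesic metrics are
convention independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover - import cycle with signal_sim
    from .signal_sim import CanonicalFaceModel

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RotationTriple",
    "UnitQuaternion",
    "RotationErrorSummary",
    "EULER_SEQ",
    "rotation_matrix",
    "estimate_pose",
    "euler_to_quaternion",
    "geodesic_deg",
    "rotation_errors",
]

#: intrinsic axis sequence: yaw about Y, then pitch about X, then roll about Z
EULER_SEQ = "YXZ"


@dataclass(frozen=True)
class RotationTriple:
    """Head orientation as (yaw, pitch, roll) in degrees."""

    yaw: float
    pitch: float
    roll: float

    def __post_init__(self) -> None:
        for name, v in (("yaw", self.yaw), ("pitch", self.pitch), ("roll", self.roll)):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not -90.0 <= v <= 90.0:
                raise ValueError(f"{name} must lie in [-90, 90] deg, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll], dtype=float)


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion (w, x, y, z) with the sign convention w >= 0."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        norm = self.w**2 + self.x**2 + self.y**2 + self.z**2
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion must have unit norm, got |q|^2 = {norm}")
        if self.w < 0:
            raise ValueError("quaternion sign convention requires w >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def dot(self, other: "UnitQuaternion") -> float:
        return float(self.as_array() @ other.as_array())


@dataclass(frozen=True)
class RotationErrorSummary:
    avg_abs_pitch_err: float
    avg_abs_yaw_err: float
    avg_abs_roll_err: float
    mse_all_angles: float
    avg_geodesic: float

    def __post_init__(self) -> None:
        for name in ("avg_abs_pitch_err", "avg_abs_yaw_err", "avg_abs_roll_err", "mse_all_angles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.avg_geodesic <= 180.0:
            raise ValueError("avg_geodesic must lie in [0, 180]")

    def to_dict(self) -> dict:
        return {
            "avg_abs_pitch_err_deg": self.avg_abs_pitch_err,
            "avg_abs_yaw_err_deg": self.avg_abs_yaw_err,
            "avg_abs_roll_err_deg": self.avg_abs_roll_err,
            "mse_all_angles_deg2": self.mse_all_angles,
            "avg_geodesic_deg": self.avg_geodesic,
        }


def rotation_matrix(rt: RotationTriple) -> np.ndarray:
    """3x3 rotation matrix of the yaw-pitch-roll triple."""
    return Rotation.from_euler(EULER_SEQ, [rt.yaw, rt.pitch, rt.roll], degrees=True).as_matrix()


def _euler_from_matrix(R: np.ndarray) -> RotationTriple:
    yaw, pitch, roll = Rotation.from_matrix(R).as_euler(EULER_SEQ, degrees=True)
    return RotationTriple(float(yaw), float(pitch), float(roll))


def estimate_pose(
    landmarks2d: Mapping[str, Sequence[float]],
    model: "CanonicalFaceModel",
) -> RotationTriple:
    """Best-fit head rotation from named 2D landmarks under scaled orthography.

    Solves the orthographic Procrustes problem: both point sets are
    centered, the least-squares 2x3 linear map from 3D model points to 2D
    image points is orthogonalized via SVD into the top two rows of a
    rotation (with a common scale), and the third row is completed by the
    cross product, guaranteeing determinant +1.

    Parameters
    ----------
    landmarks2d : mapping of landmark name -> (x, y) pixels
        At least 4 names shared with the model.
    model : CanonicalFaceModel
        Rigid 3D landmark model; correspondence is by name.
    """
    names = [n for n in model.names if n in landmarks2d]
    if len(names) < 4:
        raise ValueError(
            f"need >= 4 landmarks shared with the model, got {len(names)}"
        )
    X = np.asarray([model.points[n] for n in names], dtype=float)  # n x 3
    P = np.asarray([landmarks2d[n] for n in names], dtype=float)  # n x 2
    if P.shape != (len(names), 2):
        raise ValueError("landmarks must be 2-D points")
    Xc = X - X.mean(axis=0)
    Pc = P - P.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < 3:
        raise ValueError("degenerate model: centered 3D points are rank-deficient")
    # least-squares 2x3 map M with Pc ~ Xc @ M.T
    M, *_ = np.linalg.lstsq(Xc, Pc, rcond=None)
    M = M.T  # 2 x 3, equals scale * top-2-rows of R for exact data
    if np.linalg.matrix_rank(M) < 2:
        raise ValueError("degenerate landmark configuration: projected rank < 2")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    top = U @ Vt  # nearest matrix with orthonormal rows
    r3 = np.cross(top[0], top[1])
    R = np.vstack([top, r3])
    if np.linalg.det(R) < 0:  # defensive: cross-product completion is proper
        raise ValueError("reflection-only solution; landmark correspondence is mirrored")
    return _euler_from_matrix(R)


def euler_to_quaternion(rt: RotationTriple) -> UnitQuaternion:
    """Unit quaternion of the rotation, normalized to w >= 0."""
    x, y, z, w = Rotation.from_euler(
        EULER_SEQ, [rt.yaw, rt.pitch, rt.roll], degrees=True
    ).as_quat()
    q = np.array([w, x, y, z], dtype=float)
    if q[0] < 0:
        q = -q
    q /= np.linalg.norm(q)
    return UnitQuaternion(*q)


def geodesic_deg(q1: UnitQuaternion, q2: UnitQuaternion) -> float:
    """Geodesic distance between two orientations: 2*arccos(|q1.q2|) degrees."""
    d = abs(q1.dot(q2))
    return float(np.degrees(2.0 * np.arccos(np.clip(d, -1.0, 1.0))))


def rotation_errors(
    truth: Sequence[RotationTriple], est: Sequence[RotationTriple]
) -> RotationErrorSummary:
    """Per-axis mean absolute Euler errors, pooled MSE, and mean geodesic.

    The MSE pools the squared errors of all three angles over all frames
    (a single scalar in deg^2).
    """
    if len(truth) != len(est):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(est)} estimates")
    if len(truth) == 0:
        raise ValueError("need at least one frame")
    T = np.array([r.as_array() for r in truth])  # columns: yaw, pitch, roll
    E = np.array([r.as_array() for r in est])
    D = E - T
    geo = [geodesic_deg(euler_to_quaternion(a), euler_to_quaternion(b)) for a, b in zip(truth, est)]
    return RotationErrorSummary(
        avg_abs_pitch_err=float(np.mean(np.abs(D[:, 1]))),
        avg_abs_yaw_err=float(np.mean(np.abs(D[:, 0]))),
        avg_abs_roll_err=float(np.mean(np.abs(D[:, 2]))),
        mse_all_angles=float(np.mean(D**2)),
        avg_geodesic=float(np.mean(geo)),
    )
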