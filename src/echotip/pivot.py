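"""Pivot-calibration least squares: solve for the sensor-to-tip offset.

Rotating a tracked tool about a physically fixed tip point gives, for each
recorded pose ``(R_i, t_i)``, the rigid constraint

    R_i @ p_offset + t_i = p_fix,

where ``p_offset`` is the tip in the sensor's local frame and ``p_fix`` the
fixed pivot in the tracker frame.  Stacking all N constraints as

    [R_i | -I] @ [p_offset; p_fix] = -t_i

yields an over-determined 3N x 6 linear system solved by the singular-value
pseudo-inverse.  The RMS of the per-pose constraint mismatch is the
conventional calibration residual.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .em_poses import Pose, PoseSequence

logger = logging.getLogger(__name__)

__all__ = [
    "StackedSystem",
    "CalibrationResult",
    "InsufficientDataError",
    "DegenerateMotionError",
    "build_stacked_system",
    "solve_pivot",
    "tip_position",
    "calibration_report",
    "result_to_json",
    "result_from_json",
]

#: relative singular-value cutoff for the pseudo-inverse and rank test
SV_RCOND = 1e-10


class InsufficientDataError(ValueError):
    """Fewer than three valid poses: the system cannot be over-determined."""


class DegenerateMotionError(ValueError):
    """The rotations do not span enough of SO(3) to separate offset from pivot.

    All-identical rotations (e.g. a tool held still) leave the stacked matrix
    rank-deficient; any minimum-norm answer would be clinically meaningless,
    so this is raised instead of returning one silently.
    """


@dataclass
class StackedSystem:
    """The stacked linear system: ``design @ [p_offset; p_fix] = rhs``."""

    design: np.ndarray  # (3N, 6), rows [R_i | -I]
    rhs: np.ndarray  # (3N,), blocks -t_i

    @property
    def n_poses(self) -> int:
        return self.design.shape[0] // 3


@dataclass
class CalibrationResult:
    """Solved calibration with residual diagnostics.

    Attributes
    ----------
    p_offset : tip position in the sensor frame, mm.
    p_fix : pivot-point location in the tracker frame, mm.
    rms_residual : root-mean-square of the per-pose constraint mismatch, mm.
    per_pose_residuals : Euclidean norm of ``R_i @ p_offset + t_i - p_fix``
        for each pose used, mm.
    condition_number : ratio of extreme singular values of the design matrix.
    """

    p_offset: np.ndarray
    p_fix: np.ndarray
    rms_residual: float
    per_pose_residuals: np.ndarray = field(repr=False)
    condition_number: float
    n_poses: int

    @property
    def offset_magnitude(self) -> float:
        """Length of the sensor-to-tip offset, mm (the physical tip length)."""
        return float(np.linalg.norm(self.p_offset))


def build_stacked_system(poses: PoseSequence) -> StackedSystem:
    """Assemble the 3N x 6 design matrix [R_i | -I] and right-hand side -t_i."""
    n = len(poses)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 poses to calibrate, got {n}")
    design = np.zeros((3 * n, 6))
    rhs = np.zeros(3 * n)
    eye = np.eye(3)
    for i, pose in enumerate(poses):
        design[3 * i : 3 * i + 3, :3] = pose.rotation
        design[3 * i : 3 * i + 3, 3:] = -eye
        rhs[3 * i : 3 * i + 3] = -pose.translation
    return StackedSystem(design=design, rhs=rhs)


def solve_pivot(
    poses: PoseSequence,
    min_condition_warn: float = 1e6,
    trim_outliers: bool = False,
    trim_fraction: float = 0.05,
) -> CalibrationResult:
    """Solve the stacked pivot-calibration system by SVD pseudo-inverse.

    Parameters
    ----------
    poses : recorded pivoting motion (>= 3 poses, rotations not all equal).
    min_condition_warn : emit a warning when the design-matrix condition
        number exceeds this threshold (poorly excited motion).
    trim_outliers : optionally re-solve after dropping the worst
        ``trim_fraction`` of poses by first-pass residual (off by default;
        plain least squares is the reference behaviour).

    Returns
    -------
    CalibrationResult

    Raises
    ------
    InsufficientDataError : fewer than 3 poses.
    DegenerateMotionError : rank-deficient system (e.g. all rotations equal).
    """
    system = build_stacked_system(poses)
    result = _solve_system(system, poses, min_condition_warn)
    if trim_outliers and len(poses) > 6:
        keep = np.argsort(result.per_pose_residuals)
        n_keep = max(6, int(np.ceil(len(poses) * (1 - trim_fraction))))
        kept = PoseSequence(
            poses=[poses[int(i)] for i in sorted(keep[:n_keep])],
            source=poses.source,
            frame_id=poses.frame_id,
        )
        result = _solve_system(build_stacked_system(kept), kept, min_condition_warn)
    return result


def _solve_system(
    system: StackedSystem, poses: PoseSequence, min_condition_warn: float
) -> CalibrationResult:
    A, b = system.design, system.rhs
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= SV_RCOND * s[0]:
        raise DegenerateMotionError(
            "stacked system is rank-deficient: the recorded rotations do not "
            "vary enough to separate the tip offset from the pivot point"
        )
    condition = float(s[0] / s[-1])
    if condition > min_condition_warn:
        warnings.warn(
            f"pivot calibration poorly conditioned (condition number {condition:.3g}); "
            "pivot the tool through a wider range of orientations",
            stacklevel=3,
        )
    x = np.linalg.pinv(A, rcond=SV_RCOND) @ b
    p_offset, p_fix = x[:3], x[3:]
    residual_vectors = (A @ x - b).reshape(-1, 3)
    per_pose = np.linalg.norm(residual_vectors, axis=1)
    return CalibrationResult(
        p_offset=p_offset,
        p_fix=p_fix,
        rms_residual=float(np.sqrt(np.mean(per_pose**2))),
        per_pose_residuals=per_pose,
        condition_number=condition,
        n_poses=len(poses),
    )


def tip_position(pose: Pose, p_offset: np.ndarray) -> np.ndarray:
    """Tip location in the tracker frame for one pose: ``R @ p_offset + t``."""
    p_offset = np.asarray(p_offset, dtype=float)
    if not np.all(np.isfinite(p_offset)):
        raise ValueError("p_offset must be finite")
    return pose.rotation @ p_offset + pose.translation


def calibration_report(result: CalibrationResult) -> str:
    """Human-readable calibration summary."""
    ox, oy, oz = result.p_offset
    fx, fy, fz = result.p_fix
    return (
        "Pivot calibration result\n"
        f"  tip offset (sensor frame): ({ox:.4f}, {oy:.4f}, {oz:.4f}) mm\n"
        f"  tip offset magnitude:      {result.offset_magnitude:.3f} mm\n"
        f"  pivot point (tracker):     ({fx:.4f}, {fy:.4f}, {fz:.4f}) mm\n"
        f"  RMS residual: {result.rms_residual:.3f} mm\n"
        f"  condition number: {result.condition_number:.3g}\n"
        f"  poses used: {result.n_poses}\n"
    )


def result_to_json(result: CalibrationResult) -> str:
    """Serialize a CalibrationResult to the JSON report schema."""
    return json.dumps(
        {
            "p_offset": result.p_offset.tolist(),
            "p_offset_norm_mm": result.offset_magnitude,
            "p_fix": result.p_fix.tolist(),
            "rms_residual_mm": result.rms_residual,
            "per_pose_residuals_mm": result.per_pose_residuals.tolist(),
            "n_poses": result.n_poses,
            "condition_number": result.condition_number,
        },
        indent=2,
    )


def result_from_json(text: str) -> CalibrationResult:
    """Inverse of :func:`result_to_json`."""
    d = json.loads(text)
    return CalibrationResult(
        p_offset=np.asarray(d["p_offset"], dtype=float),
        p_fix=np.asarray(d["p_fix"], dtype=float),
        rms_residual=float(d["rms_residual_mm"]),
        per_pose_residuals=np.asarray(d["per_pose_residuals_mm"], dtype=float),
        condition_number=float(d["condition_number"]),
        n_poses=int(d["n_poses"]),
    )
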