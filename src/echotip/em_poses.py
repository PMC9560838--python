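"""6-DOF electromagnetic tracker poses: parsing, simulation, quaternion algebra.

An electromagnetic (EM) tracking system reports, at each timestamp, the pose of
a small sensor coil relative to a field generator: a unit quaternion ``(q0, qx,
qy, qz)`` (scalar-first) encoding the rotation ``R_i`` and a translation
``t_i`` in millimetres.  Pivot calibration rotates the tracked tool about a
physically fixed tip point; this module provides the pose container, a parser
for text pose logs, and a seeded simulator of pivoting motion whose ground
truth is known by construction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterator, TextIO

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Pose",
    "PoseSequence",
    "PivotTruth",
    "InvalidPoseError",
    "PoseParseError",
    "DegenerateDesignError",
    "normalize_quaternion",
    "quaternion_to_rotation",
    "rotation_to_quaternion",
    "random_rotations",
    "parse_pose_log",
    "serialize_pose_log",
    "simulate_pivot_motion",
]

POSE_LOG_HEADER = "timestamp,q0,qx,qy,qz,tx,ty,tz,status"


class InvalidPoseError(ValueError):
    """A pose is unusable (zero-norm quaternion, non-finite translation)."""


class PoseParseError(ValueError):
    """A pose log line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DegenerateDesignError(ValueError):
    """The requested motion cannot constrain a calibration (too few poses)."""


def normalize_quaternion(q: np.ndarray) -> np.ndarray:
    """Return ``q`` scaled to unit norm with the sign convention ``q0 >= 0``.

    A quaternion and its negation encode the same rotation; fixing the sign of
    the scalar part makes representations comparable.

    Raises
    ------
    InvalidPoseError
        If ``q`` has (numerically) zero norm.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise InvalidPoseError(f"quaternion must be a 4-vector, got shape {q.shape}")
    norm = np.linalg.norm(q)
    if not np.isfinite(norm) or norm < 1e-12:
        raise InvalidPoseError("quaternion has zero or non-finite norm")
    q = q / norm
    if q[0] < 0:
        q = -q
    return q


def quaternion_to_rotation(q: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Convert a scalar-first unit quaternion to a 3x3 rotation matrix.

    Uses the standard homogeneous expansion; the result is orthonormal with
    determinant +1 to machine precision for unit input.

    Raises
    ------
    ValueError
        If ``q`` deviates from unit norm by more than ``atol``.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > atol:
        raise ValueError(f"quaternion norm {norm:.6g} deviates from 1 beyond {atol}")
    w, x, y, z = q / norm
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Recover the scalar-first unit quaternion (``q0 >= 0``) of a rotation matrix.

    Shepperd's method: pick the largest diagonal combination for stability.
    """
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        if i == 0:
            s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2
            q = np.array(
                [(R[2, 1] - R[1, 2]) / s, 0.25 * s, (R[0, 1] + R[1, 0]) / s, (R[0, 2] + R[2, 0]) / s]
            )
        elif i == 1:
            s = np.sqrt(1.0 - R[0, 0] + R[1, 1] - R[2, 2]) * 2
            q = np.array(
                [(R[0, 2] - R[2, 0]) / s, (R[0, 1] + R[1, 0]) / s, 0.25 * s, (R[1, 2] + R[2, 1]) / s]
            )
        else:
            s = np.sqrt(1.0 - R[0, 0] - R[1, 1] + R[2, 2]) * 2
            q = np.array(
                [(R[1, 0] - R[0, 1]) / s, (R[0, 2] + R[2, 0]) / s, (R[1, 2] + R[2, 1]) / s, 0.25 * s]
            )
    return normalize_quaternion(q)


@dataclass
class Pose:
    """One timestamped 6-DOF reading: unit quaternion + translation in mm."""

    timestamp: float
    quaternion: np.ndarray
    translation: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.quaternion = normalize_quaternion(self.quaternion)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.translation.shape != (3,):
            raise InvalidPoseError(
                f"translation must be a 3-vector, got shape {self.translation.shape}"
            )
        if not np.all(np.isfinite(self.translation)):
            raise InvalidPoseError("translation components must be finite")

    @property
    def rotation(self) -> np.ndarray:
        """The 3x3 rotation matrix of this pose."""
        return quaternion_to_rotation(self.quaternion)


@dataclass
class PoseSequence:
    """An ordered run of poses from one tracker coordinate frame."""

    poses: list[Pose] = field(default_factory=list)
    source: str = ""
    frame_id: str = "tracker"

    def __post_init__(self) -> None:
        ts = [p.timestamp for p in self.poses]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("pose timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self) -> Iterator[Pose]:
        return iter(self.poses)

    def __getitem__(self, i: int) -> Pose:
        return self.poses[i]

    def rotations(self) -> np.ndarray:
        """Stack of rotation matrices, shape (N, 3, 3)."""
        return np.stack([p.rotation for p in self.poses])

    def translations(self) -> np.ndarray:
        """Stack of translations in mm, shape (N, 3)."""
        return np.stack([p.translation for p in self.poses])


def parse_pose_log(source: TextIO | str) -> PoseSequence:
    """Parse a tracker pose log in the text dialect written by EM tracking rigs.

    The dialect is CSV with header ``timestamp,q0,qx,qy,qz,tx,ty,tz,status``,
    one record per line, ``status`` in {OK, MISSING}.  Records flagged MISSING
    (sensor out of the field volume) are dropped with a logged count;
    quaternions are normalized on ingest.

    Raises
    ------
    PoseParseError
        On a malformed header or a non-numeric field, with the line number.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = source.read().splitlines()
    if not lines or lines[0].strip().lower() != POSE_LOG_HEADER:
        raise PoseParseError(
            f"expected header {POSE_LOG_HEADER!r}, got {lines[0]!r}" if lines else "empty stream",
            1,
        )
    poses: list[Pose] = []
    n_dropped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 9:
            raise PoseParseError(f"expected 9 fields, got {len(parts)}", lineno)
        status = parts[8].upper()
        if status not in ("OK", "MISSING"):
            raise PoseParseError(f"unknown status {parts[8]!r}", lineno)
        if status == "MISSING":
            n_dropped += 1
            continue
        try:
            values = [float(p) for p in parts[:8]]
        except ValueError as exc:
            raise PoseParseError(f"non-numeric field: {exc}", lineno) from None
        poses.append(
            Pose(
                timestamp=values[0],
                quaternion=np.array(values[1:5]),
                translation=np.array(values[5:8]),
            )
        )
    if n_dropped:
        logger.warning("dropped %d record(s) flagged MISSING", n_dropped)
    return PoseSequence(poses=poses, source=getattr(source, "name", "stream"))


def serialize_pose_log(seq: PoseSequence, stream: TextIO | None = None) -> str:
    """Write a PoseSequence in the pose-log dialect; returns the text."""
    out = [POSE_LOG_HEADER]
    for p in seq:
        q = ",".join(f"{v:.17g}" for v in p.quaternion)
        t = ",".join(f"{v:.17g}" for v in p.translation)
        out.append(f"{p.timestamp:.17g},{q},{t},OK")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` scalar-first quaternions uniform over the rotation group.

    Normalizing a 4-vector of i.i.d. standard normals is uniform on S^3, hence
    uniform over SO(3) after sign-fixing.
    """
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1
    return q


@dataclass
class PivotTruth:
    """Ground truth of a simulated pivoting motion, for recovery tests."""

    true_offset: np.ndarray
    fixed_point: np.ndarray
    noise_sd: float
    seed: int


def simulate_pivot_motion(
    true_offset: np.ndarray,
    fixed_point: np.ndarray,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 40.0,
) -> tuple[PoseSequence, PivotTruth]:
    """Simulate a sensor pivoting about a fixed point, as in pivot calibration.

    Each pose draws a uniformly random rotation ``R_i`` and sets
    ``t_i = fixed_point - R_i @ true_offset + eps_i`` with isotropic Gaussian
    translation noise of standard deviation ``noise_sd`` mm, so that
    ``R_i @ true_offset + t_i = fixed_point`` holds exactly at zero noise.

    Parameters
    ----------
    true_offset : tip position in the sensor's local frame, mm.
    fixed_point : pivot location in the tracker frame, mm.
    n : number of recorded poses (>= 3).
    noise_sd : translation noise standard deviation, mm (>= 0).
    seed : seed for rotations and noise.
    sample_rate_hz : spacing of synthetic timestamps.

    Returns
    -------
    (PoseSequence, PivotTruth)
    """
    if n < 3:
        raise DegenerateDesignError(f"pivot calibration needs >= 3 poses, got {n}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    true_offset = np.asarray(true_offset, dtype=float)
    fixed_point = np.asarray(fixed_point, dtype=float)
    rng = np.random.default_rng(seed)
    quats = random_rotations(n, rng)
    noise = rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else np.zeros((n, 3))
    poses = []
    for i in range(n):
        R = quaternion_to_rotation(quats[i])
        t = fixed_point - R @ true_offset + noise[i]
        poses.append(Pose(timestamp=i / sample_rate_hz, quaternion=quats[i], translation=t))
    seq = PoseSequence(poses=poses, source=f"simulate_pivot_motion(seed={seed})")
    return seq, PivotTruth(true_offset, fixed_point, float(noise_sd), seed)
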