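"""Segmentation evaluation and catheter-tip tracking across frame sequences.

Hard-mask Dice accuracy (the complement of the unsmoothed Dice loss), tip
extraction from a predicted mask (endpoint of the largest connected
component along its principal axis), pixel/mm tip error, and per-sequence
aggregation into a TrackReport with a missing-detection count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .segmentation import TrainConfig, UNet, predict
from .synth import EchoFrame

__all__ = [
    "TrackReport",
    "FrameResult",
    "dice_accuracy",
    "extract_tip",
    "tip_error",
    "track_sequence",
    "evaluate_masks",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def dice_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Hard Dice coefficient ``2|X∩Y| / (|X|+|Y|)``; both-empty counts as 1.

    Equals ``2TP / (2TP + FP + FN)`` on binary masks, and is the complement
    of the unsmoothed Dice loss.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    denom = predicted.sum() + truth.sum()
    if denom == 0:
        return 1.0  # both agree there is no target
    return float(2.0 * np.logical_and(predicted, truth).sum() / denom)


def extract_tip(
    mask: np.ndarray, reference: tuple[float, float] | None = None
) -> tuple[int, int] | None:
    """Locate the catheter tip in a binary mask; ``None`` when the mask is empty.

    The largest 8-connected component (ties broken by topmost-leftmost
    bounding box) is reduced to its two extremal pixels along the principal
    axis of its pixel coordinates.  With a ``reference`` point (e.g. the
    EM-mapped tip) the nearer candidate wins; without one, the candidate
    deeper in the image (larger row) is returned, matching the
    downward-pointing catheter convention of a sector scan.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return None
    labels, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        best_size = sizes.max()
        candidates = [i + 1 for i, s in enumerate(sizes) if s == best_size]
        if len(candidates) > 1:
            slices = ndimage.find_objects(labels)
            candidates.sort(key=lambda lab: (slices[lab - 1][0].start, slices[lab - 1][1].start))
        component = labels == candidates[0]
    else:
        component = mask
    coords = np.column_stack(np.nonzero(component)).astype(float)
    if len(coords) == 1:
        r, c = coords[0]
        return (int(r), int(c))
    centered = coords - coords.mean(axis=0)
    # principal axis = leading eigenvector of the coordinate covariance
    _, vecs = np.linalg.eigh(np.cov(centered.T))
    axis = vecs[:, -1]
    proj = centered @ axis
    cand = [coords[int(np.argmin(proj))], coords[int(np.argmax(proj))]]
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        pick = min(cand, key=lambda p: np.linalg.norm(p - ref))
    else:
        pick = max(cand, key=lambda p: (p[0], p[1]))
    return (int(pick[0]), int(pick[1]))


def tip_error(
    predicted_tip: tuple[float, float] | None,
    gt_tip: tuple[float, float],
    pixel_spacing: float = 1.0,
) -> float | None:
    """Euclidean tip distance scaled to mm; ``None`` propagates a missing tip."""
    if predicted_tip is None:
        return None
    d = np.hypot(predicted_tip[0] - gt_tip[0], predicted_tip[1] - gt_tip[1])
    return float(d * pixel_spacing)


@dataclass
class FrameResult:
    """Per-frame tracking outcome."""

    frame_index: int
    predicted_tip: tuple[int, int] | None
    gt_tip: tuple[int, int]
    dice_accuracy: float
    tip_error_px: float | None
    tip_error_mm: float | None


@dataclass
class TrackReport:
    """Tracking results over a frame sequence with summary statistics."""

    per_frame: list[FrameResult] = field(default_factory=list)
    n_missing: int = 0
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        """Aggregate per-frame entries (no cached-aggregate drift)."""
        dices = [f.dice_accuracy for f in self.per_frame]
        errors = [f.tip_error_mm for f in self.per_frame if f.tip_error_mm is not None]
        self.n_missing = sum(1 for f in self.per_frame if f.predicted_tip is None)
        self.summary = {
            "n_frames": len(self.per_frame),
            "n_missing": self.n_missing,
            "mean_dice": float(np.mean(dices)) if dices else None,
            "max_dice": float(np.max(dices)) if dices else None,
            "min_dice": float(np.min(dices)) if dices else None,
            "mean_tip_error_mm": float(np.mean(errors)) if errors else None,
        }
        return self.summary

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_frame": [
                    {
                        "frame_index": f.frame_index,
                        "predicted_tip": list(f.predicted_tip) if f.predicted_tip else None,
                        "gt_tip": list(f.gt_tip),
                        "dice_accuracy": f.dice_accuracy,
                        "tip_error_px": f.tip_error_px,
                        "tip_error_mm": f.tip_error_mm,
                    }
                    for f in self.per_frame
                ],
                "n_missing": self.n_missing,
                "summary": self.summary,
            },
            indent=2,
        )


def track_sequence(
    model: UNet | None,
    frames: list[EchoFrame],
    config: TrainConfig,
    predicted_masks: list[np.ndarray] | None = None,
) -> TrackReport:
    """Segment and localise the tip in every frame of a sequence.

    Runs ``predict`` + ``extract_tip`` + ``dice_accuracy`` per frame (or
    consumes precomputed ``predicted_masks``), using each frame's
    ground-truth tip as the endpoint-disambiguation reference, and aggregates
    mean/max/min Dice and the missing-detection count.
    """
    if not frames:
        raise ValueError("frame sequence must be non-empty")
    report = TrackReport()
    spacing = frames[0].geometry.pixel_spacing
    for i, frame in enumerate(frames):
        pred = predicted_masks[i] if predicted_masks is not None else predict(model, frame, config)
        tip = extract_tip(pred, reference=frame.tip_pixel)
        err_px = tip_error(tip, frame.tip_pixel, 1.0)
        report.per_frame.append(
            FrameResult(
                frame_index=frame.frame_index,
                predicted_tip=tip,
                gt_tip=tuple(frame.tip_pixel),
                dice_accuracy=dice_accuracy(pred, frame.mask),
                tip_error_px=err_px,
                tip_error_mm=None if err_px is None else err_px * spacing,
            )
        )
    report.recompute_summary()
    return report


def evaluate_masks(pred_dir: str | Path, truth_dir: str | Path) -> dict:
    """Dice accuracy per matching mask file between two directories."""
    import imageio.v3 as iio

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    scores = {}
    for p in sorted(pred_dir.glob("*.png")):
        t = truth_dir / p.name
        if not t.exists():
            continue
        scores[p.name] = dice_accuracy(iio.imread(p) > 0, iio.imread(t) > 0)
    values = list(scores.values())
    return {
        "per_mask": scores,
        "mean_dice": float(np.mean(values)) if values else None,
        "max_dice": float(np.max(values)) if values else None,
        "min_dice": float(np.min(values)) if values else None,
    }
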