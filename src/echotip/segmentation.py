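"""Patch-based 2-D UNet catheter segmentation: sampling, training, prediction.

The pipeline mirrors standard practice for sparse-target ultrasound
segmentation: offline augmentation of the training frames, biased sampling of
fixed-size patches so that most training patches actually contain the thin
catheter target (positive rate 0.95), UNet training under the soft Dice loss
with additive (Laplace) smoothing, early stopping on a fixed validation patch
set, and sliding-window (overlap-averaged) full-frame inference thresholded
into a binary mask.

Default hyperparameters are the full-scale profile: 448x448 single-channel
patches, batch 4, depth-5 UNet, dropout 0.5 at the last layer, up to 30000
iterations with early-stopping patience 6000, 10x offline augmentation.  A
``desk_config`` preset (depth 3, 64x64 patches, <= 1000 iterations) scales
the same pipeline down to CPU-minutes for experimentation and testing.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import Adam, UNet, soft_dice_loss_and_grad
from .synth import EchoFrame, SectorGeometry

__all__ = [
    "TrainConfig",
    "desk_config",
    "PatchSample",
    "LossHistory",
    "NoTargetError",
    "TrainingDivergedError",
    "dice_loss",
    "augment_dataset",
    "sample_patch",
    "build_unet",
    "train",
    "predict",
    "predict_proba",
    "save_model",
    "load_model",
    "load_train_config",
]


class NoTargetError(ValueError):
    """A positive patch was requested from a frame with an empty mask."""


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass
class TrainConfig:
    """Hyperparameters of the segmentation pipeline.

    The defaults are the full-scale profile; ``positive_rate`` is the
    probability that a sampled training patch contains at least one target
    pixel, countering the extreme foreground sparsity of a thin catheter in a
    sector image.  ``smoothing_constant`` is the additive (Laplace) constant
    in the soft Dice ratio.  Optimizer settings (adaptive moments, learning
    rate) and the validation cadence are exposed here as well.
    """

    patch_shape: tuple[int, int, int] = (1, 448, 448)
    batch_size: int = 4
    max_iterations: int = 30000
    unet_depth: int = 5
    base_channels: int = 8
    dropout_rate_last_layer: float = 0.5
    positive_rate: float = 0.95
    augmentation_factor: int = 10
    early_stopping_patience_iterations: int = 6000
    smoothing_constant: float = 1.0
    binarization_threshold: float = 0.5
    learning_rate: float = 1e-3
    validation_interval: int = 100
    validation_patches: int = 16
    augment_flip: bool = True
    augment_rotate: bool = True
    augment_intensity: bool = True
    augment_elastic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_rate <= 1:
            raise ValueError("positive_rate must be in [0, 1]")
        if self.unet_depth < 1:
            raise ValueError("unet_depth must be >= 1")
        if self.smoothing_constant < 0:
            raise ValueError("smoothing_constant must be >= 0")
        self.patch_shape = tuple(self.patch_shape)  # type: ignore[assignment]


def desk_config(**overrides) -> TrainConfig:
    """Desk-scale preset: depth-3 UNet on 64x64 patches, <= 1000 iterations.

    Same pipeline, CPU-minutes instead of GPU-hours; used throughout the test
    suite and the worked examples.
    """
    base = dict(
        patch_shape=(1, 64, 64),
        max_iterations=800,
        unet_depth=3,
        base_channels=8,
        augmentation_factor=4,
        early_stopping_patience_iterations=400,
        validation_interval=50,
    )
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class PatchSample:
    """One extracted training patch and its provenance."""

    image_patch: np.ndarray
    mask_patch: np.ndarray
    is_positive: bool
    source_frame: int
    corner: tuple[int, int]


@dataclass
class LossHistory:
    """Per-iteration training loss and periodic validation loss."""

    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_iterations: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_at: int = 0
    best_iteration: int = 0

    def to_csv(self) -> str:
        """Loss history as CSV text (iteration, split, dice_loss)."""
        buf = io.StringIO()
        buf.write("iteration,split,dice_loss\n")
        for i, v in zip(self.iterations, self.train_loss):
            buf.write(f"{i},train,{v:.17g}\n")
        for i, v in zip(self.val_iterations, self.val_loss):
            buf.write(f"{i},validation,{v:.17g}\n")
        return buf.getvalue()

    def plot(self, path: str | Path) -> None:
        """Write the Dice-loss training curve (for parameter tuning) to a file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.iterations, self.train_loss, lw=0.6, alpha=0.6, label="training")
        ax.plot(self.val_iterations, self.val_loss, "o-", ms=3, label="validation")
        ax.axvline(self.best_iteration, color="k", ls=":", lw=1, label="best iteration")
        ax.set_xlabel("iteration")
        ax.set_ylabel("Dice loss")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def dice_loss(predicted: np.ndarray, target: np.ndarray, smoothing: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s)``.

    ``predicted`` may be a probability map (soft intersection) or a hard
    mask; ``target`` is binary.  With ``smoothing > 0`` the empty-vs-empty
    case is 0 rather than 0/0.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    loss, _ = soft_dice_loss_and_grad(predicted, target, smoothing)
    return float(loss)


# ---------------------------------------------------------------------------
# offline augmentation


def _transform_frame(frame: EchoFrame, rng: np.random.Generator, config: TrainConfig) -> EchoFrame:
    from skimage.transform import rotate

    image = frame.image.astype(np.float64)
    mask = frame.mask.astype(np.float64)
    # point map tracks the tip through the same geometric chain
    tip_map = np.zeros_like(image)
    tip_map[frame.tip_pixel] = 1.0

    if config.augment_flip and rng.random() < 0.5:
        image, mask, tip_map = image[:, ::-1], mask[:, ::-1], tip_map[:, ::-1]
    if config.augment_rotate:
        angle = rng.uniform(-15.0, 15.0)
        image = rotate(image, angle, order=1, preserve_range=True)
        mask = rotate(mask, angle, order=0, preserve_range=True)
        tip_map = rotate(tip_map, angle, order=1, preserve_range=True)
    if config.augment_elastic:
        sigma, alpha = 8.0, 4.0
        dr = ndimage.gaussian_filter(rng.uniform(-1, 1, image.shape), sigma) * alpha
        dc = ndimage.gaussian_filter(rng.uniform(-1, 1, image.shape), sigma) * alpha
        rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        coords = np.array([rr + dr, cc + dc])
        image = ndimage.map_coordinates(image, coords, order=1, mode="constant")
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant")
        tip_map = ndimage.map_coordinates(tip_map, coords, order=1, mode="constant")
    if config.augment_intensity:
        image = image * rng.uniform(0.8, 1.2)

    tip = np.unravel_index(int(np.argmax(tip_map)), tip_map.shape) if tip_map.max() > 0 else frame.tip_pixel
    return EchoFrame(
        image=np.clip(image, 0.0, 1.0).astype(np.float32),
        mask=(mask > 0.5).astype(np.uint8),
        geometry=frame.geometry,
        tip_pixel=(int(tip[0]), int(tip[1])),
        frame_index=frame.frame_index,
        artifact_row=frame.artifact_row,
    )


def augment_dataset(
    frames: list[EchoFrame], factor: int, seed: int, config: TrainConfig | None = None
) -> list[EchoFrame]:
    """Enlarge a dataset ``factor``-fold by seeded offline augmentation.

    The first copy is the identity; the remaining ``factor - 1`` copies apply
    random combinations of horizontal flip, rotation within ±15°, intensity
    scaling within ±20% and a small elastic deformation, with the identical
    geometric transform applied to image and mask (masks re-binarized after
    interpolation).  Individual operations can be switched off via the
    ``augment_*`` flags of ``config``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    config = config or TrainConfig()
    out = list(frames)
    rng = np.random.default_rng(seed)
    for _ in range(factor - 1):
        for frame in frames:
            out.append(_transform_frame(frame, rng, config))
    return out


# ---------------------------------------------------------------------------
# patch sampling


def _pad_to_patch(arr: np.ndarray, ph: int, pw: int) -> np.ndarray:
    h, w = arr.shape
    if h >= ph and w >= pw:
        return arr
    return np.pad(arr, ((0, max(0, ph - h)), (0, max(0, pw - w))))


def sample_patch(
    frame: EchoFrame, config: TrainConfig, rng: np.random.Generator, want_positive: bool | None = None
) -> PatchSample:
    """Draw one training patch, positive with probability ``positive_rate``.

    A positive patch contains at least one catheter pixel.  Positive draws
    use rejection sampling over uniform corners, falling back after 50
    rejections to a corner centred on a random foreground pixel; negative
    draws reject until the patch mask is empty (a fully-foreground frame then
    yields positive patches, reflected in ``is_positive``).

    Raises
    ------
    NoTargetError
        If a positive patch is requested (``want_positive=True``) from a
        frame whose mask is empty.
    """
    _, ph, pw = config.patch_shape
    image = _pad_to_patch(frame.image, ph, pw)
    mask = _pad_to_patch(frame.mask, ph, pw)
    h, w = image.shape
    has_target = bool(frame.mask.any())
    if want_positive is None:
        want_positive = rng.random() < config.positive_rate and has_target
    elif want_positive and not has_target:
        raise NoTargetError("frame mask is empty; no positive patch exists")

    def cut(r: int, c: int) -> PatchSample:
        mp = mask[r : r + ph, c : c + pw]
        return PatchSample(
            image_patch=image[np.newaxis, r : r + ph, c : c + pw],
            mask_patch=mp.astype(np.uint8),
            is_positive=bool(mp.any()),
            source_frame=frame.frame_index,
            corner=(r, c),
        )

    for _ in range(50):
        r = int(rng.integers(0, h - ph + 1))
        c = int(rng.integers(0, w - pw + 1))
        s = cut(r, c)
        if s.is_positive == want_positive:
            return s
    if want_positive:
        fr, fc = np.nonzero(mask)
        k = int(rng.integers(len(fr)))
        r = int(np.clip(fr[k] - ph // 2, 0, h - ph))
        c = int(np.clip(fc[k] - pw // 2, 0, w - pw))
        return cut(r, c)
    return s  # no empty patch found in 50 tries: frame is (nearly) all target


def build_unet(config: TrainConfig) -> UNet:
    """Instantiate the UNet the config describes (untrained, seeded init)."""
    model = UNet(
        depth=config.unet_depth,
        base_channels=config.base_channels,
        in_channels=config.patch_shape[0],
        dropout_rate=config.dropout_rate_last_layer,
        seed=config.seed,
    )
    model.check_input(config.patch_shape)
    return model


# ---------------------------------------------------------------------------
# training


def _batch(samples: list[PatchSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image_patch for s in samples]).astype(np.float32)
    t = np.stack([s.mask_patch[np.newaxis] for s in samples]).astype(np.float32)
    return x, t


def train(
    config: TrainConfig,
    train_frames: list[EchoFrame],
    val_frames: list[EchoFrame],
) -> tuple[UNet, LossHistory]:
    """Train a UNet on sampled patches with early stopping.

    Iterates batches of ``batch_size`` patches drawn from random training
    frames under the positive/negative sampling rule; evaluates the soft Dice
    loss on a fixed seeded validation patch set every
    ``validation_interval`` iterations; stops when validation has not
    improved for ``early_stopping_patience_iterations``; returns the model
    weights from the best validation iteration.  All randomness derives from
    ``config.seed``, so two runs with identical config reproduce identical
    loss histories (single-threaded).

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite.
    """
    if not train_frames or not val_frames:
        raise ValueError("training and validation partitions must be non-empty")
    ss = np.random.SeedSequence(config.seed)
    patch_rng, drop_rng, val_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    model = build_unet(config)
    optimizer = Adam(model.params, lr=config.learning_rate)
    usable = [f for f in train_frames]

    val_samples = [
        sample_patch(f, config, val_rng)
        for f in (val_frames[i % len(val_frames)] for i in range(config.validation_patches))
    ]
    val_x, val_t = _batch(val_samples)

    history = LossHistory()
    best_loss = np.inf
    best_state = model.state_dict()
    best_iter = 0
    for it in range(1, config.max_iterations + 1):
        samples = []
        for _ in range(config.batch_size):
            frame = usable[int(patch_rng.integers(len(usable)))]
            samples.append(sample_patch(frame, config, patch_rng))
        x, t = _batch(samples)
        p, cache = model.forward(x, train=True, drop_rng=drop_rng)
        loss, dp = soft_dice_loss_and_grad(p, t, config.smoothing_constant)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite training loss at iteration {it}")
        grads = model.backward(cache, dp)
        optimizer.step(grads)
        history.iterations.append(it)
        history.train_loss.append(float(loss))

        if it % config.validation_interval == 0:
            vp, _ = model.forward(val_x, train=False)
            vloss, _ = soft_dice_loss_and_grad(vp, val_t, config.smoothing_constant)
            history.val_iterations.append(it)
            history.val_loss.append(float(vloss))
            if vloss < best_loss - 1e-7:
                best_loss, best_iter = float(vloss), it
                best_state = model.state_dict()
            elif it - best_iter >= config.early_stopping_patience_iterations:
                break
    history.stopped_at = history.iterations[-1]
    history.best_iteration = best_iter if best_iter else history.stopped_at
    if best_iter:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# inference


def predict_proba(model: UNet, image: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Full-frame probability map by tiled inference with overlap averaging.

    The frame is zero-padded to at least the patch size, covered by patch-
    sized tiles at half-patch stride, and per-pixel probabilities are
    averaged over all covering tiles before the padding is cropped.
    """
    _, ph, pw = config.patch_shape
    h, w = image.shape
    padded = _pad_to_patch(np.asarray(image, dtype=np.float32), ph, pw)
    hp, wp = padded.shape

    def positions(extent: int, size: int) -> list[int]:
        stride = max(1, size // 2)
        pos = list(range(0, extent - size + 1, stride))
        if pos[-1] != extent - size:
            pos.append(extent - size)
        return pos

    acc = np.zeros(padded.shape, dtype=np.float64)
    cnt = np.zeros(padded.shape, dtype=np.float64)
    tiles = [(r, c) for r in positions(hp, ph) for c in positions(wp, pw)]
    for start in range(0, len(tiles), max(1, config.batch_size)):
        chunk = tiles[start : start + max(1, config.batch_size)]
        x = np.stack([padded[np.newaxis, r : r + ph, c : c + pw] for r, c in chunk])
        p, _ = model.forward(x, train=False)
        for (r, c), pm in zip(chunk, p[:, 0]):
            acc[r : r + ph, c : c + pw] += pm
            cnt[r : r + ph, c : c + pw] += 1.0
    return (acc / cnt)[:h, :w]


def predict(model: UNet, frame: EchoFrame | np.ndarray, config: TrainConfig) -> np.ndarray:
    """Binary predicted mask: tiled probabilities thresholded at the config value."""
    image = frame.image if isinstance(frame, EchoFrame) else np.asarray(frame)
    proba = predict_proba(model, image, config)
    return (proba > config.binarization_threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: UNet, config: TrainConfig, path: str | Path) -> None:
    """Checkpoint: npz of weights with the config embedded as JSON."""
    meta = dict(
        depth=model.depth,
        base_channels=model.base_channels,
        in_channels=model.in_channels,
        dropout_rate=model.dropout_rate,
        config=dataclasses.asdict(config),
    )
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path: str | Path) -> tuple[UNet, TrainConfig]:
    """Inverse of :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = TrainConfig(**meta["config"])
    model = UNet(
        depth=meta["depth"],
        base_channels=meta["base_channels"],
        in_channels=meta["in_channels"],
        dropout_rate=meta["dropout_rate"],
    )
    model.load_state_dict(state)
    return model, config


def load_train_config(path: str | Path) -> TrainConfig:
    """Read a TrainConfig from a YAML file mirroring the field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return TrainConfig(**raw)
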