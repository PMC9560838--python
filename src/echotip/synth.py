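"""Synthetic 2-D echocardiography frames with ground-truth catheter masks.

Emulates water-tank phantom transoesophageal echo: a fan-shaped (sector)
field of view filled with multiplicative speckle, a few low-contrast
elliptical "cardiac structure" blobs, a thin bright curvilinear catheter whose
distal end is the tip of interest, and a horizontal reverberation band (a
water-tank artifact) that is visible in the image but deliberately excluded
from the ground-truth label, matching how such artifacts are left unlabelled
when annotating real phantom data.

Also maps a 3-D tracked tip position (tracker frame, mm) into image pixel
coordinates through a user-supplied rigid transform plus an image-plane
(slice-thickness) tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .em_poses import quaternion_to_rotation

__all__ = [
    "SectorGeometry",
    "SceneConfig",
    "EchoFrame",
    "PlaneTransform",
    "MappedTip",
    "PlacementError",
    "make_sector_mask",
    "render_frame",
    "simulate_sequence",
    "map_tip_to_image",
    "pixel_to_plane_mm",
    "plane_mm_to_pixel",
    "write_dataset",
    "read_dataset",
    "export_dicom",
]


class PlacementError(ValueError):
    """Requested catheter tip lies outside the imaging sector."""


@dataclass
class SectorGeometry:
    """Fan-shaped field of view of a phased-array probe, in pixel units.

    The sector axis points down the image (increasing row) from the apex; a
    pixel is inside the sector iff its polar radius about the apex lies in
    ``[min_depth, max_depth]`` and its bearing from the axis is within
    ``±opening_angle/2``.  ``pixel_spacing`` converts pixels to mm
    (isotropic).
    """

    image_height: int = 256
    image_width: int = 256
    apex: tuple[int, int] = (10, 128)
    opening_angle: float = 75.0
    min_depth: float = 20.0
    max_depth: float = 235.0
    pixel_spacing: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.opening_angle < 180:
            raise ValueError("opening_angle must be in (0, 180) degrees")
        if not 0 <= self.min_depth < self.max_depth:
            raise ValueError("need 0 <= min_depth < max_depth")
        if self.max_depth > self.image_height + self.image_width:
            raise ValueError("max_depth far exceeds image extent")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


@dataclass
class SceneConfig:
    """Appearance parameters of one synthetic phantom scene.

    ``speckle_scale`` is the mean background intensity inside the sector
    (fully developed speckle has unit-mean multiplicative texture, so the
    scale survives smoothing).  ``catheter_curvature`` bends the quadratic
    Bézier ribbon; 0 gives a straight segment.  The reverberation artifact is
    a horizontal band of the stated peak intensity, never labelled.
    """

    catheter_length: float = 90.0
    catheter_width: float = 5.0
    catheter_intensity: float = 0.9
    catheter_curvature: float = 0.15
    artifact_intensity: float = 0.55
    speckle_scale: float = 0.22
    background_structures: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.catheter_width < 1:
            raise ValueError("catheter_width must be >= 1 pixel")
        for name in ("catheter_intensity", "artifact_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class EchoFrame:
    """One grayscale echo-like frame with its binary catheter mask.

    ``tip_pixel`` is the ground-truth (row, col) of the catheter tip;
    ``artifact_row`` records where the reverberation band was drawn (metadata
    for analysis only — the band is not in the mask).
    """

    image: np.ndarray
    mask: np.ndarray
    geometry: SectorGeometry
    tip_pixel: tuple[int, int]
    frame_index: int = 0
    artifact_row: int | None = None


def make_sector_mask(geometry: SectorGeometry) -> np.ndarray:
    """Boolean image of the sector region defined by ``geometry``."""
    rows = np.arange(geometry.image_height)[:, None] - geometry.apex[0]
    cols = np.arange(geometry.image_width)[None, :] - geometry.apex[1]
    radius = np.hypot(rows, cols)
    # bearing measured from the downward axis
    bearing = np.degrees(np.arctan2(np.abs(cols), rows))
    return (
        (radius >= geometry.min_depth)
        & (radius <= geometry.max_depth)
        & (bearing <= geometry.opening_angle / 2)
    )


def _catheter_polyline(
    tip: tuple[float, float], tip_angle: float, length: float, curvature: float
) -> np.ndarray:
    """Dense (row, col) samples of a quadratic Bézier ending at the tip.

    ``tip_angle`` is the direction, in degrees clockwise from image-up, in
    which the catheter shaft leaves the tip (0 = shaft extends straight up
    toward the apex, matching the vertical appearance of a catheter in a
    sector scan).
    """
    a = np.radians(tip_angle)
    # unit vector from tip back along the shaft, in (row, col) coordinates
    u = np.array([-np.cos(a), np.sin(a)])
    n = np.array([-u[1], u[0]])  # perpendicular
    p2 = np.asarray(tip, dtype=float)
    p0 = p2 + length * u
    p1 = 0.5 * (p0 + p2) + curvature * length * n
    t = np.linspace(0.0, 1.0, max(64, int(4 * length)))[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _scene_layout(scene: SceneConfig, geometry: SectorGeometry, rng: np.random.Generator):
    """Draw the static parts of a scene: ellipse blobs and the artifact row."""
    sector = make_sector_mask(geometry)
    in_rows, in_cols = np.nonzero(sector)
    ellipses = []
    for _ in range(scene.background_structures):
        k = rng.integers(len(in_rows))
        ellipses.append(
            dict(
                center=(float(in_rows[k]), float(in_cols[k])),
                axes=(float(rng.uniform(8, 35)), float(rng.uniform(8, 35))),
                angle=float(rng.uniform(0, 180)),
                delta=float(rng.uniform(-0.10, 0.18)),
            )
        )
    lo = int(np.percentile(in_rows, 25))
    hi = int(np.percentile(in_rows, 85))
    artifact_row = int(rng.integers(lo, hi + 1))
    return ellipses, artifact_row


def _render_ellipses(shape: tuple[int, int], ellipses: list[dict]) -> np.ndarray:
    out = np.zeros(shape)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for e in ellipses:
        cr, ccol = e["center"]
        a, b = e["axes"]
        th = np.radians(e["angle"])
        dr, dc = rr - cr, cc - ccol
        x = dr * np.cos(th) + dc * np.sin(th)
        y = -dr * np.sin(th) + dc * np.cos(th)
        q = (x / a) ** 2 + (y / b) ** 2
        out += e["delta"] * np.clip(1.5 * (1 - q), 0.0, 1.0)  # soft-edged footprint
    return out


def render_frame(
    scene: SceneConfig,
    geometry: SectorGeometry,
    tip_position: tuple[float, float],
    tip_angle: float = 0.0,
    frame_index: int = 0,
    rng: np.random.Generator | None = None,
    layout: tuple | None = None,
) -> EchoFrame:
    """Render one frame: speckle + blobs + catheter ribbon + artifact band.

    The mask covers only the catheter ribbon; the artifact band is drawn in
    the image but never labelled.  With the default ``rng=None`` the frame is
    a pure function of ``scene.seed``.

    Raises
    ------
    PlacementError
        If ``tip_position`` falls outside the sector.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    sector = make_sector_mask(geometry)
    tr, tc = int(round(tip_position[0])), int(round(tip_position[1]))
    if not (0 <= tr < geometry.image_height and 0 <= tc < geometry.image_width) or not sector[
        tr, tc
    ]:
        raise PlacementError(f"tip {tip_position} lies outside the imaging sector")
    if layout is None:
        layout = _scene_layout(scene, geometry, rng)
    ellipses, artifact_row = layout
    shape = (geometry.image_height, geometry.image_width)

    # fully developed speckle: unit-mean exponential texture, lightly smoothed
    speckle = ndimage.gaussian_filter(rng.exponential(1.0, size=shape), sigma=1.0)
    image = scene.speckle_scale * speckle
    image += _render_ellipses(shape, ellipses)

    # reverberation band: horizontal, a few pixels tall, bright, unlabelled
    rows = np.arange(shape[0])[:, None]
    band = np.exp(-0.5 * ((rows - artifact_row) / 2.5) ** 2)
    image += scene.artifact_intensity * band * np.ones(shape)

    # catheter ribbon: distance to a dense Bézier polyline, anti-aliased edge
    mask = np.zeros(shape, dtype=np.uint8)
    if scene.catheter_intensity > 0:
        pts = _catheter_polyline(tip_position, tip_angle, scene.catheter_length, scene.catheter_curvature)
        half = scene.catheter_width / 2.0
        pad = int(np.ceil(half)) + 2
        r0 = max(0, int(pts[:, 0].min()) - pad)
        r1 = min(shape[0], int(pts[:, 0].max()) + pad + 1)
        c0 = max(0, int(pts[:, 1].min()) - pad)
        c1 = min(shape[1], int(pts[:, 1].max()) + pad + 1)
        if r1 > r0 and c1 > c0:
            grid_r, grid_c = np.mgrid[r0:r1, c0:c1]
            pix = np.column_stack([grid_r.ravel(), grid_c.ravel()]).astype(float)
            dist, _ = cKDTree(pts).query(pix, k=1)
            dist = dist.reshape(grid_r.shape)
            alpha = np.clip(half + 0.5 - dist, 0.0, 1.0)
            sub = image[r0:r1, c0:c1]
            image[r0:r1, c0:c1] = np.maximum(sub, scene.catheter_intensity * alpha)
            mask[r0:r1, c0:c1] = (dist <= half).astype(np.uint8)
    mask &= sector.astype(np.uint8)
    image = np.clip(image, 0.0, 1.0) * sector
    return EchoFrame(
        image=image.astype(np.float32),
        mask=mask,
        geometry=geometry,
        tip_pixel=(tr, tc),
        frame_index=frame_index,
        artifact_row=artifact_row,
    )


def simulate_sequence(
    scene: SceneConfig,
    geometry: SectorGeometry,
    motion: list[tuple[tuple[float, float], float]],
    frame_rate: float = 10.0,
) -> list[EchoFrame]:
    """Render a frame per motion entry ``((row, col), tip_angle_deg)``.

    Background structures and the artifact band stay fixed across the
    sequence; speckle is redrawn each frame (temporally incoherent), all
    seeded from ``scene.seed``.  ``frame_rate`` sets the implied cadence
    (default 10 Hz, i.e. 0.1 s between frames).
    """
    if not motion:
        raise ValueError("motion list must be non-empty")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    ss = np.random.SeedSequence(scene.seed)
    layout_rng = np.random.default_rng(ss.spawn(1)[0])
    layout = _scene_layout(scene, geometry, layout_rng)
    frames = []
    for i, ((row, col), angle) in enumerate(motion):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1, i)))
        frames.append(
            render_frame(scene, geometry, (row, col), angle, frame_index=i, rng=rng, layout=layout)
        )
    return frames


def make_study_frames(
    n_frames: int = 40, seed: int = 7, geometry: SectorGeometry | None = None
) -> list[EchoFrame]:
    """Independent phantom-style frames with varied catheter pose per frame.

    The standard study dataset: each frame draws its own speckle, background
    layout, catheter curvature, tip position (mid-sector) and shaft angle,
    all derived from ``seed``.
    """
    geometry = geometry or SectorGeometry()
    sector = make_sector_mask(geometry)
    rows, cols = np.nonzero(sector)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        scene = SceneConfig(
            seed=int(rng.integers(2**31)),
            catheter_curvature=float(rng.uniform(-0.25, 0.25)),
        )
        while True:
            k = int(rng.integers(len(rows)))
            r, c = int(rows[k]), int(cols[k])
            if 90 < r < 220 and 40 < c < 215:
                break
        frames.append(
            render_frame(scene, geometry, (r, c), float(rng.uniform(-20, 20)), frame_index=i)
        )
    return frames


def make_study_sequence(
    n_frames: int = 10,
    seed: int = 11,
    geometry: SectorGeometry | None = None,
    frame_rate: float = 10.0,
) -> list[EchoFrame]:
    """A moving-catheter sequence at 0.1 s cadence (default 10 frames = 1 s).

    One scene (fixed background and artifact), linearly translating tip with
    a slowly drifting shaft angle, speckle redrawn per frame.
    """
    geometry = geometry or SectorGeometry()
    rng = np.random.default_rng(seed)
    scene = SceneConfig(seed=seed, catheter_curvature=float(rng.uniform(-0.2, 0.2)))
    start = np.array([130.0, 100.0]) + rng.uniform(-15, 15, size=2)
    step = rng.uniform(-3.5, 3.5, size=2)
    angle0 = float(rng.uniform(-15, 15))
    motion = [
        (
            (float(start[0] + i * step[0]), float(start[1] + i * step[1])),
            angle0 + 0.5 * i,
        )
        for i in range(n_frames)
    ]
    return simulate_sequence(scene, geometry, motion, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# tracked-tip to image-pixel mapping


@dataclass
class PlaneTransform:
    """Rigid map from tracker frame (mm) into the image-plane frame (mm).

    In the image-plane frame, x is lateral (columns), y is depth (rows), both
    measured from the sector apex, and z is elevation out of the imaging
    plane.  The transform is ``p_plane = R @ p_tracker + t`` with ``R`` given
    as a scalar-first quaternion.
    """

    quaternion: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_thickness_mm: float = 2.0

    @property
    def rotation(self) -> np.ndarray:
        return quaternion_to_rotation(np.asarray(self.quaternion, dtype=float))


@dataclass
class MappedTip:
    """Result of projecting a tracked 3-D tip into the image."""

    row: float
    col: float
    offplane_mm: float
    in_plane: bool
    in_sector: bool

    @property
    def pixel(self) -> tuple[int, int]:
        return (int(round(self.row)), int(round(self.col)))


def pixel_to_plane_mm(geometry: SectorGeometry, pixel: tuple[float, float]) -> np.ndarray:
    """(row, col) pixel -> (x_lateral, y_depth) mm about the apex."""
    return np.array(
        [
            (pixel[1] - geometry.apex[1]) * geometry.pixel_spacing,
            (pixel[0] - geometry.apex[0]) * geometry.pixel_spacing,
        ]
    )


def plane_mm_to_pixel(geometry: SectorGeometry, xy_mm: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_plane_mm`."""
    return (
        geometry.apex[0] + xy_mm[1] / geometry.pixel_spacing,
        geometry.apex[1] + xy_mm[0] / geometry.pixel_spacing,
    )


def map_tip_to_image(
    tip_tracker: np.ndarray,
    tracker_to_image: PlaneTransform,
    geometry: SectorGeometry,
) -> MappedTip:
    """Project a tracked tip (tracker frame, mm) to image pixel coordinates.

    The tip is first moved into the image-plane frame by the rigid transform;
    if its elevation |z| exceeds the slice-thickness tolerance it is flagged
    out-of-plane.  In-plane points are converted to (row, col) through the
    isotropic pixel spacing; points landing outside the sector keep their
    coordinate but are flagged.
    """
    p = tracker_to_image.rotation @ np.asarray(tip_tracker, dtype=float) + np.asarray(
        tracker_to_image.translation
    )
    row, col = plane_mm_to_pixel(geometry, p[:2])
    in_plane = abs(p[2]) <= tracker_to_image.slice_thickness_mm
    sector = make_sector_mask(geometry)
    r, c = int(round(row)), int(round(col))
    in_sector = 0 <= r < geometry.image_height and 0 <= c < geometry.image_width and bool(sector[r, c])
    return MappedTip(row=row, col=col, offplane_mm=float(p[2]), in_plane=in_plane, in_sector=in_sector)


# ---------------------------------------------------------------------------
# dataset persistence: 16-bit PNG frames, binary PNG masks, JSON metadata


def write_dataset(frames: list[EchoFrame], out_dir: str | Path) -> None:
    """Write frames as ``frames/NNNN.png`` (16-bit), masks and meta.json."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    meta = {"geometry": asdict(frames[0].geometry), "frames": []}
    for f in frames:
        name = f"{f.frame_index:04d}.png"
        iio.imwrite(out / "frames" / name, np.round(f.image.astype(np.float64) * 65535).astype(np.uint16))
        iio.imwrite(out / "masks" / name, (f.mask * 255).astype(np.uint8))
        meta["frames"].append(
            {
                "index": f.frame_index,
                "tip_pixel": list(f.tip_pixel),
                "artifact_row": f.artifact_row,
            }
        )
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(in_dir: str | Path) -> list[EchoFrame]:
    """Inverse of :func:`write_dataset` (images come back 16-bit quantized)."""
    import imageio.v3 as iio

    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    geometry = SectorGeometry(**{**meta["geometry"], "apex": tuple(meta["geometry"]["apex"])})
    frames = []
    for entry in meta["frames"]:
        name = f"{entry['index']:04d}.png"
        image = iio.imread(src / "frames" / name).astype(np.float32) / 65535.0
        mask = (iio.imread(src / "masks" / name) > 0).astype(np.uint8)
        frames.append(
            EchoFrame(
                image=image,
                mask=mask,
                geometry=geometry,
                tip_pixel=tuple(entry["tip_pixel"]),
                frame_index=entry["index"],
                artifact_row=entry.get("artifact_row"),
            )
        )
    return frames


def export_dicom(frame: EchoFrame, path: str | Path) -> None:
    """Export one frame as a DICOM secondary-capture grayscale image."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.Rows, ds.Columns = frame.image.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [frame.geometry.pixel_spacing, frame.geometry.pixel_spacing]
    ds.InstanceNumber = frame.frame_index + 1
    ds.PixelData = np.round(frame.image.astype(np.float64) * 65535).astype("<u2").tobytes()
    pydicom.dcmwrite(path, ds)
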