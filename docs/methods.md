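# Methods

This note documents the models, parameter choices and numerical decisions
behind `echotip`, and what the synthetic experiments do and do not show.

## Pivot calibration

### Model

A 6-DOF EM sensor rigidly attached to a catheter reports poses (Rᵢ, tᵢ):
Rᵢ a rotation given as a scalar-first unit quaternion (q0, qx, qy, qz),
tᵢ a translation in mm. Pivoting the tool about a physically fixed tip
point gives Rᵢ·p_offset + tᵢ = p_fix for every pose. The solver stacks the
N constraints into a 3N×6 linear system with rows [Rᵢ | −I] and right-hand
side −tᵢ and solves for (p_offset, p_fix) jointly.

Assumptions: the tip is rigidly fixed during the recording; the tracker's
noise is dominated by translation jitter (the simulator models isotropic
Gaussian translation noise only); no magnetic-field distortion.

### Numerics

- The pseudo-inverse is computed by SVD with a relative singular-value
  cutoff of 1e-10. On well-conditioned systems it agrees with a
  normal-equations solve to better than 1e-8 (tested).
- Rank deficiency — all rotations identical, e.g. a tool held still —
  raises `DegenerateMotionError`. A minimum-norm answer in that situation
  would be clinically meaningless, so it is never returned silently.
- The condition number (ratio of extreme singular values) is reported and
  a warning is emitted above 1e6 (poorly excited motion).
- The per-pose residual is ‖Rᵢ·p_offset + tᵢ − p_fix‖ in mm; the headline
  scalar is its RMS. Both the RMS residual and the recovered-offset error
  are exposed, since "calibration error" can reasonably mean either.
- Optional trimming of the worst 5% residual poses (off by default) guards
  against isolated corrupt records; plain least squares is the reference
  behaviour.

The simulator draws rotations uniformly over SO(3) (normalized Gaussian
quaternions), which conditions the system far better than typical manual
pivoting; real hand-pivoted recordings will sit closer to the warning
threshold.

### Pose logs

Logs are CSV with header `timestamp,q0,qx,qy,qz,tx,ty,tz,status`, one
record per line, status OK or MISSING. MISSING records (sensor out of the
field volume) are dropped with a logged count rather than interpolated —
calibration needs only valid poses and interpolation would fabricate data.
Quaternions are normalized on ingest with the sign convention q0 ≥ 0.

## Synthetic phantom echo

The generator emulates water-tank phantom transoesophageal imaging of an
ablation catheter: a fan-shaped sector about an apex, fully developed
speckle, a few low-contrast elliptical blobs standing in for cardiac
structures, a thin bright curvilinear catheter, and a horizontal
reverberation band (tank-wall echo) that is rendered but never labelled —
the label covers the catheter ribbon only.

Defaults (one 256×256 frame, 0.3 mm/px isotropic):

| parameter | default | rationale |
|---|---|---|
| opening angle | 75° | phased-array sector width |
| speckle_scale | 0.22 | mean background intensity inside the sector |
| catheter width | 5 px | ≈1.5 mm: the bright core of a catheter shaft at 0.3 mm/px |
| catheter length | 90 px | shaft segment visible in the sector |
| catheter intensity | 0.9 | strongly echogenic against 0.22 background |
| artifact intensity | 0.55 | bright but below the catheter |
| curvature | 0.15 | gentle bend; 0 gives a straight segment |

Speckle is modelled as unit-mean exponential (fully developed amplitude
speckle) texture lightly smoothed by a Gaussian (σ = 1 px) and scaled, so
the configured level survives as the background mean (tested within 10%,
with positive skewness). The catheter is a quadratic Bézier ribbon
rasterized by distance-to-polyline with a 0.5 px anti-aliased edge; the
mask is the hard ≤ width/2 region. Sequences keep the background layout
and artifact row fixed and redraw speckle every frame (temporally
incoherent), at a default cadence of 10 frames/s.

What this does **not** emulate: beamforming and point-spread anisotropy,
depth-dependent attenuation and TGC, anatomically shaped chambers, probe
motion, and shadowing. Passing tests on this generator therefore show that
the pipeline learns thin bright curvilinear targets against speckle and
ignores a band artifact — not that it reaches any particular accuracy on
clinical TOE data, where reported Dice accuracies for this task are
substantially lower.

### Mapping a tracked tip into the image

The tracked 3-D tip is mapped through a user-supplied rigid transform into
an image-plane frame (x lateral, y depth, z elevation), flagged
out-of-plane when |z| exceeds a slice-thickness tolerance (default 2 mm,
half a typical elevation beamwidth), and converted to (row, col) through
the isotropic pixel spacing. Probe spatial calibration (estimating that
transform) is deliberately out of scope; the transform is configuration.
Image coordinates are 0-based (row, col) with row increasing downward.

## Segmentation pipeline

Full-scale defaults: patches 1×448×448, batch 4, up to 30000 iterations,
UNet depth 5, dropout 0.5 at the last layer, early-stopping patience 6000
iterations, positive-patch rate 0.95, 10× offline augmentation, Dice loss
with additive smoothing constant 1.0, ReLU activations, binarization
threshold 0.5.

Interpretations fixed where the convention is ambiguous:

- "positive rate 0.95" is the probability that a sampled patch contains at
  least one target pixel (per-patch, not per-slice); rejection sampling
  over corners with a fallback that centres on a random foreground pixel
  after 50 rejections.
- Iterations count batches, not samples.
- The smoothing constant is 1.0 added to numerator and denominator of the
  soft Dice ratio (the conventional smooth-Dice formulation); soft Dice is
  used for training, hard Dice for evaluation.
- Unstated optimizer settings are ecosystem defaults, config-exposed:
  adaptive moments (Adam), learning rate 1e-3, validation every 100
  iterations on a fixed seeded patch set.
- Augmentation ops: horizontal flip, rotation ±15°, intensity scaling
  ±20%, small elastic deformation (σ = 8 px, α = 4 px); image and mask get
  the identical geometric transform, masks re-binarized, each op
  individually switchable. The first copy of the dataset is the identity.

### Desk-scale profile

`desk_config()` scales the same pipeline to CPU-minutes: depth 3, 64×64
patches, base width 8 channels, 800 iterations, patience 400, validation
every 50 iterations, 4× augmentation. The study dataset is 40 generated
frames (24 train / 8 validation / 8 held-out test) with per-frame random
tip position, shaft angle and curvature. On one CPU this trains in about
two minutes and reaches held-out hard Dice ≈ 0.95; the numbers quoted in
the repository are always produced by running it, not stored.

### numpy CNN engine

No tensor/autodiff framework is used: `_nn.py` implements 3×3 same-padding
convolution (nine shifted tensor contractions), 2×2 max pooling,
nearest-neighbour upsampling, channel concatenation, inverted dropout, a
1×1 sigmoid head, the soft-Dice gradient, and Adam, each with a
hand-written backward pass. Correctness is enforced by finite-difference
gradient tests at depths 1–3. One subtlety: gradient checks must avoid
parameters sitting exactly on ReLU kinks (zero-initialized biases with
all-zero receptive fields produce pre-activations of exactly 0, where the
subgradient is ambiguous); the tests randomize biases before checking.

Training is single-threaded-deterministic: all randomness (patch choice,
dropout, validation set) derives from the config seed, and two identical
runs produce bit-identical loss histories.

### Inference

Full frames are covered by patch-sized tiles at half-patch stride with
per-pixel probability averaging, then thresholded. Inputs smaller than a
patch are zero-padded and cropped back.

## Evaluation and tracking

- Hard Dice accuracy with both-empty defined as 1.0 (predictor and truth
  agree there is no target).
- Tip extraction: largest 8-connected component (ties broken by
  topmost-leftmost bounding box), principal axis from the eigenvectors of
  the pixel-coordinate covariance, the two extremal pixels along it as
  candidates; a reference point (e.g. the EM-mapped tip) selects the
  nearer candidate, otherwise the deeper (larger-row) endpoint is taken,
  matching a downward-pointing catheter in a sector scan.
- Tip error is Euclidean distance in px and, via pixel spacing, mm. On the
  synthetic sequences the mean tip error (~2–2.5 px) is dominated by the
  rendered ribbon's rounded end-cap: the extremal mask pixel sits up to
  half a catheter width beyond the nominal tip point. No temporal
  smoothing (Kalman or otherwise) is applied.

## Known limitations

- The generator's realism gap (above) means measured Dice here
  overestimates clinical performance by design of the phantom, not of the
  method.
- The numpy engine is CPU-bound; the full-scale 448×448 depth-5 profile is
  provided for completeness but is impractical without hours of CPU time.
- Probe calibration, temporal (latency) calibration, multi-catheter
  scenes, and standard-view classification are out of scope.
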