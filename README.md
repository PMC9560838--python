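# echotip

Hybrid catheter-tip localisation in 2-D echocardiography: electromagnetic
(EM) pivot calibration to pin down the physical tip of a tracked catheter,
and a patch-based UNet segmentation pipeline to find the catheter in
low-contrast ultrasound frames — plus a synthetic phantom-echo generator and
tracking utilities that join the two halves.

## Who this is for

Researchers and engineers building image-guided cardiac intervention tools:
you have (or simulate) 6-DOF EM tracker pose logs and 2-D echo frames of a
catheter in a phantom, and you want a reproducible pipeline from raw pose
log to calibrated tip offset, and from echo frames to per-frame catheter
masks and tip coordinates.

## The two core computations

**Pivot calibration.** Rotating a tracked tool about a physically fixed tip
gives, for each recorded pose (Rᵢ, tᵢ), the constraint

    Rᵢ · p_offset + tᵢ = p_fix

where `p_offset` is the tip in the sensor's local frame and `p_fix` the
fixed pivot in the tracker frame. Stacking all N poses as rows `[Rᵢ | −I]`
against right-hand sides `−tᵢ` yields an over-determined 3N×6 system solved
by SVD pseudo-inverse; the RMS of the per-pose constraint mismatch is the
calibration residual. Degenerate motion (rotations that do not vary) raises
an error instead of returning a meaningless minimum-norm answer.

**Dice-trained UNet segmentation.** Single-channel patches are sampled so
that a patch contains the sparse catheter target with probability 0.95;
an encoder–decoder UNet (channel doubling per level, ReLU, dropout 0.5
before the sigmoid output) is trained with the smoothed soft Dice loss

    L = 1 − (2·Σ p·t + s) / (Σ p + Σ t + s)

with early stopping on a fixed validation patch set. Evaluation uses hard
Dice accuracy 2|X∩Y|/(|X|+|Y|) = 2TP/(2TP+FP+FN), and a tip is extracted
from each predicted mask as the principal-axis endpoint of the largest
connected component.

The UNet and its training loop are implemented as a compact numpy CNN engine
(`echotip/_nn.py`) with hand-written backward passes, validated against
finite differences in the test suite; no GPU is needed at desk scale.

## Worked example

```python
import numpy as np
from echotip import simulate_pivot_motion, solve_pivot, calibration_report

seq, truth = simulate_pivot_motion(
    true_offset=(3.0, 2.0, 3.0), fixed_point=(5.0, -10.0, -40.0),
    n=100, noise_sd=0.1, seed=1,
)
print(calibration_report(solve_pivot(seq)))
```

prints

```
Pivot calibration result
  tip offset (sensor frame): (2.9844, 1.9967, 2.9800) mm
  tip offset magnitude:      4.666 mm
  pivot point (tracker):     (5.0108, -10.0178, -39.9931) mm
  RMS residual: 0.177 mm
  condition number: 1.1
  poses used: 100
```

With 0.1 mm translation noise on 100 poses the solver recovers the ~4.7 mm
tip offset to within ~0.02 mm; at zero noise recovery is exact to machine
precision. The segmentation half runs the same way from Python or the CLI:

```
echotip simulate --out data/ --frames 40 --seed 7
echotip train --desk --data data/ --out model.npz
echotip track --ckpt model.npz --frames data/ --out report.json
```

`track` reports per-frame Dice accuracy, tip coordinates, tip error in px
and mm, and the count of frames with no detection.

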