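# prostseg

A toolkit for studying automatic segmentation of the prostate in T2-weighted
MRI. It packages, in one place, everything a segmentation benchmark of this
kind needs: the preprocessing protocol, four convolutional segmentation
architectures with their exact training recipe, the four evaluation scores
with slice-wise surface conventions, the nonparametric statistics used to
compare models, and a synthetic phantom generator so the entire pipeline runs
end-to-end without any patient data.

**Who it is for.** Medical-imaging researchers who want to reproduce or
extend prostate auto-contouring comparisons, and developers who need a
dependency-light reference implementation of the metrics and training
recipe. The networks run on a self-contained numpy autograd backend, so the
package needs no GPU framework; desk-scale configurations train in seconds
to minutes on one CPU.

## The models

Four encoder–decoder architectures, built as configurable graphs:

- **V-net** — 3D residual encoder–decoder. Residual blocks compute
  `ResConv(x) = PReLU(Dropout(BatchNorm(Conv3D(x)))) + x`; strided 3×3×3
  convolutions downsample, transposed convolutions upsample, skips are
  concatenations, and every level adds another 48 filters (48, 96, 144, …).
  Element-wise dropout (rate 0.5) is applied in the encoder only.
- **Transfer-style U-net** — a slice-wise EfficientNetB0 encoder behind a
  3×3×3 adapter convolution and a 224×224 centre crop, with a U-net decoder
  using filters {360, 288, 216, 144, 72} (levels P7…P3) and 4×4 kernels,
  zero-padded back onto the original grid. Pretrained 2D encoder weights can
  be injected; seeded random initialization is the default.
- **GAN** — the same generator plus a pair discriminator: ground-truth and
  generated masks concatenated, strided 4×4×4 convolution blocks (no batch
  norm in the first), a dense linear score, trained with relativistic losses
  `L_D = −log σ(D(x) − D(x̂))`, `L_G = −log σ(D(x̂) − D(x))` and a soft Dice
  term weighted 5:1 in favour of Dice.
- **EfficientDet3D** — a 3D EfficientNet backbone (MBConv expansion 2.0,
  N×N×3 kernels, level channels {32, 24, 48, 48, 64, 80, 96}) with a single
  top-down pass of fast normalized fusion
  `O = Σᵢ ReLU(ωᵢ)/(ε + Σⱼ ωⱼ) · Iᵢ` over levels projected to 48 channels,
  nearest-neighbour upscaling with 3×3×1 anti-aliasing convolutions, and a
  1×1×1 sigmoid head.

Training uses the top-k pixel loss `ℓ = −log(1 − |y − ŷ|)` averaged over the
k = 5% most poorly segmented pixels (k = 143,360 on the clinical
320×320×28 grid), mixup-compatible because targets may be soft, with Adam
and a plateau-annealed learning rate 0.001 → 0.0005 → 0.0001. The
augmentation chain is mixup (λ ~ Beta(0.5, 0.5)), horizontal flips,
rotations in [−π/4, π/4] about the depth axis, random resize (scale in
[0.7, 1.3]) and translation, and a fast elastic deformation (α = 2000,
β = 1/4, σ = 50).

## The metrics

For prediction A and ground truth B on a shared grid:

- Dice = 2|A∩B| / (|A|+|B|)
- ARVD = |V_A − V_B| / V_B
- MSD = (Σ_{a∈A_s} d(a, B_s) + Σ_{b∈B_s} d(b, A_s)) / (|A_s|+|B_s|), pooled
  over axial slices, in pixels
- HD95 = max of the directed 95th-percentile surface distances, per slice,
  averaged over slices, in pixels

MSD and HD95 are computed in 2D because contours are drawn slice by slice on
strongly anisotropic voxels; a slice where exactly one contour is empty uses
a single pixel at the image centre as that contour.

## Worked example

```python
import numpy as np
from prostseg.phantom import PhantomConfig, generate_phantom, degrade_mask
from prostseg.metrics import score_patient
from prostseg.io_preprocess import znormalize
from prostseg.augment import TrainingSample
from prostseg.models import desk_config, build_model
from prostseg.train import TrainConfig, train_model, predict_mask

cfg = PhantomConfig(grid_shape=(32, 32, 8), spacing=(2.4, 2.4, 6.6),
                    radii_range_mm=(14, 24), seed=3)
scan = generate_phantom(cfg)
print(f"phantom volume: {scan.true_volume_ml:.1f} ml "
      f"({scan.mask.voxel_count} voxels)")

sloppy = degrade_mask(scan.mask, "dilate", 1)
rec = score_patient(sloppy, scan.mask, "P000")
print(f"dilated prediction: dice={rec.dice:.3f} arvd={rec.arvd:.3f} "
      f"msd={rec.msd:.2f}px hd95={rec.hd95:.2f}px")

sample = TrainingSample(image=znormalize(scan.image), label=scan.mask)
model = build_model(desk_config("vnet", input_shape=(32, 32, 8), seed=1))
model, state = train_model(model, [sample],
                           TrainConfig(max_steps=150, augment=False, seed=0))
rec = score_patient(predict_mask(model, sample.image), scan.mask, "P000")
print(f"trained V-net:      dice={rec.dice:.3f} arvd={rec.arvd:.3f} "
      f"msd={rec.msd:.2f}px hd95={rec.hd95:.2f}px "
      f"(final loss {state.loss_history[-1]:.3f})")
```

Output:

```
phantom volume: 22.2 ml (584 voxels)
dilated prediction: dice=0.764 arvd=0.616 msd=1.44px hd95=2.12px
trained V-net:      dice=0.991 arvd=0.010 msd=0.05px hd95=0.30px (final loss 0.315)
```

The dilated mask shows how a one-voxel boundary error shows up in all four
scores; the desk-scale V-net then overfits the same phantom in 150 steps,
recovering an almost perfect contour.

The `prostseg` command exposes the same pipeline from the shell:
`simulate`, `preprocess`, `split`, `train`, `predict`, `evaluate`, and
`compare` (see `prostseg --help`).

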