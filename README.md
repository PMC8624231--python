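# mrenhance

Volumetric brain-MRI enhancement for tumor-segmentation pipelines: Gibbs
ringing removal by local sub-voxel shifts, iterative log-domain bias-field
correction, intensity normalization (z-score and Nyul landmarks), 3D adaptive
histogram equalization, BraTS-style dice metrics, and a synthetic phantom
generator — composable into named preprocessing sequences.

## The problem

Skull-stripped, co-registered brain MR volumes (BraTS-style FLAIR/T1/T1ce/T2,
240 × 240 × 155 at 1 mm isotropic) still carry acquisition artifacts that
degrade automatic tumor segmentation: **Gibbs ringing** — oscillations near
sharp boundaries from truncating high spatial frequencies in the Fourier
reconstruction — a smooth multiplicative **bias field** V = u·f from magnet
and coil inhomogeneity, and **scanner-to-scanner intensity variability**.
This package implements the corrections and lets you compose them in any
order; the order matters, and the named presets reproduce the studied
sequences (notably `seq6`: bias correction *then* Gibbs removal, versus
`seq2`: the reverse).

## The methods

- **Unringing**: every image line is re-sampled at 41 sub-voxel offsets
  s = t/40 ∈ [−½, ½] voxel via the Fourier shift theorem; per voxel the
  offset minimizing a local total-variation measure (samples at the
  zero-crossings of the ringing sinc) is kept and interpolated back to the
  grid. Directional results jx, jy merge in k-space with complementary
  weights Gx = (1+cos ky)/[(1+cos ky)+(1+cos kx)], Gy = 1 − Gx, so
  artifact-free content passes unchanged.
- **Bias correction**: in the log domain, iterate
  û_n = û_{n−1} − S*{û_{n−1} − E[û | û_{n−1}]}, estimating the expected true
  intensity by Wiener-sharpening the log-intensity histogram and smoothing
  the residual with a mask-aware Gaussian S*; the total field is the sum of
  the smoothed residuals, pinned to unit geometric mean.
- **Normalization**: z-score over the mask, or Nyul piecewise-linear mapping
  of percentile landmarks onto a standard scale learned from training
  volumes.
- **3D AHE**: per-tile histogram equalization (optional contrast limiting)
  with trilinear blending of tile mappings; 1×1×1 tiling reduces exactly to
  global equalization.
- **Metrics**: per-region dice over the nested BraTS regions (whole ⊇ core ⊇
  enhancing, labels {1,2,4}/{1,4}/{4}) and the multiclass soft dice loss
  L = −(2/K) Σ_k Σ_i l_ik m_ik / (Σ_i l_ik + Σ_i m_ik).

See `docs/methods.md` for assumptions, parameter defaults, and the validity
domain of each operator.

## Worked example

```python
import numpy as np
from mrenhance import (
    PhantomSpec, BiasFieldSpec, make_phantom, add_bias_field,
    add_gibbs_ringing, preset_sequence, run_sequence, image_quality,
)

# synthetic study: a brain-like phantom corrupted by a bias field and ringing
clean, labels = make_phantom(PhantomSpec(shape=(64, 64, 48), seed=0))
mask = clean.data > 0
biased, field = add_bias_field(clean, BiasFieldSpec(amplitude=1.25, seed=3))
ringed = add_gibbs_ringing(biased, (0.9, 0.9, 1.0))
corrupted = ringed.with_data(np.where(mask, ringed.data, 0.0))  # skull-stripped

for name in ("seq1", "seq2", "seq6"):
    out, record = run_sequence(corrupted, preset_sequence(name))
    rmse, psnr, ratio = image_quality(out, clean, mask)
    print(f"{name} ({'+'.join(record.stage_kinds)}): RMSE {rmse:.2f}  PSNR {psnr:.1f} dB")
rmse0, psnr0, _ = image_quality(corrupted, clean, mask)
print(f"uncorrected: RMSE {rmse0:.2f}  PSNR {psnr0:.1f} dB")
```

prints

```
seq1 (gibbs): RMSE 16.04  PSNR 18.6 dB
seq2 (gibbs+bias): RMSE 68.44  PSNR 6.0 dB
seq6 (bias+gibbs): RMSE 12.87  PSNR 20.5 dB
uncorrected: RMSE 15.97  PSNR 18.6 dB
```

Reading the numbers: the bias field dominates the corruption, so `seq1`
(unringing alone) barely moves masked RMSE. Running bias correction *after*
unringing (`seq2`) fails badly here — the unringing pass perturbs the
intensity distribution the histogram-sharpening step relies on — while
`seq6` (bias first, then unringing) gives the best reconstruction. Stage
order is not commutative, which is the reason the sequence abstraction
exists.

## Command line

```bash
mrenhance phantom --shape 128 128 128 --seed 1 \
    --image-out img.nii.gz --labels-out lab.nii.gz --gibbs-keep 0.9
mrenhance run --sequence seq6 --input img.nii.gz --output out.nii.gz
mrenhance unring --input img.nii.gz --output unrung.nii.gz
mrenhance biascorrect --input img.nii.gz --output corrected.nii.gz --field-output field.nii.gz
mrenhance normalize --mode zscore --input img.nii.gz --output z.nii.gz
mrenhance ahe --input img.nii.gz --output eq.nii.gz --tiles 8 8 4
mrenhance evaluate --prediction pred.nii.gz --truth lab.nii.gz
```

4D multi-modality NIfTI inputs to `run` are processed channel by channel.
Custom sequences come from a YAML config (`--config`), either `preset: seq6`
or an explicit stage list with per-stage parameter blocks.

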