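# Methods

`mrenhance` implements the preprocessing chain used to prepare skull-stripped,
co-registered brain MR volumes (BraTS-style: 240 × 240 × 155 voxels at 1 mm
isotropic, exact-zero background) for automatic tumor segmentation: Gibbs
ringing removal, bias-field correction, intensity normalization, adaptive
histogram equalization, and their composition into named sequences. This note
records the models, the numerical choices, and what the synthetic validation
suite does and does not demonstrate.

## Gibbs ringing removal (sub-voxel shifts)

Truncating k-space at acquisition convolves the image with a sinc kernel,
producing oscillations of period ≈ 2/q voxels near sharp edges, where q is the
fraction of the band retained on the stored grid. The corrector re-samples
each image line at 2·`num_shifts` + 1 candidate offsets s = t/(2·`num_shifts`)
∈ [−½, ½] voxel (realized exactly by the Fourier shift theorem), measures the
local oscillation of each resampling as the sum of absolute first differences
over the left and right windows [`min_window`, `max_window`] (taking the
smaller side, so voxels adjacent to a genuine edge look away from it), keeps
per voxel the offset with the least oscillation, and maps the chosen sample
back to the integer grid by linear interpolation. Ties are broken toward the
smallest |shift| (negative before positive), which leaves artifact-free
signals — constants exactly, smooth ramps to within a fraction of a percent —
untouched.

For 2D slices, the line corrector runs along both in-plane axes, giving jx
and jy, which are merged in k-space:

    J = FT⁻¹{ FT(jx)·Gx + FT(jy)·Gy },
    Gx = (1 + cos ky) / [(1 + cos ky) + (1 + cos kx)],  Gy = 1 − Gx.

Gx passes the high-kx content of jx (the direction jx corrected) and vice
versa; Gx + Gy = 1 holds exactly because Gy is computed as the complement, so
jx = jy reproduces itself and minimal smoothing is introduced. At the doubly
singular corner kx = ky = π (0/0) both weights are set to ½ by symmetry. The
corner term 1 + cos k is forced to exact zero at the Nyquist index. Volumes
are processed slice-by-slice in a configurable plane (default axial); all
FFTs run in double precision and the imaginary residue of the final inverse
transform is asserted below 10⁻⁸ of the signal range.

Defaults `num_shifts` = 20, windows [1, 3] follow the reference
implementation of the sub-voxel-shift method; the source publications leave
them unstated.

**Validity domain.** Half-voxel shifts can only land samples on oscillation
zero-crossings when the ringing period is near 2 voxels, i.e. when the image
is stored at (close to) its acquisition resolution. On zero-filled
reconstructions (e.g. only 25 % of the band retained on the stored grid, an
8-voxel period) no sub-voxel shift reaches a zero-crossing, and an exhaustive
per-voxel search over the full shift set improves a truncated step's RMSE by
only ~1 %: such data must be cropped back to the acquisition matrix before
unringing. Moreover, RMSE against a sharp ground truth conflates two errors:
the removable oscillation and the irreversible band-limitation blur at edges.
On a 96² phantom slice ringed at acquisition rate the corrector removes ~86 %
of the interior (plateau) oscillation RMSE while the near-edge blur — an
order of magnitude larger — is untouched, so whole-image RMSE gains are
necessarily modest. The validation suite therefore scores oscillation removal
on interior voxels, and treats whole-volume RMSE figures as composites.

## Bias-field correction (iterative residual scheme)

The observed image is modelled as V = u·f with u the true image and f a
smooth multiplicative field (noise neglected); in the log domain v̂ = û + f̂.
Each iteration of the corrector computes

    û_n = û_{n−1} − S*{ û_{n−1} − E[û | û_{n−1}] },

where E[û | û_{n−1}] is the expected true log intensity under the assumption
that the log-intensity histogram is the true distribution blurred by a
Gaussian of FWHM `sharpen_fwhm` × (masked log range): the histogram
(`histogram_bins` bins) is sharpened by Wiener deconvolution with noise
constant `wiener_noise`, and the posterior mean is evaluated on a grid and
applied by linear interpolation, clipped to the sample range. S* is the
smoothing operator, realized as mask-aware Gaussian smoothing (normalized
convolution, nearest-supported-voxel extrapolation outside the mask) with
sigma `smoothing_scale` mm, defaulting to one third of the smallest masked
extent. The total log field after n iterations is the running sum of the
smoothed residuals, and the corrected image is the input divided by the
exponentiated total — both bookkeeping identities hold to floating point and
are asserted in the tests.

Numerical choices:

- Each smoothed residual is centred to zero mean over the mask before being
  applied. The global scale of a multiplicative field is unidentifiable, so
  the estimate is pinned to unit geometric mean; without this the corrected
  image drifts in overall brightness and before/after RMSE comparisons are
  meaningless.
- Voxels ≤ 0 are excluded from the mask (never clamped): skull-stripped
  backgrounds are exact zeros and the log transform is undefined there. The
  default mask is every strictly positive voxel; an explicit mask is
  intersected with it.
- Convergence fires when the coefficient of variation of exp(residual) over
  the mask drops below `convergence_threshold` (default 10⁻³), capped at
  `max_iterations` (default 50). A constant foreground returns a unit field
  immediately.
- Single-resolution iteration with a Gaussian S*: the canonical tool's
  B-spline fitting and multi-resolution schedule are engineering beyond the
  model equations; the Gaussian honors the smoothing contract and is
  swappable behind `smooth_field`.

On phantoms multiplied by a known gaussian-bump field of amplitude 1.25 the
estimated log field correlates with the truth at r ≈ 0.98 and masked RMSE to
the clean phantom drops by ~18–25 %; on bias-free phantoms the estimated
field's CV stays below 1 %.

## Intensity normalization

**z-score**: masked voxels map to (v − mean)/sd; background stays 0. Constant
foregrounds are rejected.

**Nyul landmarks**: training computes each volume's percentiles on the
schedule (default 1, 10, 20, …, 90, 99), maps the (p1, p99) span affinely
onto the standard range (default 1–100), and averages the mapped landmarks
across volumes — making training invariant to per-volume affine intensity
changes. Application maps a volume's own percentiles piecewise-linearly onto
the learned landmarks, continuing on the terminal segments' slopes beyond
the span. The map is monotone; applying a model to its own training volume
pins the landmarks exactly. The map is defined by the masked percentiles but
applied to every voxel, so idempotence and cross-volume agreement are stated
relative to a fixed mask.

## 3D adaptive histogram equalization

The volume is partitioned into `tiles` (default 8 × 8 × 4) 3D blocks; each
block's histogram (`bins` bins over the global intensity range) yields a CDF
mapping back onto that range, and every voxel is transformed by trilinear
interpolation among the mappings of its 8 surrounding tile centers (boundary
tiles replicated). With `clip_limit` set, histograms are capped at
clip_limit × the mean bin count with uniform redistribution (CLAHE). A tile
whose histogram occupies a single bin maps by identity, so constant volumes
pass through bit-identically. With a 1 × 1 × 1 tiling the operator reduces
exactly to global histogram equalization — kept as the degenerate case
because it provides an exact independent oracle, even though global
equalization is not recommended for MR volumes. The stacked-slices/trilinear
description of the block construction admits more than one reading; the
tiled-3D interpretation implemented here reproduces its stated ingredients
(blocks of slices, per-block histograms, trilinear reconstruction).

## Segmentation metrics

Dice score 2|A∩B|/(|A|+|B|) per nested region (whole = labels {1, 2, 4},
core = {1, 4}, enhancing = {4}); empty-vs-empty is defined as 1.0 (both agree
on absence — conventions vary and this one is explicit). The multiclass soft
dice loss is L = −(2/K) Σ_k Σ_i l_ik m_ik / (Σ_i l_ik + Σ_i m_ik) with l the
per-class softmax scores and m the one-hot truth; no smoothing epsilon is
added — a class absent from both contributes 0 by the guarded rule. L = −1 at
perfect binary agreement and, with hard predictions, each class term is half
the set dice.

## Sequences

The ten presets compose the stages in the studied orders; the distinguishing
pair is seq2 = [gibbs, bias] versus seq6 = [bias, gibbs] (the starred
convention: bias correction before Gibbs removal — the best-performing order
in the source study). seq9 and seq10 repeat seq1's single-stage recipe on
other datasets and are identical as stage lists. The Nyul stage self-trains
on its input when no model is supplied. Multi-modality 4D volumes are
processed channel-by-channel with per-channel statistics. Every run returns a
record (stage order, parameters, masked mean/sd before and after each stage,
timings) sufficient to re-run identically; the whole chain is deterministic,
and all randomness in the phantom suite is seeded.

## The phantom suite: what it shows and what it does not

`make_phantom` renders piecewise-constant ellipsoid scenes — a brain
envelope, a darker deep structure, and three concentric tumor ellipsoids
labelled 2/1/4 so the BraTS nesting (enhancing ⊆ core ⊆ whole) holds by
construction. The seed drives a ±5 % per-ellipsoid intensity jitter
(geometry fixed), keeping volumes piecewise constant while distinct seeds
differ. Corruption operators: central k-space truncation per axis (DC always
kept, so the spatial mean is preserved), multiplicative gaussian-bump or
low-order-polynomial fields bounded in [1/a, a], and Gaussian or Rician
noise. The suite's corrupted condition is bias amplitude 1.25 and in-plane
keep fraction 0.9 — mild truncation, the regime of ringing present in
reconstructed MR data — followed by re-zeroing the background, as dataset
providers' skull-stripping does; without that re-zeroing, ringing leaks
tiny nonzero values into the background and any positivity-based mask is
corrupted.

Phantoms have no texture, no anatomy-scale intensity gradients within a
tissue, no noise unless injected, and sharp analytic edges; passing the suite
shows the operators implement their models correctly and compose in the
stated orders, not that any particular sequence is optimal on clinical data.
Problem sizes in the validation suite (64³–128³ phantoms, 48³ for the
composition checks) are chosen so the full suite runs in minutes on one CPU;
all operators are resolution-independent.

## Known limitations

- Unringing operates in-plane only (no through-plane pass) and assumes data
  at acquisition resolution; zero-filled inputs should be cropped upstream.
- The bias corrector is single-resolution and Gaussian-smoothed; very sharp
  or high-amplitude fields (a ≫ 1.5) may be under-fit.
- Nyul normalization assumes roughly comparable foreground histograms;
  pathology that shifts whole percentile bands can skew the mapping.
- No skull stripping, registration, or segmentation model training is
  included; volumes are assumed co-registered and stripped upstream.
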