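"""Bias-field estimation and removal in the log domain.

The observed image is modelled multiplicatively, V = u * f (noise neglected),
so in the log domain v = u + f with f a smooth additive field.  Following the
iterative residual scheme of the N4 family, each iteration

    u_n = u_{n-1} - S*{ u_{n-1} - E[u | u_{n-1}] }

estimates the expected true log intensity per voxel by sharpening the
log-intensity histogram (Wiener deconvolution of an assumed Gaussian blur),
smooths the residual spatially (the S* operator, realized here as mask-aware
Gaussian smoothing), and subtracts it.  The total log field after n
iterations is the running sum of the smoothed residuals, and the corrected
image is the input divided by its exponential.

Each residual is centred to zero mean over the mask before it is applied:
the global scale of a multiplicative field is unidentifiable, so the
estimated field is pinned to unit geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .core import Volume3D

__all__ = ["BiasParams", "BiasResult", "correct_bias", "sharpen_histogram", "smooth_field"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BiasParams:
    """Tunables of the iterative corrector.

    smoothing_scale is the Gaussian sigma of the S* operator in mm; when None
    it defaults to one third of the smallest extent of the mask's bounding
    box.  sharpen_fwhm is the assumed blur of the log-intensity histogram as
    a fraction of the masked log-intensity range.  Convergence fires when the
    coefficient of variation of exp(residual field) over the mask drops below
    convergence_threshold.
    """

    max_iterations: int = 50
    convergence_threshold: float = 0.001
    histogram_bins: int = 200
    sharpen_fwhm: float = 0.15
    wiener_noise: float = 0.01
    smoothing_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.convergence_threshold < 1:
            raise ValueError("convergence_threshold must lie in (0, 1)")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.sharpen_fwhm <= 0 or self.wiener_noise <= 0:
            raise ValueError("sharpen_fwhm and wiener_noise must be positive")
        if self.smoothing_scale is not None and self.smoothing_scale <= 0:
            raise ValueError("smoothing_scale must be positive")


@dataclass
class BiasResult:
    """Output bundle of :func:`correct_bias`.

    ``field`` is the multiplicative field estimate (unit geometric mean over
    the mask); ``log(field)`` equals the sum of ``residual_log_fields`` and
    ``corrected = input / field``, so the log-domain bookkeeping identities
    hold to floating point.
    """

    corrected: Volume3D
    field: Volume3D
    residual_log_fields: List[np.ndarray]
    iterations_run: int
    converged: bool
    mask: np.ndarray


def sharpen_histogram(log_intensities: np.ndarray, params: BiasParams = BiasParams()) -> np.ndarray:
    """Expected "true" log intensity for every sample, via histogram sharpening.

    The sample histogram is treated as the true intensity distribution blurred
    by a Gaussian of FWHM ``sharpen_fwhm`` x sample range; Wiener deconvolution
    recovers the sharp distribution, and the returned values are the posterior
    means E[true | observed] under that blur model, clipped to the sample
    range.  A zero-spread sample maps to itself.
    """
    sample = np.asarray(log_intensities, dtype=np.float64).ravel()
    if sample.size == 0:
        raise ValueError("sharpen_histogram requires a nonempty sample")
    lo, hi = float(sample.min()), float(sample.max())
    if hi <= lo:
        return sample.copy()

    nb = params.histogram_bins
    hist, edges = np.histogram(sample, bins=nb, range=(lo, hi))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    sigma = params.sharpen_fwhm * (hi - lo) * _FWHM_TO_SIGMA

    # Wiener deconvolution of the assumed blur on a zero-padded grid
    npad = 2 * nb
    kernel = np.zeros(npad)
    offsets = np.arange(npad)
    offsets = np.minimum(offsets, npad - offsets)  # circular distance
    kernel[:] = np.exp(-0.5 * (offsets * width / sigma) ** 2)
    ksum = kernel.sum()
    if ksum > 0:
        kernel /= ksum
    fh = np.fft.rfft(np.concatenate([hist, np.zeros(npad - nb)]))
    fk = np.fft.rfft(kernel)
    fkmax = np.max(np.abs(fk))
    fk_norm = fk / fkmax if fkmax > 0 else fk
    sharp = np.fft.irfft(fh * np.conj(fk_norm) / (np.abs(fk_norm) ** 2 + params.wiener_noise), npad)[:nb]
    sharp = np.clip(sharp, 0.0, None)

    # posterior mean E[true | observed] on an evaluation grid spanning [lo, hi]
    grid = np.linspace(lo, hi, nb)
    gmat = np.exp(-0.5 * ((grid[:, None] - centers[None, :]) / sigma) ** 2)
    den = gmat @ sharp
    num = gmat @ (centers * sharp)
    tiny = den.max() * 1e-12 if den.max() > 0 else 0.0
    mapping = np.where(den > tiny, num / np.where(den > tiny, den, 1.0), grid)
    mapping = np.clip(mapping, lo, hi)
    return np.interp(sample, grid, mapping)


def _sigma_voxels(mask: np.ndarray, spacing, params: BiasParams) -> np.ndarray:
    """Per-axis Gaussian sigma of S* in voxels."""
    if params.smoothing_scale is not None:
        scale_mm = params.smoothing_scale
    else:
        idx = np.nonzero(mask)
        extents = [
            (int(ix.max()) - int(ix.min()) + 1) * s for ix, s in zip(idx, spacing)
        ]
        scale_mm = min(extents) / 3.0
    return np.array([scale_mm / s for s in spacing], dtype=np.float64)


def smooth_field(residual: Volume3D, mask: Optional[np.ndarray] = None,
                 params: BiasParams = BiasParams()) -> Volume3D:
    """Mask-aware Gaussian low-pass of a residual field (the S* operator).

    Uses normalized convolution so voxels outside the mask do not bleed in;
    where the Gaussian weight of the mask is negligible the value of the
    nearest well-supported voxel is used, giving a smooth extrapolation over
    the full grid.
    """
    data = np.asarray(residual.data, dtype=np.float64)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("smooth_field requires a nonempty mask")
    if not np.all(np.isfinite(data[mask])):
        raise ValueError("residual must be finite on the mask")
    sigma = _sigma_voxels(mask, residual.spacing, params)
    w = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma, truncate=4.0)
    num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma=sigma, truncate=4.0)
    support = w > 1e-6 * w.max()
    out = np.zeros_like(data)
    out[support] = num[support] / w[support]
    if not support.all():
        # fill unsupported voxels from nearest supported neighbor
        _, idx = ndimage.distance_transform_edt(~support, return_indices=True)
        out[~support] = out[tuple(i[~support] for i in idx)]
    return residual.with_data(out)


def correct_bias(vol: Volume3D, mask: Optional[np.ndarray] = None,
                 params: BiasParams = BiasParams()) -> BiasResult:
    """Estimate and remove a smooth multiplicative bias field.

    Non-positive voxels are always excluded from the mask (the log transform
    is undefined there); by default the mask is every strictly-positive
    voxel, matching skull-stripped data with exact-zero background.
    """
    data = vol.data
    if mask is None:
        mask = data > 0
    else:
        mask = np.asarray(mask, dtype=bool) & (data > 0)
    if not mask.any():
        raise ValueError("correct_bias requires a nonempty positive-intensity mask")

    log_masked = np.log(data[mask])
    shape = data.shape
    field_log = np.zeros(shape, dtype=np.float64)
    residuals: List[np.ndarray] = []

    if np.ptp(log_masked) == 0:
        # constant foreground: nothing to estimate
        return BiasResult(
            corrected=vol.with_data(data.copy()),
            field=vol.with_data(np.ones(shape)),
            residual_log_fields=[],
            iterations_run=0,
            converged=True,
            mask=mask,
        )

    u = log_masked.copy()
    converged = False
    iterations = 0
    for _ in range(params.max_iterations):
        mapped = sharpen_histogram(u, params)
        resid_vol = np.zeros(shape, dtype=np.float64)
        resid_vol[mask] = u - mapped
        fr = smooth_field(vol.with_data(resid_vol), mask, params).data
        fr -= fr[mask].mean()  # pin the field to unit geometric mean
        u -= fr[mask]
        field_log += fr
        residuals.append(fr)
        iterations += 1
        efr = np.exp(fr[mask])
        cv = efr.std() / efr.mean()
        if cv < params.convergence_threshold:
            converged = True
            break

    fdata = np.exp(field_log)
    corrected = data / fdata
    return BiasResult(
        corrected=vol.with_data(corrected),
        field=vol.with_data(fdata),
        residual_log_fields=residuals,
        iterations_run=iterations,
        converged=converged,
        mask=mask,
    )
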