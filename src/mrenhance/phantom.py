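"""Synthetic brain-like phantoms with controllable corruption.

Piecewise-constant ellipsoid scenes stand in for skull-stripped brain MR
volumes: a large "brain" ellipsoid, optional internal structures, and three
nested tumor ellipsoids labelled in the BraTS dialect (2 = edema shell,
1 = core shell, 4 = enhancing center, so whole ⊇ core ⊇ enhancing holds by
construction).  Corruption operators inject the three degradations the
toolkit removes: Gibbs ringing by central k-space truncation, a smooth
multiplicative bias field, and additive Gaussian (or magnitude/Rician)
noise.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import LabelMap, Volume3D

__all__ = [
    "Ellipsoid",
    "TumorSpec",
    "PhantomSpec",
    "BiasFieldSpec",
    "make_phantom",
    "add_gibbs_ringing",
    "add_bias_field",
    "add_noise",
]


@dataclass
class Ellipsoid:
    """A rotated solid ellipsoid painted at a constant intensity.

    ``angles`` are intrinsic x-y-z Euler rotations in radians applied to the
    ellipsoid axes; ``center`` and ``semi_axes`` are in voxel coordinates.
    """

    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    angles: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: float = 100.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")


def _rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _inside(ell: Ellipsoid, shape: Tuple[int, int, int], scale: float = 1.0) -> np.ndarray:
    """Boolean mask of voxels inside ``ell`` with semi-axes scaled by ``scale``."""
    gx = np.arange(shape[0], dtype=np.float64)[:, None, None] - ell.center[0]
    gy = np.arange(shape[1], dtype=np.float64)[None, :, None] - ell.center[1]
    gz = np.arange(shape[2], dtype=np.float64)[None, None, :] - ell.center[2]
    rot = _rotation_matrix(ell.angles).T  # world -> ellipsoid frame
    ax = np.asarray(ell.semi_axes, dtype=np.float64) * scale
    q = np.zeros(shape, dtype=np.float64)
    for row, a in zip(rot, ax):
        u = row[0] * gx + row[1] * gy + row[2] * gz
        q += (u / a) ** 2
    return q <= 1.0


@dataclass
class TumorSpec:
    """Three nested tumor regions built by scaling one ellipsoid.

    The outer ellipsoid is the whole-tumor extent; the core and enhancing
    regions are concentric copies shrunk by ``scales`` (strictly decreasing,
    all in (0, 1]), so the BraTS nesting enhancing ⊆ core ⊆ whole is
    guaranteed geometrically.  ``intensities`` give the painted levels for
    the edema shell, core shell, and enhancing center.
    """

    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]
    angles: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    scales: Tuple[float, float, float] = (1.0, 0.6, 0.3)
    intensities: Tuple[float, float, float] = (140.0, 110.0, 170.0)
    labels: Tuple[int, int, int] = (2, 1, 4)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"tumor semi-axes must be positive, got {self.semi_axes}")
        s = self.scales
        if not (0 < s[2] < s[1] < s[0] <= 1):
            raise ValueError(f"tumor scales must be strictly decreasing in (0, 1], got {s}")


@dataclass
class PhantomSpec:
    """Scene description for :func:`make_phantom`.

    Defaults mirror the BraTS acquisition geometry (240 x 240 x 155 voxels at
    1 mm isotropic).  The seed drives a small per-ellipsoid intensity jitter
    so distinct seeds yield distinct (still piecewise-constant) volumes.
    """

    shape: Tuple[int, int, int] = (240, 240, 155)
    ellipsoids: Optional[List[Ellipsoid]] = None
    tumor: object = "auto"  # TumorSpec, None (no tumor), or "auto" for the default
    intensity_jitter: float = 0.05
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        self.shape = tuple(int(n) for n in self.shape)
        if self.ellipsoids is None:
            self.ellipsoids = _default_anatomy(self.shape)
        if isinstance(self.tumor, str):
            if self.tumor != "auto":
                raise ValueError(f"tumor must be a TumorSpec, None, or 'auto', got {self.tumor!r}")
            self.tumor = _default_tumor(self.shape)
        elif self.tumor is not None and not isinstance(self.tumor, TumorSpec):
            raise ValueError("tumor must be a TumorSpec, None, or 'auto'")
        if not 0 <= self.intensity_jitter < 1:
            raise ValueError("intensity_jitter must lie in [0, 1)")


def _default_anatomy(shape: Tuple[int, int, int]) -> List[Ellipsoid]:
    c = tuple((n - 1) / 2.0 for n in shape)
    return [
        # brain envelope
        Ellipsoid(center=c, semi_axes=(0.42 * shape[0], 0.46 * shape[1], 0.40 * shape[2]), intensity=100.0),
        # deep structure at lower intensity (ventricle-like)
        Ellipsoid(
            center=(c[0], c[1] - 0.08 * shape[1], c[2]),
            semi_axes=(0.10 * shape[0], 0.16 * shape[1], 0.12 * shape[2]),
            angles=(0.0, 0.0, 0.3),
            intensity=40.0,
        ),
    ]


def _default_tumor(shape: Tuple[int, int, int]) -> TumorSpec:
    c = tuple((n - 1) / 2.0 for n in shape)
    return TumorSpec(
        center=(c[0] + 0.18 * shape[0], c[1] + 0.10 * shape[1], c[2] + 0.05 * shape[2]),
        semi_axes=(0.14 * shape[0], 0.12 * shape[1], 0.12 * shape[2]),
        angles=(0.2, 0.1, 0.0),
    )


def make_phantom(spec: Optional[PhantomSpec] = None) -> Tuple[Volume3D, LabelMap]:
    """Render a piecewise-constant phantom and its BraTS-dialect label map.

    Ellipsoids are painted in list order (later ones overwrite), then the
    tumor's three nested regions are painted outermost-first so every voxel
    carries exactly one label and the nesting holds exactly.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    data = np.zeros(spec.shape, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)

    def jitter() -> float:
        return 1.0 + spec.intensity_jitter * rng.uniform(-1.0, 1.0)

    for ell in spec.ellipsoids:
        data[_inside(ell, spec.shape)] = ell.intensity * jitter()

    if spec.tumor is not None:
        t = spec.tumor
        base = Ellipsoid(center=t.center, semi_axes=t.semi_axes, angles=t.angles)
        for scale, level, lab in zip(t.scales, t.intensities, t.labels):
            m = _inside(base, spec.shape, scale=scale)
            data[m] = level * jitter()
            labels[m] = lab

    vol = Volume3D(data, spacing=spec.spacing)
    lmap = LabelMap(labels, spacing=spec.spacing, affine=vol.affine.copy())
    return vol, lmap


def _keep_vector(n: int, fraction: float) -> np.ndarray:
    """Centered k-space keep mask for one axis, in unshifted (FFT) order.

    The window is defined on the DC-centered spectrum; for even window sizes
    the extra sample sits on the negative-frequency side, matching the
    standard fftshift convention.
    """
    m = int(round(fraction * n))
    m = max(m, 1)
    if m >= n:
        return np.ones(n, dtype=bool)
    c = n // 2  # DC index after fftshift
    lo = c - m // 2
    keep_shifted = np.zeros(n, dtype=bool)
    keep_shifted[lo : lo + m] = True
    return np.fft.ifftshift(keep_shifted)


def add_gibbs_ringing(vol: Volume3D, keep_fraction) -> Volume3D:
    """Inject Gibbs ringing by truncating the central k-space window.

    ``keep_fraction`` is a scalar or per-axis triple in (0, 1]: the fraction
    of Fourier coefficients retained (centered on DC) along each axis.  A
    fraction of 1 keeps the axis untouched.  The DC coefficient always
    survives, so the spatial mean is preserved.
    """
    fracs = np.broadcast_to(np.asarray(keep_fraction, dtype=np.float64), (3,))
    if np.any(fracs <= 0) or np.any(fracs > 1):
        raise ValueError(f"keep_fraction must lie in (0, 1] per axis, got {tuple(fracs)}")
    spectrum = np.fft.fftn(vol.data)
    for axis, frac in enumerate(fracs):
        keep = _keep_vector(vol.data.shape[axis], float(frac))
        shape = [1, 1, 1]
        shape[axis] = -1
        spectrum *= keep.reshape(shape)
    return vol.with_data(np.fft.ifftn(spectrum).real)


@dataclass
class BiasFieldSpec:
    """Description of a smooth multiplicative bias field.

    ``amplitude`` a >= 1 bounds the field inside [1/a, a]; ``smoothness`` is
    the spatial scale in voxels (Gaussian sigma for the bump, coordinate
    normalization for the polynomial).  ``center`` pins the bump location
    (voxel coords); when None it is drawn from the central half of the
    volume using ``seed``.
    """

    kind: str = "gaussian-bump"
    amplitude: float = 1.25
    smoothness: Optional[float] = None
    center: Optional[Tuple[float, float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-bump", "low-order-polynomial"):
            raise ValueError(f"unknown bias field kind: {self.kind!r}")
        if self.amplitude < 1:
            raise ValueError(f"amplitude must be >= 1, got {self.amplitude}")


def evaluate_bias_field(shape: Tuple[int, int, int], fspec: BiasFieldSpec) -> np.ndarray:
    """Evaluate the field of ``fspec`` on a voxel grid of the given shape."""
    if fspec.amplitude == 1.0:
        return np.ones(shape, dtype=np.float64)
    rng = np.random.default_rng(fspec.seed)
    log_amp = np.log(fspec.amplitude)
    smooth = fspec.smoothness if fspec.smoothness is not None else min(shape) / 4.0
    if smooth <= 0:
        raise ValueError("smoothness must be positive")
    if fspec.kind == "gaussian-bump":
        if fspec.center is not None:
            center = np.asarray(fspec.center, dtype=np.float64)
        else:
            center = np.array([rng.uniform(0.25 * n, 0.75 * n) for n in shape])
        gx = np.arange(shape[0], dtype=np.float64)[:, None, None] - center[0]
        gy = np.arange(shape[1], dtype=np.float64)[None, :, None] - center[1]
        gz = np.arange(shape[2], dtype=np.float64)[None, None, :] - center[2]
        r2 = gx**2 + gy**2 + gz**2
        bump = np.exp(-r2 / (2.0 * smooth**2))  # in (0, 1]
        return np.exp(log_amp * (2.0 * bump - 1.0))
    # low-order-polynomial: random quadratic over centered normalized coords
    coords = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) / max(smooth, 1.0) for n in shape
    ]
    gx = coords[0][:, None, None]
    gy = coords[1][None, :, None]
    gz = coords[2][None, None, :]
    c = rng.normal(size=10)
    p = (
        c[0]
        + c[1] * gx + c[2] * gy + c[3] * gz
        + c[4] * gx * gy + c[5] * gx * gz + c[6] * gy * gz
        + c[7] * gx**2 + c[8] * gy**2 + c[9] * gz**2
    )
    peak = np.max(np.abs(p))
    if peak > 0:
        p = p / peak  # normalized to [-1, 1]
    return np.exp(log_amp * p)


def add_bias_field(vol: Volume3D, fspec: BiasFieldSpec) -> Tuple[Volume3D, Volume3D]:
    """Multiply a volume by a smooth positive field; return (corrupted, field)."""
    fdata = evaluate_bias_field(vol.data.shape, fspec)
    return vol.with_data(vol.data * fdata), vol.with_data(fdata)


def add_noise(vol: Volume3D, sigma: float, model: str = "gaussian", seed: int = 0) -> Volume3D:
    """Add acquisition noise.

    ``gaussian`` adds i.i.d. N(0, sigma^2); ``rician`` takes the magnitude of
    the signal plus complex Gaussian noise of per-channel std ``sigma`` — the
    distribution of magnitude MR images, whose zero-signal background mean is
    sigma * sqrt(pi/2).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model: {model!r}")
    if sigma == 0:
        return vol.with_data(vol.data.copy())
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        return vol.with_data(vol.data + rng.normal(0.0, sigma, size=vol.data.shape))
    re = vol.data + rng.normal(0.0, sigma, size=vol.data.shape)
    im = rng.normal(0.0, sigma, size=vol.data.shape)
    return vol.with_data(np.hypot(re, im))
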