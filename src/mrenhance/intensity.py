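"""Intensity normalization and 3D adaptive histogram equalization.

Two normalizers address scanner-to-scanner intensity variability: the z-score
map (zero mean, unit variance over the mask) and the Nyul landmark method,
which learns mean percentile landmarks on a standard scale from training
volumes and maps new volumes piecewise-linearly between their own percentiles
and the learned landmarks.  Adaptive histogram equalization partitions the
volume into 3D tiles, equalizes each tile's histogram, and blends the tile
mappings by trilinear interpolation between tile centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Volume3D

__all__ = [
    "NyulModel",
    "AHEParams",
    "zscore_normalize",
    "nyul_train",
    "nyul_apply",
    "ahe_3d",
]

DEFAULT_SCHEDULE = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)


def _resolve_mask(vol: Volume3D, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        return vol.foreground_mask()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    return mask


def zscore_normalize(vol: Volume3D, mask: Optional[np.ndarray] = None) -> Volume3D:
    """Zero-mean unit-variance normalization over the mask; background -> 0."""
    mask = _resolve_mask(vol, mask)
    vals = vol.data[mask]
    if vals.size == 0:
        raise ValueError("zscore_normalize: empty mask")
    mean = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("zscore_normalize: masked intensities are constant (zero variance)")
    out = np.zeros_like(vol.data)
    out[mask] = (vals - mean) / sd
    return vol.with_data(out)


@dataclass
class NyulModel:
    """Learned standard-scale landmarks for Nyul normalization."""

    percentile_schedule: Tuple[float, ...] = DEFAULT_SCHEDULE
    standard_landmarks: Optional[np.ndarray] = None
    standard_range: Tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        sched = np.asarray(self.percentile_schedule, dtype=np.float64)
        if sched.size < 2 or np.any(np.diff(sched) <= 0):
            raise ValueError("percentile_schedule must be strictly increasing with >= 2 entries")
        self.percentile_schedule = tuple(sched.tolist())
        s1, s2 = self.standard_range
        if not s1 < s2:
            raise ValueError("standard_range must satisfy s1 < s2")
        if self.standard_landmarks is not None:
            lm = np.asarray(self.standard_landmarks, dtype=np.float64)
            if lm.size != sched.size:
                raise ValueError("standard_landmarks length must match the schedule")
            if np.any(np.diff(lm) < 0):
                raise ValueError("standard_landmarks must be non-decreasing")
            self.standard_landmarks = lm

    def save(self, path) -> None:
        payload = {
            "percentile_schedule": list(self.percentile_schedule),
            "standard_landmarks": list(map(float, self.standard_landmarks)),
            "standard_range": list(self.standard_range),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "NyulModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            percentile_schedule=tuple(payload["percentile_schedule"]),
            standard_landmarks=np.asarray(payload["standard_landmarks"]),
            standard_range=tuple(payload["standard_range"]),
        )


def _volume_landmarks(vol: Volume3D, mask: Optional[np.ndarray], schedule) -> np.ndarray:
    vals = vol.data[_resolve_mask(vol, mask)]
    if vals.size == 0:
        raise ValueError("nyul: empty mask")
    p = np.percentile(vals, schedule)
    if p[-1] <= p[0]:
        raise ValueError("nyul: degenerate intensity span (p_low == p_high)")
    return p


def nyul_train(vols: Sequence[Volume3D], masks: Optional[Sequence[Optional[np.ndarray]]] = None,
               schedule: Sequence[float] = DEFAULT_SCHEDULE,
               standard_range: Tuple[float, float] = (1.0, 100.0)) -> NyulModel:
    """Learn mean standard-scale landmarks from training volumes.

    Each volume's scheduled percentiles are mapped affinely so its lowest and
    highest scheduled percentiles land on the standard range endpoints; the
    mapped interior landmarks are averaged across volumes.  The affine span
    mapping makes training invariant to per-volume affine intensity changes.
    """
    vols = list(vols)
    if not vols:
        raise ValueError("nyul_train requires at least one training volume")
    if masks is None:
        masks = [None] * len(vols)
    s1, s2 = standard_range
    mapped = []
    for vol, m in zip(vols, masks):
        p = _volume_landmarks(vol, m, schedule)
        mapped.append(s1 + (p - p[0]) * (s2 - s1) / (p[-1] - p[0]))
    landmarks = np.mean(mapped, axis=0)
    return NyulModel(
        percentile_schedule=tuple(schedule),
        standard_landmarks=landmarks,
        standard_range=(float(s1), float(s2)),
    )


def nyul_apply(vol: Volume3D, model: NyulModel, mask: Optional[np.ndarray] = None) -> Volume3D:
    """Map a volume onto the standard scale learned by :func:`nyul_train`.

    Intensities between consecutive own-percentiles map linearly onto the
    corresponding standard landmarks; values beyond the outermost scheduled
    percentiles continue on the terminal segments' slopes.  The map is
    non-decreasing and is applied to the whole volume (masked voxels define
    the percentiles).
    """
    if model.standard_landmarks is None:
        raise ValueError("nyul_apply: model has no trained landmarks")
    p = _volume_landmarks(vol, mask, model.percentile_schedule)
    lm = model.standard_landmarks
    data = vol.data
    out = np.interp(data, p, lm)
    # continue on terminal slopes beyond the learned span
    lo_slope = _segment_slope(p, lm, head=True)
    hi_slope = _segment_slope(p, lm, head=False)
    below = data < p[0]
    above = data > p[-1]
    out[below] = lm[0] + (data[below] - p[0]) * lo_slope
    out[above] = lm[-1] + (data[above] - p[-1]) * hi_slope
    return vol.with_data(out)


def _segment_slope(p: np.ndarray, lm: np.ndarray, head: bool) -> float:
    """Slope of the first (head) or last non-degenerate landmark segment."""
    if head:
        for i in range(1, len(p)):
            if p[i] > p[0]:
                return (lm[i] - lm[0]) / (p[i] - p[0])
    else:
        for i in range(len(p) - 2, -1, -1):
            if p[i] < p[-1]:
                return (lm[-1] - lm[i]) / (p[-1] - p[i])
    return 0.0


@dataclass
class AHEParams:
    """Tiling and histogram resolution for :func:`ahe_3d`.

    ``clip_limit`` (if set) caps each tile histogram at clip_limit x the mean
    bin count, redistributing the excess uniformly — the contrast-limited
    (CLAHE) variant.  None means plain adaptive equalization.
    """

    tiles: Tuple[int, int, int] = (8, 8, 4)
    bins: int = 256
    clip_limit: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.tiles) != 3 or any(int(t) < 1 for t in self.tiles):
            raise ValueError(f"tiles must be three counts >= 1, got {self.tiles}")
        self.tiles = tuple(int(t) for t in self.tiles)
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")


def _tile_bounds(n: int, t: int) -> List[Tuple[int, int]]:
    edges = np.linspace(0, n, t + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(t)]


def _lerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    # a + t*(b-a): exact when a == b, keeping degenerate tiles bit-identical
    return a + t * (b - a)


def ahe_3d(vol: Volume3D, params: AHEParams = AHEParams()) -> Volume3D:
    """3D tiled adaptive histogram equalization with trilinear blending.

    Each tile's histogram CDF (over ``bins`` bins spanning the global
    intensity range) defines a monotone mapping back onto that range; every
    voxel is transformed by trilinear interpolation among the mappings of
    its 8 surrounding tile centers, with boundary tiles replicated.  A tile
    whose histogram occupies a single bin maps by identity, so constant
    volumes pass through unchanged.
    """
    data = vol.data
    tx, ty, tz = params.tiles
    for t, n in zip(params.tiles, data.shape):
        if t > n:
            raise ValueError(f"more tiles than voxels along an axis: tiles={params.tiles}, shape={data.shape}")
    vmin = float(data.min())
    vmax = float(data.max())
    if vmax <= vmin:
        return vol.with_data(data.copy())

    nb = params.bins
    # global binning shared by all tiles
    bidx = np.clip(((data - vmin) * (nb / (vmax - vmin))).astype(np.int64), 0, nb - 1)

    bounds = [_tile_bounds(n, t) for n, t in zip(data.shape, params.tiles)]
    ntiles = tx * ty * tz
    luts = np.empty((ntiles, nb), dtype=np.float64)
    identity = np.zeros(ntiles, dtype=bool)
    centers = [np.array([(lo + hi - 1) / 2.0 for lo, hi in b]) for b in bounds]

    for ix in range(tx):
        for iy in range(ty):
            for iz in range(tz):
                tid = (ix * ty + iy) * tz + iz
                sl = (
                    slice(*bounds[0][ix]),
                    slice(*bounds[1][iy]),
                    slice(*bounds[2][iz]),
                )
                h = np.bincount(bidx[sl].ravel(), minlength=nb).astype(np.float64)
                if np.count_nonzero(h) <= 1:
                    identity[tid] = True
                    luts[tid] = 0.0  # unused; voxel value substituted at gather time
                    continue
                if params.clip_limit is not None:
                    cap = params.clip_limit * h.sum() / nb
                    excess = np.sum(np.maximum(h - cap, 0.0))
                    h = np.minimum(h, cap) + excess / nb
                cdf = np.cumsum(h) / h.sum()
                luts[tid] = vmin + (vmax - vmin) * cdf

    # fractional tile coordinate of every voxel along each axis (replicated ends)
    tcoord = []
    for axis, (cs, t) in enumerate(zip(centers, params.tiles)):
        x = np.arange(data.shape[axis], dtype=np.float64)
        pos = np.interp(x, cs, np.arange(t, dtype=np.float64))
        tcoord.append(pos)
    i0 = [np.clip(np.floor(p).astype(np.int64), 0, t - 1) for p, t in zip(tcoord, params.tiles)]
    i1 = [np.minimum(i + 1, t - 1) for i, t in zip(i0, params.tiles)]
    frac = [p - i for p, i in zip(tcoord, i0)]

    fx = frac[0][:, None, None]
    fy = frac[1][None, :, None]
    fz = frac[2][None, None, :]

    def corner(ax, ay, az):
        ixs = (i0[0] if ax == 0 else i1[0])[:, None, None]
        iys = (i0[1] if ay == 0 else i1[1])[None, :, None]
        izs = (i0[2] if az == 0 else i1[2])[None, None, :]
        tid = (ixs * ty + iys) * tz + izs
        vals = luts[tid, bidx]
        if identity.any():
            vals = np.where(identity[tid], data, vals)
        return vals

    c00 = _lerp(corner(0, 0, 0), corner(0, 0, 1), fz)
    c01 = _lerp(corner(0, 1, 0), corner(0, 1, 1), fz)
    c10 = _lerp(corner(1, 0, 0), corner(1, 0, 1), fz)
    c11 = _lerp(corner(1, 1, 0), corner(1, 1, 1), fz)
    c0 = _lerp(c00, c01, fy)
    c1 = _lerp(c10, c11, fy)
    out = _lerp(c0, c1, fx)
    return vol.with_data(out)
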