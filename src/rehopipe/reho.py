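"""Regional homogeneity: Kendall's coefficient of concordance per voxel.

Kendall's W treats the K voxels of a neighbourhood as raters ranking the T
time points.  With mid-ranks and the standard tie correction,

    W = 12 * sum_t (R_t - K(T+1)/2)^2  /  (K^2 (T^3 - T) - K * sum_j T_j)

where ``R_t`` is the rank sum at time t over the K series and
``T_j = sum (t^3 - t)`` over the tie-group sizes of series j.  W is 0 for no
agreement and 1 for perfect concordance, and is invariant to strictly
monotone transforms of each series.

The voxel-wise map uses the same ranks and the same formula as the standalone
:func:`kcc`, accumulated over the neighbourhood stencil with shifted adds, so
the two routes agree exactly (rank sums are multiples of 1/2 and stay far
below the float53 integer range, making every intermediate sum exact).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import BoldSeries, BrainMask

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def _rank_and_tiecorr(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks (1-based) along the last axis plus tie correction per row.

    Returns ``(ranks, tiecorr)`` with ``ranks.shape == X.shape`` and
    ``tiecorr = sum over tie groups of (m**3 - m)`` along the last axis.
    Vectorised over the leading axes.
    """
    X = np.asarray(X)
    T = X.shape[-1]
    order = np.argsort(X, axis=-1)  # tie runs are value-based; stability not needed
    s = np.take_along_axis(X, order, axis=-1)
    idx = np.arange(T)
    has_ties = (s[..., 1:] == s[..., :-1]).any()
    if not has_ties:
        # fast path: ranks are just sort positions, no tie correction anywhere
        ranks = np.empty(X.shape, dtype=np.float64)
        np.put_along_axis(ranks, order, (idx + 1).astype(np.float64), axis=-1)
        return ranks, np.zeros(X.shape[:-1], dtype=np.float64)
    new_run = np.ones(X.shape, dtype=bool)
    new_run[..., 1:] = s[..., 1:] != s[..., :-1]
    # start index of each element's tie run, propagated forward
    start = np.where(new_run, idx, 0)
    start = np.maximum.accumulate(start, axis=-1)
    # end index, propagated backward
    is_last = np.empty(X.shape, dtype=bool)
    is_last[..., :-1] = new_run[..., 1:]
    is_last[..., -1] = True
    end = np.where(is_last, idx, T - 1)
    end = np.flip(np.minimum.accumulate(np.flip(end, axis=-1), axis=-1), axis=-1)
    ranks_sorted = (start + end) / 2.0 + 1.0
    ranks = np.empty(X.shape, dtype=np.float64)
    np.put_along_axis(ranks, order, ranks_sorted, axis=-1)
    # sum over tie groups of (m^3 - m) == sum over elements of 3k^2 - 3k,
    # k the 1-based position within the run
    k = idx - start + 1
    tiecorr = 3.0 * np.sum(k * k - k, axis=-1, dtype=np.float64)
    return ranks, tiecorr


def kcc(series: np.ndarray) -> float:
    """Kendall's W of a K x T matrix (K series ranking T time points).

    Mid-ranks with tie correction; returns 0 (with a warning) when every
    series is constant, where concordance is undefined.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("kcc expects a K x T matrix")
    K, T = series.shape
    if K < 2:
        raise ValueError("kcc needs at least 2 series")
    if T < 3:
        raise ValueError("kcc needs at least 3 time points")
    if not np.isfinite(series).all():
        raise ValueError("kcc input contains non-finite values")
    ranks, tiecorr = _rank_and_tiecorr(series)
    R = ranks.sum(axis=0)
    S = np.sum((R - K * (T + 1) / 2.0) ** 2)
    denom = K * K * (T ** 3 - T) - K * tiecorr.sum()
    if denom <= 0:
        warnings.warn("all series constant; Kendall's W undefined, returning 0")
        return 0.0
    return float(12.0 * S / denom)


@dataclass
class ReHoMap:
    """3D Kendall's W map; ``k_map`` records the effective K per voxel."""

    data: np.ndarray
    affine: np.ndarray
    neighborhood_size: int = 27
    standardized: bool = False
    k_map: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ReHoMap must be 3D")


def neighborhood_offsets(size: int) -> list[tuple[int, int, int]]:
    """Offsets of the 7 (faces), 19 (faces+edges) or 27 (full cube) stencil."""
    if size not in (7, 19, 27):
        raise ValueError("neighborhood must be one of 7, 19, 27")
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                nz = (dx != 0) + (dy != 0) + (dz != 0)
                if size == 7 and nz > 1:
                    continue
                if size == 19 and nz > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def _shifted_add(acc: np.ndarray, vol: np.ndarray, offset) -> None:
    """acc[x,y,z] += vol[x+dx, y+dy, z+dz] with zero boundary, in place."""
    dx, dy, dz = offset
    src = [slice(max(d, 0), vol.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))]
    dst = [slice(max(-d, 0), vol.shape[i] + min(-d, 0)) for i, d in enumerate((dx, dy, dz))]
    acc[tuple(dst)] += vol[tuple(src)]


def _box_sum_axis(vol: np.ndarray, axis: int) -> np.ndarray:
    """Radius-1 box sum along one axis with zero boundary."""
    out = vol.copy()
    n = vol.shape[axis]
    lead = (slice(None),) * axis
    out[lead + (slice(0, n - 1),)] += vol[lead + (slice(1, n),)]
    out[lead + (slice(1, n),)] += vol[lead + (slice(0, n - 1),)]
    return out


def reho_map(bold: BoldSeries, mask: BrainMask, neighborhood: int = 27,
             require_full_neighborhood: bool = False) -> ReHoMap:
    """Voxel-wise Kendall's W over each voxel's in-mask neighbourhood.

    Out-of-mask neighbours are simply excluded, so the effective K varies at
    mask borders (recorded in ``k_map``); voxels with fewer than 2 in-mask
    members get 0.  With ``require_full_neighborhood`` voxels whose stencil is
    clipped by the mask are zeroed instead.
    """
    mask.check_geometry(bold)
    offsets = neighborhood_offsets(neighborhood)
    T = bold.n_timepoints
    if T < 3:
        raise ValueError("reho_map needs at least 3 time points")
    shape = bold.shape3d
    inmask = mask.data

    sel = inmask.reshape(-1)
    series = bold.data.reshape(-1, T)[sel].astype(np.float64)
    ranks_flat, tie_flat = _rank_and_tiecorr(series)

    ranks = np.zeros(shape + (T,), dtype=np.float64)
    ranks.reshape(-1, T)[sel] = ranks_flat
    ties = np.zeros(shape, dtype=np.float64)
    ties.reshape(-1)[sel] = tie_flat
    m = inmask.astype(np.float64)

    if neighborhood == 27:
        # full-cube stencil is separable: three 1D box sums (exact additions,
        # so the result is identical to the direct 27-offset accumulation)
        R, K, TC = ranks, m, ties
        for axis in range(3):
            R = _box_sum_axis(R, axis)
            K = _box_sum_axis(K, axis)
            TC = _box_sum_axis(TC, axis)
    else:
        R = np.zeros(shape + (T,), dtype=np.float64)
        K = np.zeros(shape, dtype=np.float64)
        TC = np.zeros(shape, dtype=np.float64)
        for off in offsets:
            _shifted_add(R, ranks, off)
            _shifted_add(K, m, off)
            _shifted_add(TC, ties, off)

    S = np.sum((R - K[..., None] * (T + 1) / 2.0) ** 2, axis=-1)
    denom = K * K * (T ** 3 - T) - K * TC
    W = np.zeros(shape, dtype=np.float64)
    valid = inmask & (K >= 2) & (denom > 0)
    if require_full_neighborhood:
        valid &= K == len(offsets)
    W[valid] = 12.0 * S[valid] / denom[valid]
    kmap = np.where(inmask, K, 0.0)
    return ReHoMap(data=W, affine=bold.affine, neighborhood_size=neighborhood,
                   standardized=False, k_map=kmap)


def standardize_global(rmap: ReHoMap, mask: BrainMask) -> ReHoMap:
    """Divide by the in-mask mean so the standardised map averages to 1."""
    mask.check_geometry(rmap)
    mean = rmap.data[mask.data].mean()
    if mean <= 0:
        raise ValueError(f"in-mask mean {mean} not positive; cannot standardize")
    out = np.zeros_like(rmap.data)
    out[mask.data] = rmap.data[mask.data] / mean
    return ReHoMap(data=out, affine=rmap.affine,
                   neighborhood_size=rmap.neighborhood_size,
                   standardized=True, k_map=rmap.k_map)


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def smooth_gaussian(rmap: ReHoMap, fwhm_mm: float = 8.0,
                    mask: BrainMask | None = None) -> ReHoMap:
    """Masked Gaussian smoothing: smooth map*mask and renormalise by the
    smoothed mask, so constants inside the mask stay constant (no edge
    dilution).  ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ReHoMap(data=rmap.data.copy(), affine=rmap.affine,
                       neighborhood_size=rmap.neighborhood_size,
                       standardized=rmap.standardized, k_map=rmap.k_map)
    sigmas = fwhm_mm / (FWHM_TO_SIGMA * voxel_sizes_mm(rmap.affine))
    if mask is None:
        sm = gaussian_filter(rmap.data, sigma=sigmas)
        return ReHoMap(data=sm, affine=rmap.affine,
                       neighborhood_size=rmap.neighborhood_size,
                       standardized=rmap.standardized, k_map=rmap.k_map)
    mask.check_geometry(rmap)
    m = mask.data.astype(float)
    num = gaussian_filter(rmap.data * m, sigma=sigmas)
    den = gaussian_filter(m, sigma=sigmas)
    out = np.zeros_like(rmap.data)
    inside = mask.data & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return ReHoMap(data=out, affine=rmap.affine,
                   neighborhood_size=rmap.neighborhood_size,
                   standardized=rmap.standardized, k_map=rmap.k_map)


def subject_reho(bold: BoldSeries, mask: BrainMask, neighborhood: int = 27,
                 fwhm_mm: float = 8.0, standardize: bool = True,
                 require_full_neighborhood: bool = False) -> ReHoMap:
    """Full per-subject ReHo chain: KCC map -> global standardisation -> smoothing."""
    rmap = reho_map(bold, mask, neighborhood=neighborhood,
                    require_full_neighborhood=require_full_neighborhood)
    if standardize:
        rmap = standardize_global(rmap, mask)
    if fwhm_mm > 0:
        rmap = smooth_gaussian(rmap, fwhm_mm=fwhm_mm, mask=mask)
    return rmap
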