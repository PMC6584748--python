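"""Group-level voxelwise inference and clinical statistics.

Two-sample pooled-variance t-maps (patients minus controls), cluster forming
at an uncorrected voxel threshold with a minimum extent, cluster-level
family-wise-error control via the permutation distribution of the maximum
supra-threshold cluster extent, ROI extraction, Pearson correlations with
clinical scores, and the demographic chi-square / t tests of a standard
case-control characteristics table.

The FWE mechanism: under the null the group labels are exchangeable, so
relabelling subjects and recording the maximum cluster extent (over both
contrast directions) per relabelling yields the null distribution of the most
extreme cluster anywhere in the volume; comparing each observed cluster's
extent against it controls the FWE rate across all reported clusters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import BrainMask
from .reho import ReHoMap

logger = logging.getLogger(__name__)


@dataclass
class StatMap:
    """Voxelwise two-sample t statistics with their degrees of freedom."""

    t_values: np.ndarray
    df: int
    affine: np.ndarray
    mask: BrainMask


@dataclass
class ClusterResult:
    """One supra-threshold cluster: members, extent, peak, sign, FWE p."""

    voxel_members: np.ndarray  # (extent, 3) int voxel indices
    extent: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    sign: str  # "positive" (A > B) or "negative"
    fwe_p: float = 1.0


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float
    x_name: str = "x"
    y_name: str = "y"


def _stack(maps: list[ReHoMap], mask: BrainMask) -> np.ndarray:
    """N x V matrix of in-mask values, geometry-checked."""
    for m in maps:
        mask.check_geometry(m)
    sel = mask.data.reshape(-1)
    return np.stack([m.data.reshape(-1)[sel] for m in maps])


def _tmap_from_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; zero-variance columns -> 0."""
    nA, nB = A.shape[0], B.shape[0]
    mA, mB = A.mean(axis=0), B.mean(axis=0)
    ssA = ((A - mA) ** 2).sum(axis=0)
    ssB = ((B - mB) ** 2).sum(axis=0)
    sp2 = (ssA + ssB) / (nA + nB - 2)
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mA - mB) / denom, 0.0)
    return t


def voxelwise_ttest(maps_A: list[ReHoMap], maps_B: list[ReHoMap],
                    mask: BrainMask) -> StatMap:
    """Pooled two-sample t per in-mask voxel, oriented A - B (patients - controls)."""
    if len(maps_A) < 2 or len(maps_B) < 2:
        raise ValueError("need at least 2 subjects per group")
    A = _stack(maps_A, mask)
    B = _stack(maps_B, mask)
    t_flat = _tmap_from_rows(A, B)
    if np.any((A.std(axis=0) == 0) & (B.std(axis=0) == 0)):
        warnings.warn("zero-variance voxels set to t = 0")
    t = np.zeros(mask.data.shape)
    t[mask.data] = t_flat
    return StatMap(t_values=t, df=len(maps_A) + len(maps_B) - 2,
                   affine=maps_A[0].affine, mask=mask)


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _clusters_one_sign(t: np.ndarray, cutoff: float, sign: str, min_extent: int,
                       struct: np.ndarray, affine: np.ndarray) -> list[ClusterResult]:
    supra = t > cutoff if sign == "positive" else t < -cutoff
    labels, n_lab = ndimage.label(supra, structure=struct)
    out = []
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        if len(members) < min_extent:
            continue
        vals = t[tuple(members.T)]
        peak_idx = int(np.argmax(vals)) if sign == "positive" else int(np.argmin(vals))
        peak_voxel = tuple(int(v) for v in members[peak_idx])
        peak_mm = tuple((np.asarray(affine) @ np.array(peak_voxel + (1,)))[:3])
        out.append(ClusterResult(voxel_members=members, extent=len(members),
                                 peak_t=float(vals[peak_idx]), peak_voxel=peak_voxel,
                                 peak_mm=peak_mm, sign=sign))
    out.sort(key=lambda c: -c.extent)
    return out


def form_clusters(stat: StatMap, voxel_p: float = 0.001, min_extent: int = 100,
                  connectivity: int = 18) -> list[ClusterResult]:
    """Connected supra-threshold components per sign, extent-filtered.

    The voxel threshold is the one-tailed |t| cutoff at ``voxel_p`` applied to
    each contrast direction separately.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    cutoff = float(stats.t.isf(voxel_p, stat.df))
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    clusters = []
    for sign in ("positive", "negative"):
        clusters.extend(_clusters_one_sign(stat.t_values, cutoff, sign,
                                           min_extent, struct, stat.affine))
    return clusters


def _max_extent(t: np.ndarray, cutoff: float, struct: np.ndarray) -> int:
    """Largest supra-threshold cluster extent over both signs (0 if none)."""
    best = 0
    for supra in (t > cutoff, t < -cutoff):
        labels, n_lab = ndimage.label(supra, structure=struct)
        if n_lab:
            best = max(best, int(np.bincount(labels.reshape(-1))[1:].max()))
    return best


def cluster_fwe(maps_A: list[ReHoMap], maps_B: list[ReHoMap], mask: BrainMask,
                voxel_p: float = 0.001, min_extent: int = 100,
                connectivity: int = 18, n_perm: int = 1000,
                seed: int = 0) -> list[ClusterResult]:
    """Observed clusters with permutation-based cluster-level FWE p-values.

    The null is the maximum supra-threshold cluster extent (over both contrast
    directions) across ``n_perm`` random relabelings of the group labels;
    ``fwe_p = (1 + #{null >= observed extent}) / (n_perm + 1)``.  When the
    number of distinct relabelings is at most ``n_perm`` the permutation space
    is enumerated exactly instead (the identity counts, so p > 0).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse FWE p-value resolution")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A = _stack(maps_A, mask)
    B = _stack(maps_B, mask)
    nA, nB = A.shape[0], B.shape[0]
    allmaps = np.vstack([A, B])
    df = nA + nB - 2
    cutoff = float(stats.t.isf(voxel_p, df))
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    shape = mask.data.shape
    sel = mask.data

    def tvol(rows_A: np.ndarray) -> np.ndarray:
        in_A = np.zeros(nA + nB, dtype=bool)
        in_A[rows_A] = True
        t = np.zeros(shape)
        t[sel] = _tmap_from_rows(allmaps[in_A], allmaps[~in_A])
        return t

    observed_t = tvol(np.arange(nA))
    stat = StatMap(t_values=observed_t, df=df, affine=maps_A[0].affine, mask=mask)
    clusters = form_clusters(stat, voxel_p=voxel_p, min_extent=min_extent,
                             connectivity=connectivity)

    n_distinct = math.comb(nA + nB, nA)
    if n_distinct <= n_perm:
        null = np.array([
            _max_extent(tvol(np.array(rows)), cutoff, struct)
            for rows in combinations(range(nA + nB), nA)
        ])
        for c in clusters:
            c.fwe_p = float((null >= c.extent).sum()) / n_distinct
        logger.info("cluster FWE: enumerated all %d relabelings", n_distinct)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            rows_A = rng.choice(nA + nB, size=nA, replace=False)
            null[i] = _max_extent(tvol(rows_A), cutoff, struct)
        for c in clusters:
            c.fwe_p = float(1 + (null >= c.extent).sum()) / (n_perm + 1)
    return clusters


def roi_mean(rmap: ReHoMap, roi: np.ndarray) -> float:
    """Arithmetic mean of a map over a boolean ROI volume or (n,3) index array."""
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if not roi.any():
            raise ValueError("empty ROI")
        return float(rmap.data[roi].mean())
    if roi.ndim != 2 or roi.shape[1] != 3 or len(roi) == 0:
        raise ValueError("ROI must be a boolean volume or nonempty (n, 3) indices")
    return float(rmap.data[tuple(roi.T)].mean())


def pearson_with_p(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with the two-tailed p from t = r sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=n, p_two_tailed=pearson_p_from_r(r, n),
                             x_name=x_name, y_name=y_name)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p of a Pearson correlation from its printed (r, n)."""
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must be in [-1, 1]")
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclass
class DemographicTests:
    gender_chi2: float
    gender_p: float
    age_t: float
    age_p: float


def chi2_gender(n_male_A: int, n_female_A: int, n_male_B: int, n_female_B: int,
                correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 gender table (no Yates correction by default)."""
    table = np.array([[n_male_A, n_female_A], [n_male_B, n_female_B]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("gender table has an empty row or column")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def ttest_from_summary(mean_A: float, sd_A: float, n_A: int,
                       mean_B: float, sd_B: float, n_B: int) -> tuple[float, float]:
    """Pooled two-sample t and two-tailed p from summary statistics."""
    res = stats.ttest_ind_from_stats(mean_A, sd_A, n_A, mean_B, sd_B, n_B,
                                     equal_var=True)
    return float(res.statistic), float(res.pvalue)


def demographics(table: pd.DataFrame, correction: bool = False) -> DemographicTests:
    """Gender chi-square and pooled age t-test between patients and controls."""
    pat = table[table["group"] == "patient"]
    con = table[table["group"] == "control"]
    if len(pat) == 0 or len(con) == 0:
        raise ValueError("both groups must be present")
    chi2, chi2_p = chi2_gender((pat["gender"] == "M").sum(), (pat["gender"] == "F").sum(),
                               (con["gender"] == "M").sum(), (con["gender"] == "F").sum(),
                               correction=correction)
    res = stats.ttest_ind(pat["age"].to_numpy(float), con["age"].to_numpy(float),
                          equal_var=True)
    return DemographicTests(gender_chi2=chi2, gender_p=chi2_p,
                            age_t=float(res.statistic), age_p=float(res.pvalue))


def clinical_correlations(roi_values: np.ndarray, table: pd.DataFrame,
                          score_columns=("ybocs_total", "obsessions", "compulsions",
                                         "hamd", "hama", "duration_years"),
                          roi_name: str = "roi") -> pd.DataFrame:
    """Pearson correlations of an ROI measure with each clinical score (patients).

    ``roi_values`` aligns with the patient rows of ``table``; pairs with a
    missing score are dropped per correlation.  Reported uncorrected.
    """
    pat = table[table["group"] == "patient"]
    rows = []
    for col in score_columns:
        if col not in pat.columns:
            continue
        y = pat[col].to_numpy(float)
        keep = np.isfinite(y) & np.isfinite(roi_values)
        if keep.sum() < 3 or np.std(y[keep]) == 0:
            continue
        res = pearson_with_p(roi_values[keep], y[keep], x_name=roi_name, y_name=col)
        rows.append({"roi": roi_name, "score": col, "r": res.r, "n": res.n,
                     "p": res.p_two_tailed})
    return pd.DataFrame(rows)


def clusters_to_table(clusters: list[ClusterResult]) -> pd.DataFrame:
    """Cluster summary table (sign, extent, peak t, peak mm, FWE p)."""
    rows = [{
        "sign": c.sign, "extent": c.extent, "peak_t": c.peak_t,
        "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1], "peak_z_mm": c.peak_mm[2],
        "fwe_p": c.fwe_p,
    } for c in clusters]
    return pd.DataFrame(rows, columns=["sign", "extent", "peak_t", "peak_x_mm",
                                       "peak_y_mm", "peak_z_mm", "fwe_p"])
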