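"""Reusable simulation studies over the pipeline.

Each function runs a self-contained Monte-Carlo experiment on synthetic
cohorts — null calibration of the ReHo statistic and of the cluster-extent
FWE procedure, calibration of the MVPA permutation p-value, planted-effect
recovery at the default study conditions, and the clinical-correlation link —
and returns plain numbers.  The analysis drivers, the test suite and the
results-reproduction script all call these, so every reported figure comes
from one code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import BoldSeries, BrainMask
from .mvpa import FeatureMatrix, build_features, permutation_test, svm_loocv
from .preprocess import preprocess_bold
from .reho import reho_map, subject_reho
from .synth import RoiSpec, SyntheticConfig, make_cohort, roi_voxels
from .univariate import cluster_fwe, pearson_with_p


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def null_reho_mean(shape=(16, 16, 16), n_timepoints: int = 200,
                   neighborhood: int = 27, seed: int = 0) -> float:
    """Mean in-mask ReHo of an i.i.d. Gaussian-noise volume.

    Under independence Kendall's W over K raters has expectation 1/K.  The
    mean is taken over voxels with a complete stencil (edge voxels have a
    smaller effective K and hence a larger null W, which would bias the check
    of the stated K).
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(tuple(shape) + (n_timepoints,))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    bold = BoldSeries(data=data, affine=affine, tr_seconds=2.0, subject_id="null")
    mask = BrainMask(data=np.ones(shape, dtype=bool), affine=affine)
    rmap = reho_map(bold, mask, neighborhood=neighborhood)
    full = rmap.k_map == neighborhood
    return float(rmap.data[full].mean())


def _null_config(shape, n_timepoints, n_per_group, seed) -> SyntheticConfig:
    """Cohort config with no planted effect (no ROI: both groups identical)."""
    return SyntheticConfig(shape=shape, n_timepoints=n_timepoints,
                           n_per_group=n_per_group, rois=(), seed=seed)


def fwe_type_i_rate(n_datasets: int = 200, shape=(12, 12, 12),
                    n_timepoints: int = 100, n_per_group: int = 8,
                    n_perm: int = 200, voxel_p: float = 0.001,
                    min_extent: int = 5, connectivity: int = 18,
                    seed: int = 0) -> dict:
    """Fraction of null datasets with any FWE-significant cluster at 0.05.

    Both groups are drawn from the same generative distribution, so any
    cluster with fwe_p < 0.05 is a false positive.  The grid, group size and
    minimum extent are scaled down so the study fits in minutes; the
    permutation mechanism under test is unchanged.
    """
    seeds = _seeds(seed, n_datasets)
    hits = 0
    for s in seeds:
        cfg = _null_config(shape, n_timepoints, n_per_group, int(s))
        bolds, _, cohort, brain, _ = make_cohort(cfg)
        maps = [reho_map(b, brain) for b in bolds]
        is_pat = (cohort["group"] == "patient").to_numpy()
        maps_A = [m for m, p in zip(maps, is_pat) if p]
        maps_B = [m for m, p in zip(maps, is_pat) if not p]
        clusters = cluster_fwe(maps_A, maps_B, brain, voxel_p=voxel_p,
                               min_extent=min_extent, connectivity=connectivity,
                               n_perm=n_perm, seed=int(s) + 1)
        if any(c.fwe_p < 0.05 for c in clusters):
            hits += 1
    return {"false_positive_rate": hits / n_datasets, "n_datasets": n_datasets,
            "n_hits": hits}


def mvpa_null_pvalues(n_datasets: int = 100, n_per_group: int = 8,
                      n_features: int = 60, n_perm: int = 99,
                      seed: int = 0) -> dict:
    """Permutation p-values of the SVM LOOCV accuracy on label-exchangeable data.

    Features are pure noise, so p should be ~uniform; reported is the fraction
    of datasets with p <= 0.05 (nominal false-positive rate of the MVPA test).
    """
    seeds = _seeds(seed, n_datasets)
    pvals = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        n = 2 * n_per_group
        X = rng.standard_normal((n, n_features))
        labels = np.array([1] * n_per_group + [-1] * n_per_group)
        voxel_index = np.column_stack([np.arange(n_features),
                                       np.zeros(n_features, int),
                                       np.zeros(n_features, int)])
        feats = FeatureMatrix(matrix=X, voxel_index=voxel_index, labels=labels,
                              subject_ids=[f"s{i}" for i in range(n)],
                              affine=np.eye(4), shape3d=(n_features, 1, 1))
        p = permutation_test(feats, n_perm=n_perm, seed=int(s) + 1)
        pvals.append(p)
    pvals = np.array(pvals)
    return {"p_values": pvals,
            "fraction_below_05": float((pvals <= 0.05).mean()),
            "n_datasets": n_datasets}


@dataclass
class RecoveryRun:
    found_in_roi: bool
    n_significant: int
    best_fwe_p: float
    peak_in_roi: bool


def _cohort_reho_maps(cfg: SyntheticConfig, fwhm_mm: float = 8.0):
    """Generate, QC-free preprocess, and map one cohort; returns maps + metadata."""
    bolds, motions, cohort, brain, tissue = make_cohort(cfg)
    maps = []
    for bold, motion in zip(bolds, motions):
        clean = preprocess_bold(bold, motion, brain,
                                csf=tissue["csf"], wm=tissue["wm"])
        maps.append(subject_reho(clean, brain, fwhm_mm=fwhm_mm))
    return maps, cohort, brain


def planted_cluster_recovery(n_runs: int = 20, n_perm: int = 200,
                             seed: int = 0, config: SyntheticConfig | None = None,
                             fwhm_mm: float = 8.0) -> dict:
    """Planted-ROI recovery rate of the univariate stage at default conditions.

    For each seeded cohort (default 24^3 grid, 200 frames, 20+20 subjects, one
    ROI with patient/control synchrony 0.45/0.25) the full chain
    preprocess -> ReHo -> cluster-extent FWE is run; a success is an
    FWE-significant cluster (p < 0.05) overlapping the planted ROI.
    """
    base = config or SyntheticConfig()
    roi = roi_voxels(base, base.rois[0].name)
    runs: list[RecoveryRun] = []
    for s in _seeds(seed, n_runs):
        cfg = dataclasses.replace(base, seed=int(s))
        maps, cohort, brain = _cohort_reho_maps(cfg, fwhm_mm=fwhm_mm)
        is_pat = (cohort["group"] == "patient").to_numpy()
        maps_A = [m for m, p in zip(maps, is_pat) if p]
        maps_B = [m for m, p in zip(maps, is_pat) if not p]
        clusters = cluster_fwe(maps_A, maps_B, brain, n_perm=n_perm,
                               seed=int(s) + 1)
        sig = [c for c in clusters if c.fwe_p < 0.05]
        in_roi = [c for c in sig
                  if roi[tuple(c.voxel_members.T)].any()]
        peak_in = any(roi[c.peak_voxel] for c in in_roi)
        runs.append(RecoveryRun(
            found_in_roi=bool(in_roi),
            n_significant=len(sig),
            best_fwe_p=min((c.fwe_p for c in clusters), default=1.0),
            peak_in_roi=peak_in,
        ))
    rate = float(np.mean([r.found_in_roi for r in runs]))
    return {"recovery_rate": rate, "n_runs": n_runs, "runs": runs}


def svm_recovery(seed: int = 0, n_perm: int = 199, n_cohorts: int = 5,
                 config: SyntheticConfig | None = None) -> dict:
    """LOOCV SVM performance at the default planted-effect conditions.

    Accuracy/sensitivity/specificity (percent) and AUC are averaged over
    ``n_cohorts`` independent cohort draws (a single 20+20 draw carries a few
    percent of sampling noise); the label-permutation test runs on the first
    cohort, where the strong planted effect saturates the p-value at its
    minimum 1/(n_perm + 1).
    """
    base = config or SyntheticConfig()
    accs, sens, specs, aucs = [], [], [], []
    perm_p = None
    for s in _seeds(seed, n_cohorts):
        cfg = dataclasses.replace(base, seed=int(s))
        maps, cohort, brain = _cohort_reho_maps(cfg)
        labels = np.where((cohort["group"] == "patient").to_numpy(), 1, -1)
        feats = build_features(maps, brain, labels,
                               subject_ids=list(cohort["id"]))
        report = svm_loocv(feats, seed=int(s))
        accs.append(report.accuracy)
        sens.append(report.sensitivity)
        specs.append(report.specificity)
        aucs.append(report.auc)
        if perm_p is None:
            perm_p = permutation_test(feats, n_perm=n_perm, seed=int(s) + 1,
                                      observed_accuracy=report.accuracy)
    return {"accuracy": float(np.mean(accs)), "sensitivity": float(np.mean(sens)),
            "specificity": float(np.mean(specs)), "auc": float(np.mean(aucs)),
            "per_cohort_accuracy": accs, "n_cohorts": n_cohorts,
            "permutation_p": perm_p, "n_perm": n_perm,
            "min_attainable_p": 1.0 / (n_perm + 1)}


def clinical_link_correlation(n_draws: int = 50, n_per_group: int = 88,
                              seed: int = 0) -> dict:
    """Sample correlation between measured ROI ReHo and the linked symptom score.

    Uses a small grid (the link calibration depends on group size, not volume
    size) with the default link slope/noise targeting r ~ 0.24 at n = 88
    patients; returns the per-draw sample correlations and their mean.
    """
    base = SyntheticConfig(
        shape=(10, 10, 10), n_timepoints=100, n_per_group=n_per_group,
        rois=(RoiSpec("sfg", (4, 4, 4), 2, 0.25, 0.45),),
        global_amp=0.0, drift_sd=0.0, tissue_amp=0.0,
    )
    roi = roi_voxels(base, "sfg")
    rs = []
    for s in _seeds(seed, n_draws):
        cfg = dataclasses.replace(base, seed=int(s))
        bolds, _, cohort, brain, _ = make_cohort(cfg)
        is_pat = (cohort["group"] == "patient").to_numpy()
        vals, scores = [], []
        for bold, (_, row) in zip(bolds, cohort.iterrows()):
            if row["group"] != "patient":
                continue
            rmap = reho_map(bold, brain)
            vals.append(rmap.data[roi].mean())
            scores.append(row["ybocs_total"])
        res = pearson_with_p(np.array(vals), np.array(scores))
        rs.append(res.r)
    rs = np.array(rs)
    return {"mean_r": float(rs.mean()), "sd_r": float(rs.std()),
            "r_values": rs, "n_draws": n_draws, "n_patients": n_per_group}
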