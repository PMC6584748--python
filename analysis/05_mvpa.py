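#!/usr/bin/env python
"""Multivariate classification of the standardised ReHo maps.

Linear SVM (C = 1) on all in-mask voxels, leave-one-subject-per-group-out
cross-validation, 1,000-permutation significance test, ROC, and the
discriminative map of the top 30% |weight| voxels.

Writes results/svm_report.json, results/roc_points.csv,
results/discriminative_peaks.csv; weight maps go to scratch/mvpa/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rehopipe.io import read_cohort, read_map, read_mask, write_map
from rehopipe.mvpa import (build_features, discriminative_map,
                           discriminative_peaks, permutation_test, svm_loocv)
from rehopipe.reho import ReHoMap

IN, REHO, OUT, RESULTS = (Path("scratch/cohort"), Path("scratch/reho"),
                          Path("scratch/mvpa"), Path("results"))
SEED = 2026


def main():
    cohort = read_cohort(IN / "cohort.csv")
    brain = read_mask(IN / "brain_mask.nii.gz")
    maps, labels, ids = [], [], []
    for _, rec in cohort.iterrows():
        path = REHO / f"{rec['id']}_szreho.nii.gz"
        if path.exists():
            data, affine = read_map(path)
            maps.append(ReHoMap(data=data, affine=affine, standardized=True))
            labels.append(1 if rec["group"] == "patient" else -1)
            ids.append(rec["id"])
    feats = build_features(maps, brain, np.array(labels), subject_ids=ids)
    print(f"feature matrix: {feats.matrix.shape[0]} subjects x "
          f"{feats.matrix.shape[1]} voxels")

    report = svm_loocv(feats, C=1.0, seed=SEED)
    report.permutation_p = permutation_test(feats, n_perm=1000, seed=SEED,
                                            observed_accuracy=report.accuracy)
    summary = {"accuracy_percent": report.accuracy,
               "sensitivity_percent": report.sensitivity,
               "specificity_percent": report.specificity,
               "auc": report.auc,
               "permutation_p": report.permutation_p,
               "n_permutations": 1000}
    OUT.mkdir(parents=True, exist_ok=True)
    with open(RESULTS / "svm_report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        RESULTS / "roc_points.csv", index=False)
    write_map(report.weight_map, brain.affine, OUT / "weight_map.nii.gz")
    dmap = discriminative_map(report.weight_map[brain.data], feats.voxel_index,
                              feats.shape3d, fraction=0.30)
    write_map(dmap.weights, brain.affine, OUT / "discriminative_map.nii.gz")
    peaks = discriminative_peaks(dmap, brain.affine, top=10)
    peaks.to_csv(RESULTS / "discriminative_peaks.csv", index=False)
    print(json.dumps(summary, indent=2, sort_keys=True))
    print("\ntop discriminative voxels (mm, signed weight):")
    print(peaks.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
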