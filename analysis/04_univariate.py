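#!/usr/bin/env python
"""Group inference: two-sample t-maps with cluster-extent permutation FWE,
ROI extraction and clinical correlations.

Voxel threshold p < 0.001, minimum extent 100 voxels, cluster-level FWE by
the permutation distribution of the maximum supra-threshold cluster extent
(1,000 relabelings).  Significant clusters become ROIs whose patient-wise
mean standardised ReHo is correlated with the clinical scores.

Writes results/clusters.csv, results/clinical_correlations.csv,
results/demographics.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rehopipe.io import read_cohort, read_map, read_mask
from rehopipe.reho import ReHoMap
from rehopipe.univariate import (clinical_correlations, cluster_fwe,
                                 clusters_to_table, demographics, roi_mean)

IN, REHO, RESULTS = Path("scratch/cohort"), Path("scratch/reho"), Path("results")
SEED = 2026


def main():
    cohort = read_cohort(IN / "cohort.csv")
    brain = read_mask(IN / "brain_mask.nii.gz")
    maps, kept = [], []
    for _, rec in cohort.iterrows():
        path = REHO / f"{rec['id']}_szreho.nii.gz"
        if path.exists():
            data, affine = read_map(path)
            maps.append(ReHoMap(data=data, affine=affine, standardized=True))
            kept.append(rec)
    kept = pd.DataFrame(kept).reset_index(drop=True)
    is_pat = (kept["group"] == "patient").to_numpy()
    maps_A = [m for m, p in zip(maps, is_pat) if p]
    maps_B = [m for m, p in zip(maps, is_pat) if not p]
    print(f"{len(maps_A)} patients vs {len(maps_B)} controls")

    clusters = cluster_fwe(maps_A, maps_B, brain, voxel_p=0.001, min_extent=100,
                           connectivity=18, n_perm=1000, seed=SEED)
    table = clusters_to_table(clusters)
    table.to_csv(RESULTS / "clusters.csv", index=False)
    print(table.to_string(index=False) if len(table) else "no clusters survive")

    demo = demographics(kept)
    pd.DataFrame([{"gender_chi2": demo.gender_chi2, "gender_p": demo.gender_p,
                   "age_t": demo.age_t, "age_p": demo.age_p}]).to_csv(
        RESULTS / "demographics.csv", index=False)

    sig = [c for c in clusters if c.fwe_p < 0.05]
    frames = []
    pat_maps = [m for m, p in zip(maps, is_pat) if p]
    for j, c in enumerate(sig):
        vals = np.array([roi_mean(m, c.voxel_members) for m in pat_maps])
        frames.append(clinical_correlations(vals, kept,
                                            roi_name=f"cluster{j}_{c.sign}"))
    corr = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["roi", "score", "r", "n", "p"]))
    corr.to_csv(RESULTS / "clinical_correlations.csv", index=False)
    if len(corr):
        print("\nclinical correlations of significant-cluster mean ReHo (patients):")
        print(corr.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
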