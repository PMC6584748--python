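#!/usr/bin/env python
"""Generate the synthetic study cohort.

Two groups of 20 subjects on a 24^3 grid of 3 mm voxels, 200 frames at
TR = 2 s, one planted region ("sfg", radius 3 voxels = 123 voxels) with
neighbourhood synchrony 0.45 in patients vs 0.25 in controls over a 0.10
background, two planted bad movers, and realistic clinical scores whose
Y-BOCS total is linked to each patient's latent ROI synchrony.

Volumes and motion files go to scratch/cohort/ (large, regenerable);
the cohort table and a demographic summary go to results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from rehopipe.io import write_bold, write_cohort, write_map, write_motion
from rehopipe.synth import SyntheticConfig, make_cohort
from rehopipe.univariate import demographics

SEED = 2026
OUT = Path("scratch/cohort")
RESULTS = Path("results")


def main():
    cfg = dataclasses.replace(SyntheticConfig(), seed=SEED, n_bad_movers=2)
    print(f"simulating {2 * cfg.n_per_group} subjects, shape {cfg.shape}, "
          f"T={cfg.n_timepoints}, seed={cfg.seed}")
    bolds, motions, cohort, brain, tissue = make_cohort(cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_map(brain.data, brain.affine, OUT / "brain_mask.nii.gz")
    for name, m in tissue.items():
        write_map(m.data, m.affine, OUT / f"{name}_mask.nii.gz")
    for bold, motion in zip(bolds, motions):
        write_bold(bold, OUT / f"{bold.subject_id}_bold.nii.gz")
        write_motion(motion, OUT / f"rp_{motion.subject_id}.txt")
    write_cohort(cohort, OUT / "cohort.csv")
    write_cohort(cohort, RESULTS / "cohort.csv")

    demo = demographics(cohort)
    pat = cohort[cohort.group == "patient"]
    con = cohort[cohort.group == "control"]
    summary = pd.DataFrame([
        {"characteristic": "n", "patients": len(pat), "controls": len(con)},
        {"characteristic": "age_mean", "patients": pat.age.mean().round(2),
         "controls": con.age.mean().round(2)},
        {"characteristic": "male_fraction",
         "patients": (pat.gender == "M").mean().round(3),
         "controls": (con.gender == "M").mean().round(3)},
        {"characteristic": "ybocs_total_mean",
         "patients": pat.ybocs_total.mean().round(2), "controls": None},
        {"characteristic": "gender_chi2", "patients": round(demo.gender_chi2, 3),
         "controls": round(demo.gender_p, 3)},
        {"characteristic": "age_t", "patients": round(demo.age_t, 3),
         "controls": round(demo.age_p, 3)},
    ])
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote volumes to {OUT}/, tables to {RESULTS}/")


if __name__ == "__main__":
    main()
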