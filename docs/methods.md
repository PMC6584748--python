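# Methods

This note documents the models, parameter choices and numerical decisions
behind `rehopipe`, and what the synthetic studies do and do not establish.

## Synthetic cohort model

Each subject's 4D BOLD volume is built from zero-mean, unit-variance
band-limited (0.01–0.08 Hz) Gaussian series.  A voxel `v` in region `r` gets

    x_v(t) = sqrt(rho_r) * s_r(t) + sqrt(1 - rho_r) * e_v(t)

with one shared driver `s_r` per region and i.i.d. noise `e_v`.  Any two
voxels of the same region then correlate at exactly `rho_r`, and Kendall's W
over a neighbourhood is monotone in `rho_r` — the minimal generative
counterpart of "local synchrony", which is what ReHo measures.  Regions are
the planted spherical ROIs plus eight background octants (so even background
synchrony is local, not global).  On top of the synchrony signal each voxel
receives a baseline of 100 with signal SD 2 (percent-scale BOLD units), a
shared global fluctuation (amplitude 0.5), a per-voxel random linear drift
(slope SD 0.5 over the run), and a tissue driver (amplitude 1.0) inside the
CSF/WM compartments — precisely the components nuisance regression,
detrending and band-passing are supposed to remove.

Groups differ only through the planted-ROI synchrony: controls sit exactly at
`rho_control`; patients are drawn `Normal(rho_patient, 0.06)` (clipped to
[0, 0.95]).  The patient-side scatter is the latent severity `z_i`
(standardised across patients) that the primary symptom score is linked to:

    ybocs_total_i = 21.5 + slope * z_i + Normal(0, noise_sd)

with `slope = 1.4`, `noise_sd = 5.2`, chosen so the score SD is ~5.4 (the
population value the clinical marginals emulate) and the population
correlation between score and latent synchrony is `1.4 / 5.39 = 0.26`;
after attenuation by ReHo measurement noise the measured correlation sits
near 0.24 at n = 88 patients.  The obsession subscale is linked to the same
latent with a proportionally scaled slope; the remaining clinical scores are
independent draws around their population means.  Controls carry no symptom
scores.

Motion is a bounded random walk (translation step SD 0.02 mm, rotation step
SD 0.0002 rad, clipped at ±1.2 mm / ±1.15°), which keeps ordinary subjects
well inside the exclusion limits with mean FD around 0.07 mm.  A planted
"bad mover" has the second half of the run shifted so the x-translation hits
exactly 2.0 mm — guaranteed to violate the 1.5 mm rule.  Motion traces drive
QC and the nuisance design only; the BOLD volumes themselves contain no
motion artifact.

**Defaults** (the study conditions): 24×24×24 grid of 3 mm voxels, 200
frames at TR = 2 s, 20 subjects per group, one ROI of radius 3 voxels
(123 voxels) with synchrony 0.45 (patients) vs 0.25 (controls) over a 0.10
background.  The grid size keeps a full pipeline run under a minute per
cohort while leaving room for 100-voxel cluster extents; the ROI size is
chosen so the planted cluster can clear the 100-voxel minimum extent.

**What the generator does not emulate:** spatial correlation of the noise
(beyond the shared drivers), physiological (cardiac/respiratory) noise,
motion-induced intensity artifacts, registration error, anatomical tissue
geometry, or site/scanner effects.  Passing tests therefore establish the
*statistical* correctness of each stage (calibration, recovery, invariances)
on data satisfying the stages' assumptions — not robustness to the artifact
structure of real scans.

## Preprocessing

Stage order is nuisance regression → linear detrend → ideal band-pass,
applied per voxel with one OLS solve per design.  The nuisance design is the
Friston-24 motion expansion ([R_t, R_{t−1}, R_t², R_{t−1}²], lagged rows
zero-filled at t = 1), CSF mean, WM mean, global mean and a constant.
Exact-duplicate and numerically-zero columns are dropped (a zero motion
trace collapses 24 columns to one); a genuinely rank-deficient design is an
error.

Framewise displacement is the Power variant: backward differences, absolute
translations plus rotations converted to arc length on a 50 mm sphere
(radius configurable).  QC limits are strict: movement ≥ 1.5 mm or ≥ 1.5° in
any direction, or mean FD ≥ 0.2, excludes the subject (the inclusion rules
are written as strict inequalities, so equality at the boundary fails).

The band-pass is an ideal DFT mask (bins with 0.01 ≤ f ≤ 0.08 Hz kept, DC
removed, inclusive edges) — zero-phase and idempotent, matching the
DFT-based filters of the classic resting-state toolchains rather than a
Butterworth roll-off.

Band-passing residuals reintroduces a small correlation with the regressors
(regression protected the full-band columns, the filter then removed only
part of each series), so the composed `preprocess_bold` finishes by
orthogonalising against the *band-limited projections* of the design columns
and the linear ramp.  This is the filter-the-regressors-with-the-data
recommendation from the nuisance-regression literature, and it makes the
composed pipeline an exact projector: re-running it on its own output changes
nothing (verified to < 1e-8; in practice ~1e-11).  The standalone stage
functions keep their plain definitions.

## ReHo / Kendall's W

`kcc` uses mid-ranks with the standard tie correction:

    W = 12 * sum_t (R_t − K(T+1)/2)² / (K²(T³−T) − K·ΣT_j),   T_j = Σ(t³−t).

All-constant input (denominator 0) is defined as W = 0 with a warning.  The
voxelwise map ranks every in-mask series once and accumulates neighbourhood
rank sums by shifted adds (for the 27-stencil, three separable radius-1 box
sums).  Because ranks are multiples of ½ and every intermediate sum stays far
below 2^53, all sums are exact in double precision regardless of summation
order — so the map agrees **bit-for-bit** with voxel-by-voxel application of
`kcc`, which the tests assert with zero tolerance.

Edge handling: neighbours outside the mask are simply excluded, so the
effective K varies at mask borders and is recorded per voxel (`k_map`);
voxels with fewer than 2 in-mask members get 0.  The strict alternative
(`require_full_neighborhood`) zeroes voxels with clipped stencils instead.
Null calibration checks (E[W] = 1/K) are evaluated over complete-stencil
voxels, since edge voxels legitimately sit at 1/K_eff > 1/27.

Standardisation divides by the in-mask mean (idempotent, mean exactly 1);
smoothing is a masked Gaussian — smooth(map·mask)/smooth(mask) inside the
mask — with σ = FWHM / (2√(2 ln 2) · voxel size) per axis, so constants are
preserved and the in-mask mean stays ≈ 1 after smoothing.  Order:
standardise, then smooth.

## Univariate inference

Voxelwise pooled-variance two-sample t (patients − controls); zero-variance
voxels get t = 0 with a warning.  Clusters form per contrast direction at the
one-tailed |t| cutoff for p < 0.001 under 18-connectivity (6/26
configurable), with a 100-voxel minimum extent.

Cluster-level FWE is by permutation: each relabelling of the group
assignment yields a t-map, and the **maximum supra-threshold cluster extent
over both directions** is recorded; a cluster's FWE p is
`(1 + #{null ≥ extent}) / (n_perm + 1)`.  Pooling the two directions into
one maximum is deliberate — testing each direction against its own null at
α would give a family-wise rate of up to 2α across the two contrasts,
whereas the pooled maximum controls the whole family at the nominal level
(the type-I study confirms ~5%).  When fewer than `n_perm` distinct
relabelings exist they are enumerated exactly; note that with equal group
sizes the complement relabelling always ties the observed two-sided
statistic, so the exact minimum p is 2/N rather than 1/N.

Clinical correlations are Pearson r with the two-tailed p from
t = r√(n−2)/√(1−r²) at df = n−2, computed per significant cluster over the
patients' cluster-mean standardised ReHo, reported uncorrected.
Demographics: Pearson chi-square without continuity correction on the 2×2
gender table (a Yates flag exists), pooled two-sample t for age, with a
summary-statistics variant for published-table inputs.

## MVPA

Features are the standardised ReHo values of every in-mask voxel
(subjects × voxels, lexicographic voxel order, invertible back to maps).  The
classifier is a soft-margin linear SVM with **C = 1 and no tuning loop** —
there is no inner search to bias the cross-validated estimate, and the
weight vector is directly interpretable.  Cross-validation leaves out one
patient and one control per fold (positional pairing; a single seeded
permutation shuffles fold order identically for both groups, making fold
composition invariant under a global label flip — an invariance the tests
assert).  Leftover subjects of a larger group get singleton folds.

Significance: each permutation replicate shuffles all labels once and
re-runs the *entire* LOOCV; p = (1 + #{perm accuracy ≥ observed})/(n_perm+1).
The reported weight map is a refit on all subjects (the per-fold mean map is
also computed and its correlation with the refit logged).  The
discriminative map keeps the top 30% of voxels by |w| (ties at the cutoff
broken by voxel order); the alternative reading — threshold at 30% of
max |w| — is available as `value-fraction`.  Positive weights mean higher
ReHo in patients.

## Problem sizes of the validation studies

The Monte-Carlo studies are sized to run on one CPU in minutes: FWE type-I
calibration uses 200 null cohorts on a 12³ grid (8+8 subjects, T = 100, 200
permutations, minimum extent scaled to 5 voxels — on ~900 in-mask voxels a
100-voxel minimum would make the test vacuous); MVPA null calibration uses
100 datasets of 16 subjects × 60 noise features with 99 permutations;
planted-effect recovery runs 20 cohorts at the full default conditions;
the severity-link study uses 50 draws of 88 patients on a 10³ grid (the
link calibration depends on group size, not volume size).  SVM performance
at the default conditions is reported as the mean over 5 cohort draws, since
a single 20+20 split carries several percent of draw-to-draw noise.

## Known limitations

- The permutation FWE assumes exchangeable subjects under the null; it does
  not model per-subject covariates (age/gender regressors are out of scope —
  the group comparison is a plain two-sample test).
- Anatomical labelling of peaks, small-volume correction, and local-maxima
  splitting within clusters are not implemented; cluster tables report the
  single peak per cluster.
- Real-data robustness (motion artifact in the voxel data, physiological
  noise, registration error) is outside what the synthetic studies can show.
- `kcc`'s exact-agreement guarantee relies on double-precision rank sums; it
  holds for any realistic K and T (K·T·T < 2^53) but not for astronomically
  long series.
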