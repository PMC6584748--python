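"""Synthetic two-group resting-state cohort generator.

The generator emulates the data structure of a case-control ReHo study without
any scanner data: 4D BOLD volumes on a small grid with controllable local
temporal synchrony, planted group-difference regions, rigid-body motion traces,
tissue masks for nuisance extraction, and a clinical table whose symptom scores
are linked to the planted synchrony.

Synchrony model
---------------
Every voxel ``v`` belonging to a region ``r`` (a planted ROI, or one octant of
the background) receives

    x_v(t) = sqrt(rho_r) * s_r(t) + sqrt(1 - rho_r) * e_v(t)

where ``s_r`` is one shared band-limited driver per region and ``e_v`` is
i.i.d. band-limited noise, all zero-mean unit-variance.  Neighbouring voxels in
the same region then share correlation exactly ``rho_r``, and Kendall's W over
a neighbourhood increases monotonically with ``rho_r``.  Patients and controls
differ only through the per-group ``rho`` of the planted ROIs.

On top of the synchrony signal each voxel gets a baseline of 100 (typical
normalised BOLD units), a global fluctuation shared brain-wide, a per-voxel
linear drift, and a tissue driver inside the CSF/WM compartments — the
components the nuisance-regression stage is supposed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfft, rfftfreq

from .io import BoldSeries, BrainMask, MotionTrace

__all__ = [
    "RoiSpec",
    "ClinicalLink",
    "SyntheticConfig",
    "make_band_limited_signal",
    "make_subject_bold",
    "make_motion",
    "make_cohort",
]


@dataclass(frozen=True)
class RoiSpec:
    """A spherical planted region with per-group neighbourhood synchrony."""

    name: str
    center_voxel: tuple[int, int, int]
    radius_voxels: int
    rho_control: float
    rho_patient: float

    def __post_init__(self):
        for rho in (self.rho_control, self.rho_patient):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"ROI {self.name}: rho must be in [0, 1), got {rho}")
        if self.radius_voxels < 1:
            raise ValueError(f"ROI {self.name}: radius must be >= 1 voxel")


@dataclass(frozen=True)
class ClinicalLink:
    """Link from a subject's latent ROI synchrony to the primary symptom score.

    ``score_i = intercept + slope * z_i + Normal(0, noise_sd)`` where ``z_i`` is
    the subject's planted-ROI synchrony standardised across patients.  The
    population correlation between score and latent synchrony is therefore
    ``slope / sqrt(slope**2 + noise_sd**2)``.
    """

    roi_name: str = "sfg"
    slope: float = 1.4
    noise_sd: float = 5.2
    intercept: float = 21.5


# population means/SDs emulating a typical adult case-control characteristics table
_CLINICAL_MARGINALS = {
    "obsessions": (13.15, 5.07),
    "compulsions": (8.32, 5.35),
    "hamd": (8.74, 4.92),
    "hama": (8.78, 4.46),
    "duration_years": (7.32, 5.58),
}


def _default_rois() -> tuple[RoiSpec, ...]:
    return (RoiSpec(name="sfg", center_voxel=(8, 8, 15), radius_voxels=3,
                    rho_control=0.25, rho_patient=0.45),)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with small-grid defaults.

    Defaults mirror the emulated acquisition (TR = 2 s, 200 frames, band
    0.01-0.08 Hz) on a 24x24x24 grid of 3 mm voxels, 20 subjects per group,
    one planted ROI with patient synchrony 0.45 vs control 0.25 over a 0.1
    background.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    voxel_size_mm: float = 3.0
    n_per_group: int = 20
    rho_background: float = 0.10
    rho_subject_sd: float = 0.06
    band_hz: tuple[float, float] = (0.01, 0.08)
    rois: tuple[RoiSpec, ...] = field(default_factory=_default_rois)
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    signal_sd: float = 2.0
    global_amp: float = 0.5
    drift_sd: float = 0.5
    tissue_amp: float = 1.0
    motion_sd: float = 0.02
    n_bad_movers: int = 0
    medication_naive_fraction: float = 74 / 88
    male_fraction: float = 56 / 88
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        low, high = self.band_hz
        nyquist = 0.5 / self.tr_seconds
        if not (0.0 <= low < high < nyquist):
            raise ValueError(
                f"band {self.band_hz} invalid for TR={self.tr_seconds}s "
                f"(Nyquist {nyquist} Hz)"
            )
        if not (0.0 <= self.rho_background < 1.0):
            raise ValueError("rho_background must be in [0, 1)")
        if self.n_bad_movers > self.n_per_group:
            raise ValueError("n_bad_movers cannot exceed n_per_group")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        # centre the grid on the origin, like an MNI-style bounding box
        aff[:3, 3] = -self.voxel_size_mm * (np.array(self.shape) - 1) / 2.0
        return aff


def _band_bins(n_timepoints: int, tr_seconds: float, band_hz) -> np.ndarray:
    low, high = band_hz
    nyquist = 0.5 / tr_seconds
    if not (0.0 <= low < high < nyquist):
        raise ValueError(f"band {band_hz} outside (0, {nyquist}) Hz")
    freqs = rfftfreq(n_timepoints, d=tr_seconds)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ValueError(f"no DFT bins inside band {band_hz} at T={n_timepoints}")
    return keep


def _band_limited_batch(rng: np.random.Generator, n_series: int,
                        n_timepoints: int, tr_seconds: float, band_hz) -> np.ndarray:
    """(n_series, T) array of zero-mean unit-variance band-limited series."""
    keep = _band_bins(n_timepoints, tr_seconds, band_hz)
    white = rng.standard_normal((n_series, n_timepoints))
    spectrum = rfft(white, axis=-1)
    spectrum[:, ~keep] = 0.0
    x = irfft(spectrum, n=n_timepoints, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_band_limited_signal(n_timepoints: int, tr_seconds: float,
                             band_hz=(0.01, 0.08), seed: int | None = 0) -> np.ndarray:
    """One zero-mean, unit-variance series with all spectral power inside *band_hz*."""
    rng = np.random.default_rng(seed)
    return _band_limited_batch(rng, 1, n_timepoints, tr_seconds, band_hz)[0]


# ---------------------------------------------------------------------------
# masks and region geometry
# ---------------------------------------------------------------------------

def _ball(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius ** 2


def brain_mask_for(config: SyntheticConfig) -> BrainMask:
    """Ellipsoidal brain mask inscribed in the grid (1-voxel margin)."""
    shape = np.array(config.shape)
    center = (shape - 1) / 2.0
    semi = shape / 2.0 - 1.0
    grids = np.ogrid[tuple(slice(0, s) for s in config.shape)]
    inside = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0
    return BrainMask(data=inside, affine=config.affine)


def tissue_masks_for(config: SyntheticConfig, brain: BrainMask) -> dict[str, BrainMask]:
    """Fixed CSF (central box, 'ventricles') and WM (off-centre box) compartments."""
    shape = np.array(config.shape)
    c = shape // 2
    w = np.maximum(shape // 8, 1)
    csf = np.zeros(config.shape, dtype=bool)
    csf[c[0] - w[0]:c[0] + w[0], c[1] - w[1]:c[1] + w[1], c[2] - w[2]:c[2] + w[2]] = True
    wm = np.zeros(config.shape, dtype=bool)
    off = c + shape // 5
    wm[off[0] - w[0]:off[0] + w[0], off[1] - w[1]:off[1] + w[1], c[2] - w[2]:c[2] + w[2]] = True
    csf &= brain.data
    wm &= brain.data & ~csf
    return {
        "csf": BrainMask(data=csf, affine=config.affine),
        "wm": BrainMask(data=wm, affine=config.affine),
    }


def _region_labels(config: SyntheticConfig, brain: BrainMask) -> np.ndarray:
    """Integer region id per voxel: 0..7 background octants, 8+ planted ROIs.

    Raises on ROIs that overlap each other or stick out of the brain mask.
    """
    shape = config.shape
    center = np.array(shape) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    labels = ((grids[0] >= center[0]).astype(np.int16) * 4
              + (grids[1] >= center[1]).astype(np.int16) * 2
              + (grids[2] >= center[2]).astype(np.int16))
    claimed = np.zeros(shape, dtype=bool)
    for k, roi in enumerate(config.rois):
        ball = _ball(shape, roi.center_voxel, roi.radius_voxels)
        if not (ball <= brain.data).all():
            raise ValueError(f"ROI {roi.name!r} does not fit inside the brain mask")
        if (ball & claimed).any():
            raise ValueError(f"ROI {roi.name!r} overlaps a previous ROI")
        claimed |= ball
        labels[ball] = 8 + k
    return labels


def roi_voxels(config: SyntheticConfig, roi_name: str) -> np.ndarray:
    """Boolean volume of the named planted ROI."""
    for roi in config.rois:
        if roi.name == roi_name:
            return _ball(config.shape, roi.center_voxel, roi.radius_voxels)
    raise KeyError(f"no ROI named {roi_name!r}")


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

def _draw_roi_rhos(config: SyntheticConfig, group: str,
                   rng: np.random.Generator) -> dict[str, float]:
    """Per-subject realised ROI synchrony.

    Controls sit exactly at the group value; patients get between-subject
    scatter (``rho_subject_sd``) modelling severity heterogeneity — the latent
    ``z_i`` that the clinical scores are linked to.
    """
    rhos = {}
    for roi in config.rois:
        if group == "patient":
            rho = roi.rho_patient + config.rho_subject_sd * rng.standard_normal()
        else:
            rho = roi.rho_control
        rhos[roi.name] = float(np.clip(rho, 0.0, 0.95))
    return rhos


def make_subject_bold(config: SyntheticConfig, group: str, subject_seed: int,
                      subject_id: str = "", _return_latent: bool = False):
    """Generate one subject's 4D BOLD volume under the shared-driver model.

    Deterministic in ``(config, group, subject_seed)``.  When
    ``_return_latent`` is set, also returns the realised per-ROI rho values
    (used by :func:`make_cohort` to couple clinical scores to synchrony).
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    brain = brain_mask_for(config)
    labels = _region_labels(config, brain)
    T = config.n_timepoints
    rhos = _draw_roi_rhos(config, group, rng)

    n_regions = 8 + len(config.rois)
    drivers = _band_limited_batch(rng, n_regions, T, config.tr_seconds, config.band_hz)
    region_rho = np.empty(n_regions)
    region_rho[:8] = config.rho_background
    for k, roi in enumerate(config.rois):
        region_rho[8 + k] = rhos[roi.name]

    in_mask = brain.data
    n_vox = int(in_mask.sum())
    noise = _band_limited_batch(rng, n_vox, T, config.tr_seconds, config.band_hz)

    vox_labels = labels[in_mask]
    rho_v = region_rho[vox_labels][:, None]
    x = np.sqrt(rho_v) * drivers[vox_labels] + np.sqrt(1.0 - rho_v) * noise

    series = 100.0 + config.signal_sd * x
    if config.global_amp > 0:
        g = _band_limited_batch(rng, 1, T, config.tr_seconds, config.band_hz)[0]
        series += config.global_amp * g
    if config.drift_sd > 0:
        ramp = np.linspace(-0.5, 0.5, T)
        slopes = config.drift_sd * rng.standard_normal((n_vox, 1))
        series += slopes * ramp
    if config.tissue_amp > 0:
        tissue = tissue_masks_for(config, brain)
        t_driver = _band_limited_batch(rng, 2, T, config.tr_seconds, config.band_hz)
        for j, name in enumerate(("csf", "wm")):
            sel = tissue[name].data[in_mask]
            series[sel] += config.tissue_amp * t_driver[j]

    data = np.zeros(config.shape + (T,), dtype=np.float32)
    data[in_mask] = series.astype(np.float32)
    bold = BoldSeries(data=data, affine=config.affine,
                      tr_seconds=config.tr_seconds, subject_id=subject_id)
    if _return_latent:
        return bold, rhos
    return bold


def make_motion(config: SyntheticConfig, subject_seed: int,
                bad_mover: bool = False, subject_id: str = "") -> MotionTrace:
    """Bounded random-walk motion trace; ``bad_mover`` plants a >1.5 mm excursion.

    Good movers stay within +-1.2 mm / +-1.15 deg by clipping the walk, so with
    the default step size they pass the standard exclusion rules.  Bad movers
    get the second half of the run shifted so the x-translation hits exactly
    2.0 mm at the midpoint, which violates the 1.5 mm limit by construction
    (and produces a large FD spike).
    """
    rng = np.random.default_rng(subject_seed)
    T = config.n_timepoints
    if config.motion_sd == 0 and not bad_mover:
        z = np.zeros((T, 3))
        return MotionTrace(translations_mm=z, rotations_rad=z.copy(), subject_id=subject_id)
    trans = np.cumsum(config.motion_sd * rng.standard_normal((T, 3)), axis=0)
    rot = np.cumsum(config.motion_sd * 0.01 * rng.standard_normal((T, 3)), axis=0)
    trans = np.clip(trans, -1.2, 1.2)
    rot = np.clip(rot, -0.02, 0.02)  # 0.02 rad ~ 1.15 deg
    if bad_mover:
        mid = T // 2
        trans[mid:, 0] += 2.0 - trans[mid, 0]
    return MotionTrace(translations_mm=trans, rotations_rad=rot, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def make_cohort(config: SyntheticConfig):
    """Generate the full synthetic study.

    Returns ``(bolds, motions, cohort, brain_mask, tissue_masks)`` where
    ``cohort`` is a DataFrame with one row per subject: group, demographics,
    clinical scores (patients only, typical published marginals), the planted
    ``bad_mover`` flag, a ``medication_naive`` flag, and the latent
    standardised ROI synchrony ``latent_synchrony`` that the primary symptom
    score is linked to.
    """
    n = config.n_per_group
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = ss.generate_state(4 * n + 1, dtype=np.uint32)
    clin_rng = np.random.default_rng(sub_seeds[-1])

    groups = ["patient"] * n + ["control"] * n
    ids = [f"sub-P{i+1:03d}" for i in range(n)] + [f"sub-C{i+1:03d}" for i in range(n)]

    # plant bad movers alternately across groups so both lose subjects evenly
    bad_order = [i // 2 if i % 2 == 0 else n + i // 2 for i in range(2 * n)]
    bad_set = set(bad_order[: config.n_bad_movers])

    bolds, motions, latents = [], [], []
    for i in range(2 * n):
        bold, rhos = make_subject_bold(config, groups[i], int(sub_seeds[i]),
                                       subject_id=ids[i], _return_latent=True)
        motion = make_motion(config, int(sub_seeds[2 * n + i]),
                             bad_mover=(i in bad_set), subject_id=ids[i])
        bolds.append(bold)
        motions.append(motion)
        link_roi = config.clinical_link.roi_name if config.rois else None
        latents.append(rhos.get(link_roi, 0.0) if link_roi else 0.0)

    latents = np.array(latents)
    pat = slice(0, n)
    z = np.zeros(2 * n)
    pat_sd = latents[pat].std()
    if pat_sd > 0:
        z[pat] = (latents[pat] - latents[pat].mean()) / pat_sd

    link = config.clinical_link
    n_male = int(round(config.male_fraction * n))
    gender = (["M"] * n_male + ["F"] * (n - n_male)) * 2
    age = np.concatenate([
        np.clip(clin_rng.normal(29.16, 8.71, n), 18, 60),
        np.clip(clin_rng.normal(27.88, 10.58, n), 18, 60),
    ])

    scores = {c: np.full(2 * n, np.nan) for c in
              ("ybocs_total", "obsessions", "compulsions", "hamd", "hama", "duration_years")}
    scores["ybocs_total"][pat] = (link.intercept + link.slope * z[pat]
                                  + clin_rng.normal(0, link.noise_sd, n))
    mu_o, sd_o = _CLINICAL_MARGINALS["obsessions"]
    obs_slope = link.slope * (0.224 * sd_o) / (0.241 * 5.38)
    obs_noise = np.sqrt(max(sd_o ** 2 - obs_slope ** 2, 0.1))
    scores["obsessions"][pat] = mu_o + obs_slope * z[pat] + clin_rng.normal(0, obs_noise, n)
    for name in ("compulsions", "hamd", "hama", "duration_years"):
        mu, sd = _CLINICAL_MARGINALS[name]
        scores[name][pat] = np.clip(clin_rng.normal(mu, sd, n), 0.1, None)

    n_naive = int(round(config.medication_naive_fraction * n))
    naive = np.array([True] * (2 * n))
    naive[pat] = np.array([i < n_naive for i in range(n)])

    cohort = pd.DataFrame({
        "id": ids,
        "group": groups,
        "age": np.round(age, 2),
        "gender": gender,
        **{k: np.round(v, 3) for k, v in scores.items()},
        "medication_naive": naive,
        "bad_mover": [i in bad_set for i in range(2 * n)],
        "latent_synchrony": np.round(z, 6),
        "qc_pass": True,
    })

    brain = brain_mask_for(config)
    tissue = tissue_masks_for(config, brain)
    return bolds, motions, cohort, brain, tissue
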