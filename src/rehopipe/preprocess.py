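"""Temporal preprocessing and motion quality control.

Implements the stages downstream of realignment/normalisation: framewise
displacement (Power variant), threshold-based motion screening, the Friston
24-parameter motion design, nuisance regression (motion + CSF + WM + global
mean), per-voxel linear detrending, and an ideal DFT band-pass filter.  The
canonical stage order is nuisance regression -> detrend -> band-pass, wrapped
in :func:`preprocess_bold`.

All regressions are ordinary least squares solved once per design and applied
to every in-mask voxel simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .io import BoldSeries, BrainMask, MotionTrace

logger = logging.getLogger(__name__)


def framewise_displacement(motion: MotionTrace, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Power framewise displacement: FD_t = sum|d trans| + r * sum|d rot|.

    Backward differences; rotations (radians) are converted to arc length on a
    sphere of ``sphere_radius_mm`` (default 50 mm).  FD at the first frame is 0.
    """
    if motion.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius_mm * dr])
    return fd


@dataclass
class QcReport:
    """Motion screening outcome for one subject; fails are strict (>= limit)."""

    subject_id: str
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    mean_fd: float
    passed: bool
    reasons: list[str]


def qc_screen(motion: MotionTrace, trans_limit_mm: float = 1.5,
              rot_limit_deg: float = 1.5, mean_fd_limit: float = 0.2,
              fd_sphere_radius_mm: float = 50.0) -> QcReport:
    """Screen a motion trace against the standard exclusion rules.

    The inclusion criteria are strict inequalities (movement < 1.5 mm and
    < 1.5 deg in every direction, mean FD < 0.2), so a subject sitting exactly
    on a limit is excluded.
    """
    max_trans = float(np.abs(motion.translations_mm).max())
    max_rot_deg = float(np.degrees(np.abs(motion.rotations_rad).max()))
    mean_fd = float(framewise_displacement(motion, fd_sphere_radius_mm).mean())
    reasons = []
    if max_trans >= trans_limit_mm:
        reasons.append(f"max translation {max_trans:.3f} mm >= {trans_limit_mm} mm")
    if max_rot_deg >= rot_limit_deg:
        reasons.append(f"max rotation {max_rot_deg:.3f} deg >= {rot_limit_deg} deg")
    if mean_fd >= mean_fd_limit:
        reasons.append(f"mean FD {mean_fd:.4f} >= {mean_fd_limit}")
    return QcReport(subject_id=motion.subject_id,
                    max_abs_translation_mm=max_trans,
                    max_abs_rotation_deg=max_rot_deg,
                    mean_fd=mean_fd,
                    passed=not reasons,
                    reasons=reasons)


def friston24(motion: MotionTrace) -> np.ndarray:
    """T x 24 Friston motion design: [R_t, R_{t-1}, R_t^2, R_{t-1}^2].

    The lagged block at the first frame is zero-filled (SPM convention) rather
    than dropping the frame.
    """
    R = motion.as_matrix()
    if R.shape[0] < 2:
        raise ValueError("friston24 needs at least 2 frames")
    R_lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, R_lag, R ** 2, R_lag ** 2])


@dataclass
class NuisanceDesign:
    """Design matrix for nuisance regression with named columns."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix / label mismatch")


def build_nuisance_design(motion: MotionTrace, bold: BoldSeries, brain: BrainMask,
                          csf: BrainMask | None = None, wm: BrainMask | None = None,
                          global_signal: bool = True) -> NuisanceDesign:
    """Friston-24 motion block + CSF mean + WM mean + global mean + constant."""
    if motion.n_frames != bold.n_timepoints:
        raise ValueError("motion trace and BOLD series length differ")
    brain.check_geometry(bold)
    cols = [friston24(motion)]
    labels = ([f"mot{i+1}" for i in range(6)] + [f"mot{i+1}_lag" for i in range(6)]
              + [f"mot{i+1}_sq" for i in range(6)] + [f"mot{i+1}_lag_sq" for i in range(6)])
    flat = bold.data.reshape(-1, bold.n_timepoints)
    for name, tmask in (("csf", csf), ("wm", wm)):
        if tmask is not None:
            sel = tmask.data.reshape(-1)
            cols.append(flat[sel].mean(axis=0, dtype=np.float64)[:, None])
            labels.append(name)
    if global_signal:
        sel = brain.data.reshape(-1)
        cols.append(flat[sel].mean(axis=0, dtype=np.float64)[:, None])
        labels.append("global")
    cols.append(np.ones((bold.n_timepoints, 1)))
    labels.append("const")
    return NuisanceDesign(matrix=np.hstack(cols), labels=labels)


def _dedupe_columns(X: np.ndarray, labels: list[str]):
    """Drop exact duplicate and numerically-zero columns.

    A zero-motion trace collapses the 24 motion columns to a single zero
    column, and re-running the pipeline on its own output produces tissue/
    global columns that are zero to rounding; both must not fail the rank
    check.
    """
    scale = max(float(np.abs(X).max()), 1.0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.abs(col).max() <= 1e-10 * scale:
            continue
        if any(np.array_equal(col, X[:, k]) for k in keep):
            continue
        keep.append(j)
    if not keep:  # pathological all-zero design: keep the constant term
        keep = [X.shape[1] - 1]
    return X[:, keep], [labels[j] for j in keep]


def regress_nuisance(bold: BoldSeries, design: NuisanceDesign, mask: BrainMask) -> BoldSeries:
    """OLS residuals of every in-mask voxel series on the nuisance design.

    Residuals are orthogonal to every retained design column.  Raises if the
    design is rank deficient after removing exact duplicate columns.
    """
    mask.check_geometry(bold)
    X, labels = _dedupe_columns(design.matrix, design.labels)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"nuisance design rank deficient ({rank} < {X.shape[1]}) after de-duplication"
        )
    sel = mask.data.reshape(-1)
    Y = bold.data.reshape(-1, bold.n_timepoints)[sel].T.astype(float)  # T x V
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    out = np.zeros(bold.data.shape, dtype=np.float64)
    out.reshape(-1, bold.n_timepoints)[sel] = resid.T
    return BoldSeries(data=out, affine=bold.affine, tr_seconds=bold.tr_seconds,
                      subject_id=bold.subject_id)


def detrend_linear(bold: BoldSeries, mask: BrainMask) -> BoldSeries:
    """Remove the per-voxel least-squares line; output orthogonal to [1, t]."""
    mask.check_geometry(bold)
    T = bold.n_timepoints
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t])
    sel = mask.data.reshape(-1)
    Y = bold.data.reshape(-1, T)[sel].T.astype(float)
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    out = np.zeros(bold.data.shape, dtype=np.float64)
    out.reshape(-1, T)[sel] = resid.T
    return BoldSeries(data=out, affine=bold.affine, tr_seconds=bold.tr_seconds,
                      subject_id=bold.subject_id)


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08,
             mask: BrainMask | None = None) -> BoldSeries:
    """Ideal (zero-phase) DFT band-pass: keep bins with frequency in [low, high].

    The DC bin is always removed, so the output is zero-mean.  Bin selection is
    inclusive at both edges; no roll-off.
    """
    nyquist = 0.5 / bold.tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) invalid for TR={bold.tr_seconds}s "
            f"(Nyquist {nyquist} Hz)"
        )
    T = bold.n_timepoints
    freqs = rfftfreq(T, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    if mask is not None:
        mask.check_geometry(bold)
        sel = mask.data.reshape(-1)
    else:
        sel = np.ones(int(np.prod(bold.shape3d)), dtype=bool)
    Y = bold.data.reshape(-1, T)[sel].astype(float)
    spectrum = rfft(Y, axis=-1)
    spectrum[:, ~keep] = 0.0
    filt = irfft(spectrum, n=T, axis=-1)
    out = np.zeros(bold.data.shape, dtype=np.float64)
    out.reshape(-1, T)[sel] = filt
    return BoldSeries(data=out, affine=bold.affine, tr_seconds=bold.tr_seconds,
                      subject_id=bold.subject_id)


def _bandlimit_matrix(X: np.ndarray, tr_seconds: float,
                      low_hz: float, high_hz: float) -> np.ndarray:
    """Project design columns onto the pass band (same DFT mask as bandpass)."""
    T = X.shape[0]
    freqs = rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spectrum = rfft(X, axis=0)
    spectrum[~keep] = 0.0
    return irfft(spectrum, n=T, axis=0)


def preprocess_bold(bold: BoldSeries, motion: MotionTrace, brain: BrainMask,
                    csf: BrainMask | None = None, wm: BrainMask | None = None,
                    low_hz: float = 0.01, high_hz: float = 0.08,
                    global_signal: bool = True) -> BoldSeries:
    """Canonical stage order: nuisance regression -> linear detrend -> band-pass.

    Band-passing after regression reintroduces a small correlation with the
    nuisance regressors (only their out-of-band part was implicitly protected),
    so a final orthogonalisation against the band-limited projections of the
    design columns and the linear ramp is applied.  This removes in-band
    nuisance leakage and makes the composed pipeline an exact projector:
    re-running it on its own output is the identity to rounding.
    """
    design = build_nuisance_design(motion, bold, brain, csf=csf, wm=wm,
                                   global_signal=global_signal)
    logger.info("preprocess %s: nuisance columns %d -> detrend -> band-pass %.3f-%.3f Hz",
                bold.subject_id, design.matrix.shape[1], low_hz, high_hz)
    out = regress_nuisance(bold, design, brain)
    out = detrend_linear(out, brain)
    out = bandpass(out, low_hz=low_hz, high_hz=high_hz, mask=brain)

    T = bold.n_timepoints
    ramp = np.arange(T, dtype=float)[:, None]
    Xb = _bandlimit_matrix(np.hstack([design.matrix, ramp]), bold.tr_seconds,
                           low_hz, high_hz)
    Xb, _ = _dedupe_columns(Xb, [f"c{j}" for j in range(Xb.shape[1])])
    if Xb.shape[1]:
        sel = brain.data.reshape(-1)
        Y = out.data.reshape(-1, T)[sel].T.astype(float)
        resid = Y - Xb @ (np.linalg.pinv(Xb) @ Y)
        data = np.zeros(out.data.shape, dtype=np.float64)
        data.reshape(-1, T)[sel] = resid.T
        out = BoldSeries(data=data, affine=out.affine, tr_seconds=out.tr_seconds,
                         subject_id=out.subject_id)
    return out
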