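import numpy as np
import pytest

from rehopipe.io import BoldSeries, BrainMask, MotionTrace
from rehopipe.preprocess import (NuisanceDesign, bandpass, build_nuisance_design,
                                 detrend_linear, framewise_displacement, friston24,
                                 preprocess_bold, qc_screen, regress_nuisance)
from rehopipe.synth import SyntheticConfig, brain_mask_for, make_motion, \
    make_subject_bold, tissue_masks_for


def _trace(trans, rot=None):
    trans = np.asarray(trans, dtype=float)
    rot = np.zeros_like(trans) if rot is None else np.asarray(rot, dtype=float)
    return MotionTrace(translations_mm=trans, rotations_rad=rot, subject_id="t")


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = framewise_displacement(_trace(np.zeros((10, 3))))
        assert np.array_equal(fd, np.zeros(10))

    def test_single_translation_step(self):
        trans = np.zeros((5, 3))
        trans[1:, 0] = 0.1  # +0.1 mm in x from frame 2 on
        fd = framewise_displacement(_trace(trans))
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(0.1)
        assert np.allclose(fd[2:], 0.0)

    def test_rotation_scaled_by_sphere_radius(self):
        rot = np.zeros((4, 3))
        rot[1:, 2] = 0.002  # 0.002 rad step at frame 2
        fd = framewise_displacement(_trace(np.zeros((4, 3)), rot))
        assert fd[1] == pytest.approx(50 * 0.002)  # = 0.1 mm

    def test_mixed_step_sums_contributions(self):
        trans = np.zeros((3, 3)); trans[1, 0] = 0.05
        rot = np.zeros((3, 3)); rot[1, 1] = 0.001
        fd = framewise_displacement(_trace(trans, rot))
        assert fd[1] == pytest.approx(0.05 + 50 * 0.001)


class TestQcScreen:
    def test_zero_trace_passes(self):
        rep = qc_screen(_trace(np.zeros((10, 3))))
        assert rep.passed and rep.reasons == []

    def test_large_translation_fails_with_reason(self):
        trans = np.zeros((10, 3)); trans[4, 1] = 1.6
        rep = qc_screen(_trace(trans))
        assert not rep.passed
        assert any("translation" in r for r in rep.reasons)

    def test_boundary_translation_is_strict(self):
        trans = np.zeros((10, 3)); trans[0, 0] = 1.5
        assert not qc_screen(_trace(trans)).passed

    def test_boundary_mean_fd_is_strict(self):
        # two frames, one 0.4 mm step: mean FD = 0.2 exactly -> excluded
        trans = np.zeros((2, 3)); trans[1, 0] = 0.4
        rep = qc_screen(_trace(trans))
        assert rep.mean_fd == 0.2
        assert not rep.passed
        assert any("FD" in r for r in rep.reasons)

    def test_rotation_limit_in_degrees(self):
        rot = np.zeros((5, 3)); rot[2, 0] = np.radians(1.6)
        rep = qc_screen(_trace(np.zeros((5, 3)), rot))
        assert not rep.passed
        assert any("rotation" in r for r in rep.reasons)


class TestFriston24:
    def test_zero_motion_gives_zero_matrix(self):
        X = friston24(_trace(np.zeros((10, 3))))
        assert X.shape == (10, 24)
        assert not X.any()

    def test_constant_motion_blocks(self):
        X = friston24(_trace(np.full((4, 3), 2.0), np.full((4, 3), 0.5)))
        assert np.allclose(X[:, :3], 2.0) and np.allclose(X[:, 3:6], 0.5)
        assert np.allclose(X[0, 6:12], 0.0)       # lag zero-filled at t=1
        assert np.allclose(X[1:, 6:9], 2.0)
        assert np.allclose(X[:, 12:15], 4.0)      # squares
        assert np.allclose(X[1:, 18:21], 4.0)

    def test_against_hand_built_oracle(self, rng):
        R = rng.standard_normal((5, 6))
        trace = MotionTrace(translations_mm=R[:, :3], rotations_rad=R[:, 3:])
        X = friston24(trace)
        lag = np.vstack([np.zeros(6), R[:-1]])
        expected = np.hstack([R, lag, R ** 2, lag ** 2])
        assert np.allclose(X, expected)
        assert np.linalg.matrix_rank(X) <= 24


class TestRegressNuisance:
    def _setup(self, rng, T=30, n_vox=10):
        affine = np.eye(4)
        data = rng.standard_normal((n_vox, 1, 1, T))
        bold = BoldSeries(data=data, affine=affine, tr_seconds=2.0)
        mask = BrainMask(data=np.ones((n_vox, 1, 1), bool), affine=affine)
        return bold, mask

    def test_design_column_annihilated(self, rng):
        bold, mask = self._setup(rng)
        col = rng.standard_normal(30)
        bold.data[3, 0, 0] = 2.5 * col
        design = NuisanceDesign(matrix=np.column_stack([col, np.ones(30)]),
                                labels=["c", "const"])
        out = regress_nuisance(bold, design, mask)
        assert np.abs(out.data[3, 0, 0]).max() < 1e-10

    def test_constant_only_demeans(self, rng):
        bold, mask = self._setup(rng)
        design = NuisanceDesign(matrix=np.ones((30, 1)), labels=["const"])
        out = regress_nuisance(bold, design, mask)
        expected = bold.data - bold.data.mean(axis=-1, keepdims=True)
        assert np.abs(out.data - expected).max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        bold, mask = self._setup(rng)
        X = np.column_stack([rng.standard_normal((30, 3)), np.ones(30)])
        design = NuisanceDesign(matrix=X, labels=list("abc") + ["const"])
        out = regress_nuisance(bold, design, mask)
        for v in range(10):
            y = bold.data[v, 0, 0]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.abs(out.data[v, 0, 0] - (y - X @ beta)).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, rng):
        bold, mask = self._setup(rng)
        X = np.column_stack([rng.standard_normal((30, 4)), np.ones(30)])
        design = NuisanceDesign(matrix=X, labels=list("abcd") + ["const"])
        out = regress_nuisance(bold, design, mask)
        Y = out.data.reshape(-1, 30).T
        dots = np.abs(X.T @ Y)
        bound = 1e-6 * np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(Y, axis=0)
        assert (dots <= bound + 1e-12).all()

    def test_rank_deficient_design_rejected(self, rng):
        bold, mask = self._setup(rng)
        c = rng.standard_normal(30)
        X = np.column_stack([c, 2 * c, np.ones(30)])  # collinear, not duplicate
        design = NuisanceDesign(matrix=X, labels=["a", "b", "const"])
        with pytest.raises(ValueError, match="rank deficient"):
            regress_nuisance(bold, design, mask)


class TestDetrend:
    def test_ramp_removed(self, rng):
        t = np.arange(30, dtype=float)
        data = (3.0 + 0.5 * t)[None, None, None, :].repeat(4, axis=0)
        bold = BoldSeries(data=data, affine=np.eye(4), tr_seconds=2.0)
        mask = BrainMask(data=np.ones((4, 1, 1), bool), affine=np.eye(4))
        out = detrend_linear(bold, mask)
        assert np.abs(out.data).max() < 1e-10

    def test_idempotent(self, rng):
        bold = BoldSeries(data=rng.standard_normal((4, 1, 1, 30)),
                          affine=np.eye(4), tr_seconds=2.0)
        mask = BrainMask(data=np.ones((4, 1, 1), bool), affine=np.eye(4))
        once = detrend_linear(bold, mask)
        twice = detrend_linear(once, mask)
        assert np.abs(twice.data - once.data).max() < 1e-10

    def test_sinusoid_recovered_from_sinusoid_plus_ramp(self):
        t = np.arange(64, dtype=float)
        sine = np.sin(2 * np.pi * 8 * t / 64)  # full periods: orthogonal to [1, t]
        data = (sine + 2.0 + 0.3 * t)[None, None, None, :]
        bold = BoldSeries(data=data, affine=np.eye(4), tr_seconds=2.0)
        mask = BrainMask(data=np.ones((1, 1, 1), bool), affine=np.eye(4))
        out = detrend_linear(bold, mask)
        # explicit least-squares oracle
        X = np.column_stack([np.ones(64), t])
        beta = np.linalg.solve(X.T @ X, X.T @ data[0, 0, 0])
        expected = data[0, 0, 0] - X @ beta
        assert np.abs(out.data[0, 0, 0] - expected).max() < 1e-8


class TestBandpass:
    def _sine_bold(self, freq_hz, T=200, tr=2.0):
        t = np.arange(T) * tr
        data = np.sin(2 * np.pi * freq_hz * t)[None, None, None, :]
        return BoldSeries(data=data, affine=np.eye(4), tr_seconds=tr)

    def test_in_band_sinusoid_passes(self):
        bold = self._sine_bold(0.04)
        out = bandpass(bold)
        ratio = out.data.std() / bold.data.std()
        assert ratio > 0.99

    def test_out_of_band_sinusoid_blocked(self):
        bold = self._sine_bold(0.2)
        out = bandpass(bold)
        assert out.data.std() / bold.data.std() < 0.01

    def test_constant_series_zeroed(self):
        bold = BoldSeries(data=np.full((2, 1, 1, 50), 7.0), affine=np.eye(4),
                          tr_seconds=2.0)
        out = bandpass(bold)
        assert np.abs(out.data).max() < 1e-10

    def test_invalid_band_for_tr(self):
        bold = self._sine_bold(0.04, tr=8.0)  # Nyquist 0.0625 < 0.08
        with pytest.raises(ValueError, match="band"):
            bandpass(bold)

    def test_zero_phase_no_time_shift(self):
        bold = self._sine_bold(0.04)
        out = bandpass(bold)
        # same-frequency sinusoid must come back in phase, not shifted
        assert np.corrcoef(out.data[0, 0, 0], bold.data[0, 0, 0])[0, 1] > 0.999


class TestComposedPipeline:
    @pytest.fixture()
    def subject(self):
        cfg = SyntheticConfig(shape=(10, 10, 10), n_timepoints=100, seed=0)
        bold = make_subject_bold(cfg, "patient", 21)
        motion = make_motion(cfg, 22)
        brain = brain_mask_for(cfg)
        tissue = tissue_masks_for(cfg, brain)
        return cfg, bold, motion, brain, tissue

    def test_composition_idempotent(self, subject):
        _, bold, motion, brain, tissue = subject
        once = preprocess_bold(bold, motion, brain, csf=tissue["csf"], wm=tissue["wm"])
        twice = preprocess_bold(once, motion, brain, csf=tissue["csf"], wm=tissue["wm"])
        assert np.abs(twice.data - once.data).max() < 1e-8

    def test_output_orthogonal_to_design(self, subject):
        _, bold, motion, brain, tissue = subject
        design = build_nuisance_design(motion, bold, brain, csf=tissue["csf"],
                                       wm=tissue["wm"])
        out = regress_nuisance(bold, design, brain)
        Y = out.data.reshape(-1, 100)[brain.data.reshape(-1)].T
        X = design.matrix
        dots = np.abs(X.T @ Y)
        bound = 1e-6 * np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(Y, axis=0)
        assert (dots <= bound + 1e-12).all()

    def test_fortran_ordered_input_equals_c_ordered(self, subject):
        """Volumes loaded from NIfTI come F-ordered; results must not differ."""
        _, bold, motion, brain, tissue = subject
        f_bold = BoldSeries(data=np.asfortranarray(bold.data), affine=bold.affine,
                            tr_seconds=bold.tr_seconds)
        a = preprocess_bold(bold, motion, brain, csf=tissue["csf"], wm=tissue["wm"])
        b = preprocess_bold(f_bold, motion, brain, csf=tissue["csf"], wm=tissue["wm"])
        assert a.data[brain.data].std() > 0
        assert np.array_equal(a.data, b.data)

    def test_output_band_limited(self, subject):
        _, bold, motion, brain, tissue = subject
        out = preprocess_bold(bold, motion, brain, csf=tissue["csf"], wm=tissue["wm"])
        series = out.data[brain.data]
        power = np.abs(np.fft.rfft(series, axis=-1)) ** 2
        freqs = np.fft.rfftfreq(100, 2.0)
        oob = power[:, (freqs < 0.01) | (freqs > 0.08)].sum()
        assert oob / power.sum() < 1e-20
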