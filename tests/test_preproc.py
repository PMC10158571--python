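"""Nuisance-regression and band-pass contracts."""

import inspect

import numpy as np
import pandas as pd
import pytest

from natisc.config import NetworkSpec, Condition, SimulationConfig
from natisc.preproc import (
    NuisanceSet,
    bandpass,
    build_nuisance_set,
    clean_run,
    detect_outlier_frames,
    extract_noise_pcs,
    framewise_displacement,
    motion_with_derivatives,
    regress_nuisance,
)
from natisc.synthetic import MOTION_COLUMNS, simulate_naturalistic_run


def _motion_df(n, rng=None, scale=0.0):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(scale * rng.standard_normal((n, 6)), columns=MOTION_COLUMNS)


class TestNoisePCs:
    def test_rank_one_compartment(self):
        t = np.sin(np.linspace(0, 8 * np.pi, 100))
        run = np.vstack([2.0 * t, -1.0 * t, 0.5 * t + 3.0])
        pcs, mean = extract_noise_pcs(run, np.arange(3), k=5)
        assert pcs.shape[1] == 1  # rank 1 after centering
        r = np.corrcoef(pcs[:, 0], t)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        np.testing.assert_allclose(mean, run.mean(axis=0))

    def test_matches_dense_eigendecomposition(self, rng):
        run = rng.standard_normal((50, 160))
        pcs, _ = extract_noise_pcs(run, np.arange(50), k=5)
        # oracle: eigenvectors of the frame x frame covariance of centered data
        Xc = run - run.mean(axis=1, keepdims=True)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        oracle = v[:, np.argsort(w)[::-1][:5]]
        for j in range(5):
            assert abs(abs(pcs[:, j] @ oracle[:, j]) - 1.0) < 1e-8
        # orthonormal over frames
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-10)

    def test_default_k_is_five(self):
        assert inspect.signature(extract_noise_pcs).parameters["k"].default == 5

    def test_empty_compartment_rejected(self):
        with pytest.raises(ValueError):
            extract_noise_pcs(np.zeros((4, 10)), np.array([], dtype=int))


class TestOutlierFrames:
    def test_quiet_run_has_no_flags(self):
        flags = detect_outlier_frames(np.ones(100), _motion_df(100))
        assert not flags.any()

    def test_defaults_match_convention(self):
        sig = inspect.signature(detect_outlier_frames)
        assert sig.parameters["z_thresh"].default == 5.0
        assert sig.parameters["motion_thresh"].default == 0.9

    def test_injected_global_signal_step_flagged_exactly(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0, 1.0, 200)
        g[40:] += 10.0 * 1.414  # step of 10 sd of the baseline delta series
        flags = detect_outlier_frames(g, _motion_df(200))
        # oracle: recompute the delta z-scores by hand
        dg = np.diff(g, prepend=g[:1])
        dg[0] = 0.0
        z = np.zeros_like(dg)
        z[1:] = (dg[1:] - dg[1:].mean()) / dg[1:].std()
        expected = np.abs(z) > 5.0
        expected[0] = False
        np.testing.assert_array_equal(flags, expected)
        assert flags[40] and flags.sum() == expected.sum()

    def test_motion_jump_flagged_via_fd(self):
        m = _motion_df(100)
        m.loc[50:, "trans_x"] += 1.0  # 1 mm jump > 0.9 mm threshold
        flags = detect_outlier_frames(np.ones(100), m)
        assert flags[50] and flags.sum() == 1
        fd = framewise_displacement(m)
        assert fd[50] == pytest.approx(1.0)

    def test_rotation_converted_on_50mm_sphere(self):
        m = _motion_df(10)
        m.loc[5:, "rot_z"] += 0.01  # 0.01 rad -> 0.5 mm on a 50 mm sphere
        assert framewise_displacement(m)[5] == pytest.approx(0.5)


class TestRegressNuisance:
    def _nuisance(self, n, rng):
        motion = _motion_df(n, rng, scale=0.01)
        return NuisanceSet(motion=motion_with_derivatives(motion))

    def test_nuisance_column_removed_entirely(self, rng):
        n = 120
        nuis = self._nuisance(n, rng)
        run = np.vstack([3.0 * nuis.motion[:, 0] + 1.0, rng.standard_normal(n)])
        resid = regress_nuisance(run, nuis)
        np.testing.assert_allclose(resid[0], 0.0, atol=1e-10)

    def test_orthogonal_signal_only_centered(self, rng):
        n = 240
        nuis = NuisanceSet(motion=np.zeros((n, 0)), detrend_order=0)
        x = np.sin(2 * np.pi * np.arange(n) / 20)
        resid = regress_nuisance(x[None, :], nuis)
        np.testing.assert_allclose(resid[0], x - x.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 150
        motion = _motion_df(n, rng, scale=0.05)
        run = rng.standard_normal((30, n))
        nuis = NuisanceSet(motion=motion_with_derivatives(motion))
        resid = regress_nuisance(run, nuis)
        D, _ = nuis.design_matrix(n)
        Dc = D - D.mean(axis=0)
        keep = Dc.std(axis=0) > 0
        corr = np.corrcoef(np.vstack([resid, Dc[:, keep].T]))[:30, 30:]
        assert np.abs(corr).max() < 1e-8

    def test_idempotent(self, rng):
        n = 150
        motion = _motion_df(n, rng, scale=0.05)
        run = rng.standard_normal((10, n))
        nuis = NuisanceSet(motion=motion_with_derivatives(motion))
        r1 = regress_nuisance(run, nuis)
        r2 = regress_nuisance(r1, nuis)
        assert np.max(np.abs(r1 - r2)) < 1e-10 * max(1.0, np.max(np.abs(r1)))

    def test_collinear_columns_dropped_not_fatal(self, rng):
        n = 100
        motion = _motion_df(n, rng, scale=0.05)
        M = motion_with_derivatives(motion)
        M[:, 6] = M[:, 0]  # duplicate column
        nuis = NuisanceSet(motion=M)
        resid = regress_nuisance(rng.standard_normal((5, n)), nuis)
        assert np.all(np.isfinite(resid))

    def test_injected_nuisance_recovered_from_generator(self):
        nets = (NetworkSpec("language", 2, 8),)
        conds = (Condition("story", "+Lang+ToM"),)
        cfg = SimulationConfig(
            n_subjects=3, n_timepoints=160, networks=nets, conditions=conds,
            coupling={("language", "story"): 0.3}, grid_shape=(8, 8, 4), seed=21,
        )
        run = simulate_naturalistic_run(cfg, "story")
        layout = run.layout
        for i in range(run.n_subjects):
            nuis = build_nuisance_set(run.bold[i], run.motion[i], layout.wm, layout.csf, layout.gm)
            resid = regress_nuisance(run.bold[i], nuis)
            for name, src in run.ground_truth.nuisance_sources[i].items():
                corr = np.array(
                    [np.corrcoef(resid[v], src)[0, 1] for v in layout.parcels["language_p1"]]
                )
                assert np.abs(corr).max() < 0.05, name


class TestBandpass:
    def test_constant_series_zeroed(self):
        out = bandpass(np.full((2, 200), 7.0), tr=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    @pytest.mark.parametrize("method", ["butter", "fft"])
    def test_passband_sinusoid_preserved(self, method):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, tr=2.0, method=method)
        ratio = y[100:-100].std() / x[100:-100].std()
        assert 20 * np.log10(ratio) > -1.0  # within 1 dB

    @pytest.mark.parametrize("freq", [0.002, 0.2])
    def test_stopband_attenuated(self, freq):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, tr=2.0)
        ratio = y.std() / x.std()
        assert 20 * np.log10(ratio) < -20.0

    def test_zero_phase(self):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, tr=2.0)
        xc, yc = x[100:-100], y[100:-100]
        lags = [np.dot(np.roll(xc, l), yc) for l in (-2, -1, 0, 1, 2)]
        assert int(np.argmax(lags)) == 2  # peak cross-correlation at lag 0

    def test_default_band(self):
        assert inspect.signature(bandpass).parameters["band"].default == (0.008, 0.09)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), tr=2.0, band=(0.01, 0.3))

    def test_clean_run_provenance(self, rng):
        n = 160
        motion = _motion_df(n, rng, scale=0.02)
        nuis = NuisanceSet(motion=motion_with_derivatives(motion))
        out = clean_run(rng.standard_normal((4, n)), nuis, tr=2.0)
        assert out.band == (0.008, 0.09)
        assert out.data.shape == (4, n)
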