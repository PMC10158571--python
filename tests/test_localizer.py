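"""Localizer GLM, contrast maps, and fROI definition."""

import inspect

import numpy as np
import pytest
from scipy import stats

from natisc.localizer import (
    ContrastMap,
    FROI,
    LocalizerDesign,
    build_design_matrix,
    define_froi,
    double_gamma_hrf,
    exclude_overlap,
    fit_glm_contrast,
    hrf_convolved_boxcars,
    make_default_localizer_design,
    qc_subject,
)


class TestHRF:
    def test_peaks_five_to_six_seconds(self):
        h = double_gamma_hrf(tr=0.5)
        assert 5.0 <= np.argmax(h) * 0.5 <= 6.5

    def test_matches_canonical_spm_shape(self):
        # independent oracle: nilearn's canonical (SPM) HRF; nilearn shifts
        # onset by one sample (loc=dt), so compare at the best alignment lag
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        ours = double_gamma_hrf(tr=0.5, duration=32.0)
        ref = spm_hrf(0.5, oversampling=1, time_length=32.0)
        n = min(len(ours), len(ref))
        best = max(np.corrcoef(ours[: n - lag], ref[lag:n])[0, 1] for lag in range(3))
        assert best > 0.999

    def test_unit_sum(self):
        assert double_gamma_hrf(tr=2.0).sum() == pytest.approx(1.0)


class TestDesignMatrix:
    def test_single_condition_column_count(self):
        d = LocalizerDesign([(16.0, 16.0, "task")], 80, 2.0, {"task": 1.0})
        X = build_design_matrix(d, highpass_s=None)
        assert list(X.columns) == ["task", "task_derivative", "intercept"]

    def test_two_condition_column_count(self):
        d = make_default_localizer_design(160, 2.0)
        X = build_design_matrix(d)
        cond_cols = [c for c in X.columns if not c.startswith(("drift", "intercept"))]
        assert len(cond_cols) == 4  # 2 conditions x (boxcar + derivative)
        assert "intercept" in X.columns

    def test_convolved_boxcar_peak_lag(self):
        d = LocalizerDesign([(40.0, 4.0, "task")], 100, 2.0, {"task": 1.0})
        x = hrf_convolved_boxcars(d)["task"]
        # oracle: numeric convolution with the double-gamma, peak ~5-6 s after onset
        peak_s = np.argmax(x) * 2.0 - 40.0
        assert 4.0 <= peak_s <= 8.0

    def test_overlapping_blocks_rejected(self):
        d = LocalizerDesign([(10.0, 20.0, "a"), (20.0, 20.0, "b")], 100, 2.0, {"a": 1, "b": -1})
        with pytest.raises(ValueError):
            d.validate()

    def test_contrast_condition_without_blocks_rejected(self):
        d = LocalizerDesign([(16.0, 16.0, "task")], 80, 2.0, {"task": 1.0, "ghost": -1.0})
        with pytest.raises(ValueError):
            build_design_matrix(d)


class TestGLM:
    def _design(self):
        d = make_default_localizer_design(160, 2.0)
        return d, build_design_matrix(d)

    def test_noiseless_linear_recovery(self):
        d, X = self._design()
        y = (3.0 * X["task"] - 3.0 * X["control"]).to_numpy()[None, :]
        cmap = fit_glm_contrast(y, X, {"task": 1.0, "control": -1.0})
        assert cmap.effect[0] == pytest.approx(6.0, abs=1e-8)

    def test_null_t_statistics_follow_student_t(self, rng):
        d, X = self._design()
        run = rng.standard_normal((10_000, 160))
        cmap = fit_glm_contrast(run, X, d.contrast)
        ks = stats.kstest(cmap.t, stats.t(df=cmap.df).cdf)
        assert ks.pvalue > 0.01

    def test_graded_effects_rank_recovered(self, rng):
        d, X = self._design()
        effects = np.linspace(0.0, 3.0, 400)
        rhos = []
        for _ in range(10):
            run = effects[:, None] * (X["task"] - X["control"]).to_numpy() + rng.standard_normal((400, 160))
            cmap = fit_glm_contrast(run, X, d.contrast)
            rhos.append(stats.spearmanr(effects, cmap.effect).statistic)
        assert np.mean(rhos) > 0.8

    def test_too_few_frames_rejected(self):
        d, X = self._design()
        with pytest.raises(ValueError):
            fit_glm_contrast(np.zeros((2, X.shape[1] - 1)), X.iloc[: X.shape[1] - 1], d.contrast)


class TestDefineFroi:
    def test_small_parcel_argmax(self, rng):
        values = rng.standard_normal(64)
        parcel = np.arange(20, 40)
        cmap = ContrastMap(effect=values, t=values, df=100.0)
        froi = define_froi(cmap, parcel, fraction=0.10)
        top2 = parcel[np.argsort(values[parcel])[::-1][:2]]
        assert set(froi.voxels) == set(top2.tolist())

    def test_default_fraction(self):
        assert inspect.signature(define_froi).parameters["fraction"].default == 0.10

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            values = np.round(rng.standard_normal(n), 1)  # coarse values force ties
            parcel = np.arange(n)
            cmap = ContrastMap(effect=values, t=values, df=50.0)
            froi = define_froi(cmap, parcel, fraction=0.10)
            k = max(1, int(np.ceil(0.10 * n)))
            # oracle: full stable sort by (-value, index)
            oracle = sorted(range(n), key=lambda i: (-values[i], i))[:k]
            assert sorted(froi.voxels) == sorted(oracle)

    def test_invariant_to_monotone_transform(self, rng):
        values = rng.standard_normal(100)
        parcel = np.arange(100)
        a = define_froi(ContrastMap(values, values, 50.0), parcel)
        b = define_froi(ContrastMap(np.exp(2 * values), values, 50.0), parcel)
        assert a.voxels == b.voxels

    def test_empty_parcel_rejected(self):
        with pytest.raises(ValueError):
            define_froi(ContrastMap(np.zeros(10), np.zeros(10), 50.0), np.array([], dtype=int))


class TestQCSubject:
    def _cmap_with_supra(self, n_supra, df=150.0):
        t_thresh = stats.t.isf(0.001, df)
        t = np.zeros(200)
        t[:n_supra] = t_thresh + 1.0
        return ContrastMap(effect=t, t=t, df=df)

    def test_boundary_99_fails_100_passes(self):
        masks = [np.arange(200)]
        ok99, n99 = qc_subject(self._cmap_with_supra(99), masks)
        ok100, n100 = qc_subject(self._cmap_with_supra(100), masks)
        assert (ok99, n99) == (False, 99)
        assert (ok100, n100) == (True, 100)

    def test_zero_map_fails(self):
        ok, n = qc_subject(self._cmap_with_supra(0), [np.arange(200)])
        assert not ok and n == 0

    def test_planted_effect_counted(self, rng):
        df = 150.0
        t = rng.normal(0, 1, 500)
        t[:150] = 10.0  # strong planted effect in 150 mask voxels
        cmap = ContrastMap(effect=t, t=t, df=df)
        ok, n = qc_subject(cmap, [np.arange(150)])
        assert ok and n == 150


class TestExcludeOverlap:
    def test_disjoint_unchanged(self):
        f1 = FROI(0, "p1", "language", (1, 2, 3))
        f2 = FROI(0, "p2", "tom", (4, 5))
        out, report = exclude_overlap([f1, f2])
        assert out[0].voxels == (1, 2, 3) and out[1].voxels == (4, 5)
        assert report["n_overlap"].sum() == 0

    def test_shared_voxels_removed_from_both(self):
        shared = tuple(range(7))
        f1 = FROI(0, "p1", "language", shared + (10, 11))
        f2 = FROI(0, "p2", "tom", shared + (20,))
        out, report = exclude_overlap([f1, f2])
        assert out[0].voxels == (10, 11)
        assert out[1].voxels == (20,)
        assert report["n_overlap"].iloc[0] == 7

    def test_same_network_overlap_kept(self):
        f1 = FROI(0, "p1", "language", (1, 2))
        f2 = FROI(0, "p2", "language", (2, 3))
        out, _ = exclude_overlap([f1, f2])
        assert out[0].voxels == (1, 2) and out[1].voxels == (2, 3)

    def test_matches_set_difference_oracle(self, rng):
        frois = []
        for s in range(3):
            for net, p in (("language", "a"), ("tom", "b"), ("md", "c")):
                vox = tuple(sorted(rng.choice(50, size=12, replace=False).tolist()))
                frois.append(FROI(s, p, net, vox))
        out, _ = exclude_overlap(frois)
        for f_new, f_old in zip(out, frois):
            # oracle: brute-force set difference against all other-network voxels
            others = set()
            for g in frois:
                if g.subject == f_old.subject and g.network != f_old.network:
                    others |= set(g.voxels)
            assert set(f_new.voxels) == set(f_old.voxels) - others

    def test_cross_subject_overlap_ignored(self):
        f1 = FROI(0, "p1", "language", (1, 2))
        f2 = FROI(1, "p2", "tom", (1, 2))
        out, _ = exclude_overlap([f1, f2])
        assert out[0].voxels == (1, 2) and out[1].voxels == (1, 2)
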