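"""Study-2 battery: hemodynamics, GLM, PCA, contrasts, spatial ANOVA and
multiple-testing corrections."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from abrnirs import battery as bt
from abrnirs import stimuli as st
from abrnirs import synthetic as sy

from _oracles import bh_brute as _bh_brute
from _oracles import holm_brute as _holm_brute

FS = 10.0


class TestTotalHemoglobin:
    def test_examples(self):
        assert bt.total_hemoglobin(np.array(1.2), np.array(-0.4)) == pytest.approx(0.8)
        x = np.linspace(-1, 1, 50)
        assert np.abs(bt.total_hemoglobin(x, -x)).max() == 0.0

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.normal(size=(2, 4, 100))
        expect = np.array([[a[i, j] + b[i, j] for j in range(100)] for i in range(4)])
        assert np.array_equal(bt.total_hemoglobin(a, b), expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bt.total_hemoglobin(np.zeros(3), np.zeros(4))


class TestSmooth:
    def test_constant_unchanged(self):
        x = np.full((2, 50), 3.3)
        assert np.allclose(bt.smooth(x, FS, 0.5), x)

    def test_impulse_response(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = bt.smooth(x, sample_rate=25.0, window_s=0.2)  # 5-sample window
        assert np.allclose(out[8:13], 0.2)
        assert np.abs(out[:8]).max() == 0.0

    def test_noise_variance_reduction(self, rng):
        x = rng.normal(size=100_000)
        w = 5
        out = bt.smooth(x, sample_rate=1.0, window_s=w)
        assert out.var() / x.var() == pytest.approx(1 / w, rel=0.20)


class TestEpochBlocks:
    def test_constant_signal_zero_epochs(self, warble_protocol):
        data = np.full((2, 920), 7.0)
        ep = bt.epoch_blocks(data, FS, warble_protocol.onsets("warble"))
        assert ep.percent.shape[:2] == (2, 3)
        assert np.abs(ep.percent).max() == 0.0

    def test_three_onsets_three_epochs(self, fnirs_pair, warble_protocol):
        raw, _, _ = fnirs_pair
        ep = bt.epoch_blocks(raw.data, FS, warble_protocol.onsets("warble"))
        assert ep.percent.shape[1] == 3
        assert ep.n_dropped == 0

    def test_out_of_range_epoch_dropped(self):
        data = np.ones((1, 100))
        ep = bt.epoch_blocks(data, FS, np.array([1.0, 5.0]))
        assert ep.n_dropped >= 1

    def test_injected_beta_recovered_as_percent(self, warble_protocol):
        truth = sy.HemoTruth(channel_betas=np.array([-0.02]), cardiac_amp=0,
                             respiratory_amp=0, vasomotor_amp=0,
                             drift_slope=0, noise_sd=0)
        raw, _ = sy.simulate_fnirs(warble_protocol, truth, ["ch"])
        ep = bt.epoch_blocks(raw.data, FS, warble_protocol.onsets("warble")[:1])
        assert ep.percent.min() == pytest.approx(-2.0, rel=0.10)


class TestGrandAverageAndPca:
    def test_identical_epochs_sem_zero(self):
        x = np.tile(np.sin(np.linspace(0, 5, 80)), (6, 1))
        mean, sem = bt.grand_average(x)
        assert np.allclose(mean, x[0])
        assert np.abs(sem).max() <= 1e-12

    def test_two_symmetric_epochs(self):
        a = np.linspace(0.5, 2.0, 40)
        mean, sem = bt.grand_average(np.vstack([a, -a]))
        assert np.abs(mean).max() <= 1e-12
        assert np.allclose(sem, a)

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError):
            bt.grand_average(np.ones((1, 10)))

    def test_cohort_trough_near_truth(self, warble_protocol):
        truth = sy.HemoTruth(seed=21)
        raw, _ = sy.simulate_fnirs(warble_protocol, truth)
        ep = bt.epoch_blocks(raw.data, FS, warble_protocol.onsets("warble"))
        mean, _ = bt.grand_average(ep.percent.reshape(-1, ep.percent.shape[-1]))
        trough_s = ep.times[np.argmin(mean)]
        assert abs(trough_s - truth.trough_latency) <= 2.0

    def test_rank_one_matrix_pc1_explains_all(self, rng):
        pattern = np.sin(np.linspace(0, 6, 120))
        X = np.outer(rng.normal(size=30), pattern)
        res = bt.pca_epochs(X)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_components_orthogonal_and_fractions_valid(self, rng):
        res = bt.pca_epochs(rng.normal(size=(40, 60)))
        G = res.components @ res.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-9)
        f = res.explained_variance_fraction
        assert np.all(f >= 0) and np.all(np.diff(f) <= 1e-12) and f.sum() <= 1 + 1e-9

    def test_pc1_recovers_injected_kernel(self, warble_protocol):
        """With task-locked structure and measurement noise (no shared
        systemic oscillations, which are a separate confound), PC1 is the
        injected hemodynamic kernel."""
        truth = sy.HemoTruth(seed=33)
        epochs = []
        for s in range(10):
            raw, _ = sy.simulate_fnirs(
                warble_protocol,
                sy.HemoTruth(seed=100 + s, cardiac_amp=0.0,
                             respiratory_amp=0.0, vasomotor_amp=0.0),
            )
            ep = bt.epoch_blocks(raw.data, FS, warble_protocol.onsets("warble"))
            epochs.append(ep.percent.reshape(-1, ep.percent.shape[-1]))
        res = bt.pca_epochs(np.concatenate(epochs, axis=0))
        kernel = sy.gamma_response_kernel(truth.trough_latency,
                                          truth.response_duration, FS)
        ref = np.zeros(ep.times.size)
        post = ep.times >= 0
        ref[post] = -kernel[: post.sum()]
        r = np.corrcoef(res.components[0], ref)[0, 1]
        assert abs(r) > 0.9


class TestGlm:
    def test_noiseless_beta_recovery(self, warble_protocol):
        n = 920
        reg = bt.task_regressor(n, FS, warble_protocol)
        fit = bt.glm_single(2.0 * reg, FS, warble_protocol)
        assert fit["beta"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_beta_field_recovery_at_moderate_noise(self, warble_protocol):
        rng = np.random.default_rng(7)
        est, true = [], []
        for s in range(8):
            betas = -np.abs(rng.normal(0.02, 0.008, size=8))
            truth = sy.HemoTruth(channel_betas=betas, noise_sd=0.01, seed=200 + s)
            raw, _ = sy.simulate_fnirs(warble_protocol, truth)
            fit = bt.glm_single(bt.fractional_change(raw.data), FS, warble_protocol)
            est.extend(fit["beta"])
            true.extend(-betas)
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.95

    def test_group_table_shape_and_flags(self, warble_protocol):
        cohort = [sy.simulate_fnirs(warble_protocol, sy.HemoTruth(seed=s))[0]
                  for s in range(5)]
        fit = bt.glm_task(cohort, warble_protocol)
        assert list(fit.table["channel"]) == [f"Ch {i}" for i in range(1, 9)]
        assert (fit.table["significant"] == (fit.table["p_fdr"] < 0.05)).all()
        assert fit.subject_betas.shape == (5, 8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            bt._ols(np.ones((1, 10)), np.ones((10, 2)))


class TestCrossCorr:
    def test_series_equals_regressor(self, warble_protocol):
        reg = bt.task_regressor(920, FS, warble_protocol)
        df = bt.crosscorr_channels(reg[None, :], reg, FS)
        assert df["peak_r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert df["lag_r_s"].iloc[0] == 0.0

    def test_negated_series(self, warble_protocol):
        reg = bt.task_regressor(920, FS, warble_protocol)
        df = bt.crosscorr_channels(-reg[None, :], reg, FS)
        assert df["peak_r"].iloc[0] == pytest.approx(-1.0, abs=1e-9)
        assert df["lag_r_s"].iloc[0] == 0.0

    def test_task_locked_decrease_is_negative(self, warble_protocol):
        cohort = [sy.simulate_fnirs(warble_protocol, sy.HemoTruth(seed=s))[0]
                  for s in range(5)]
        table = bt.crosscorr_task(cohort, warble_protocol)
        assert (table["mean_peak_r"] < 0).all()
        assert (table["mean_peak_cov"] < 0).all()

    def test_group_detection_rate_at_default_effect(self, warble_protocol):
        detections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = [
                sy.simulate_fnirs(warble_protocol,
                                  sy.HemoTruth(seed=seed * 100 + s))[0]
                for s in range(10)
            ]
            table = bt.crosscorr_task(cohort, warble_protocol)
            detections += int((table["p_value"] < 0.05).all())
        assert detections >= 19  # >= 95% of seeds


class TestContrast:
    def test_segment_against_itself(self, rng):
        x = rng.normal(size=20)
        r, p = bt.compare_segments(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_injected_response_vs_flat_silence(self, warble_protocol):
        truth = sy.HemoTruth(channel_betas=np.array([-0.02]), cardiac_amp=0,
                             respiratory_amp=0, vasomotor_amp=0,
                             drift_slope=0, noise_sd=0)
        _, chromo = sy.simulate_fnirs(warble_protocol, truth, ["ch"])
        _, _, hbt, _ = chromo.chromophores()
        cm = bt.stim_silence_contrast([(hbt, FS)], warble_protocol)
        assert (cm.p_matrix < 0.05).any()
        assert cm.p_values.size == 9

    def test_matrix_marks_consistent(self, fnirs_pair, warble_protocol):
        _, chromo, _ = fnirs_pair
        _, _, hbt, _ = chromo.chromophores()
        cm = bt.stim_silence_contrast([(hbt, FS)], warble_protocol)
        assert cm.r_matrix.shape == cm.p_matrix.shape == (3, 3)
        assert np.array_equal(cm.r_marks, np.abs(cm.r_matrix) > 0.25)
        assert np.array_equal(cm.p_marks, cm.p_matrix < 0.05)
        counts, edges = cm.p_histogram()
        assert 0.05 in edges
        assert counts.sum() == cm.p_values.size

    def test_unequal_segments_rejected(self):
        with pytest.raises(ValueError):
            bt.compare_segments(np.zeros(5), np.zeros(6))


def _rm_anova_closed_form(B):
    """Textbook one-way repeated-measures decomposition."""
    S, C = B.shape
    grand = B.mean()
    ss_ch = S * ((B.mean(axis=0) - grand) ** 2).sum()
    ss_subj = C * ((B.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((B - grand) ** 2).sum() - ss_ch - ss_subj
    df1, df2 = C - 1, (C - 1) * (S - 1)
    return (ss_ch / df1) / (ss_err / df2), df1, df2


class TestSpatialAnova:
    def test_identical_channels_f_zero(self):
        B = np.tile(np.random.default_rng(0).normal(size=(12, 1)), (1, 5))
        res = bt.spatial_anova(B)
        assert res.F_value == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_dfs_for_8_channels_23_subjects(self, rng):
        res = bt.spatial_anova(rng.normal(size=(23, 8)))
        assert (res.df_num, res.df_den) == (7.0, 154.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form(self, seed):
        B = np.random.default_rng(seed).normal(size=(9, 6))
        res = bt.spatial_anova(B)
        F, df1, df2 = _rm_anova_closed_form(B)
        assert res.F_value == pytest.approx(F, rel=1e-9)
        assert (res.df_num, res.df_den) == (df1, df2)

    def test_posthoc_matrix_properties(self, rng):
        res = bt.spatial_anova(rng.normal(size=(10, 4)))
        M = res.posthoc.to_numpy()
        assert np.allclose(M, M.T, equal_nan=True)
        assert np.isnan(np.diag(M)).all()
        off = M[~np.isnan(M)]
        assert np.all((off >= 0) & (off <= 1))

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            bt.spatial_anova(rng.normal(size=(1, 8)))
        with pytest.raises(ValueError):
            bt.spatial_anova(rng.normal(size=(8, 1)))




class TestCorrections:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(
            bt.holm_correct([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bt.fdr_correct([0.001, 0.01, 0.03, 0.04]), [0.004, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bt.holm_correct([0.3])[0] == 0.3
        assert bt.fdr_correct([0.3])[0] == 0.3

    def test_equal_ps_unchanged_by_bh(self):
        np.testing.assert_allclose(bt.fdr_correct([0.2] * 5), [0.2] * 5)

    def test_invalid_p_rejected(self):
        for fn in (bt.holm_correct, bt.fdr_correct):
            with pytest.raises(ValueError):
                fn([0.5, 1.2])

    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=80, derandomize=True)
    def test_matches_brute_force(self, p):
        p = np.array(p)
        np.testing.assert_allclose(bt.holm_correct(p), _holm_brute(p), atol=1e-12)
        np.testing.assert_allclose(bt.fdr_correct(p), _bh_brute(p), atol=1e-12)

    def test_all_permutations_of_small_sets(self):
        base = [0.011, 0.2, 0.04, 0.9, 0.0005]
        for perm in itertools.permutations(base):
            p = np.array(perm)
            np.testing.assert_allclose(bt.holm_correct(p), _holm_brute(p), atol=1e-12)
            np.testing.assert_allclose(bt.fdr_correct(p), _bh_brute(p), atol=1e-12)
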