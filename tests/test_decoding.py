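"""Decoder ensembles: splits, tuning, effective r-squared, bootstrap curves."""

import numpy as np
import pytest

from neurosong.containers import Spectrogram
from neurosong.decoding import (
    DecoderConfig,
    DecoderEnsemble,
    aggregate_grid_indices,
    decoding_split,
    duration_curve,
    effective_r_squared,
    electrode_count_curve,
    fit_decoder_ensemble,
    mlp_param_count,
    tune_hyperparameter,
)
from neurosong.encoding import r_squared
from neurosong.features import LagMatrix, build_lag_matrix


def _linear_problem(rng, n_frames=3000, n_elec=8, n_lags=10, noise=0.3):
    """HFA linear in a smooth Gaussian target; returns (lag matrix, y full)."""
    from scipy import signal as sig

    b, a = sig.butter(2, 8.0, fs=100.0)
    target = sig.lfilter(b, a, rng.normal(size=n_frames))
    target /= target.std()
    hfa = np.column_stack([
        np.convolve(target, rng.normal(size=5), mode="same") + noise * rng.normal(size=n_frames)
        for _ in range(n_elec)
    ])
    base = build_lag_matrix(hfa, np.zeros(n_frames), n_lags=n_lags, direction="anticausal")
    lm = LagMatrix(X=base.X, y=target[base.frame_index], frame_index=base.frame_index,
                   column_map=base.column_map, n_channels=n_elec, n_lags=n_lags,
                   direction="anticausal")
    return lm, target


class TestParamCount:
    def test_printed_formula(self):
        assert mlp_param_count(347, 50, 64) == 347 * 50 * 64 + 64 * 64 + 64
        assert mlp_param_count(1, 1, 1) == 3

    def test_linear_feature_count_is_e_times_l(self):
        lm, _ = _linear_problem(np.random.default_rng(0), n_frames=200)
        assert lm.n_features == 8 * 10


class TestGridAggregation:
    def test_constant_indices(self):
        grid = (0.1, 0.2, 0.3, 0.4, 0.5)
        assert aggregate_grid_indices(np.array([3, 3, 3]), grid) == 0.4

    def test_rounding_of_mean_index(self):
        grid = tuple(float(v) for v in range(10))
        idx = np.array([2, 3, 3, 3, 4, 4, 4, 4, 5, 5])  # mean 3.7 -> index 4
        assert aggregate_grid_indices(idx, grid) == 4.0


class TestDecodingSplit:
    def test_fixed_test_never_in_train_or_val(self):
        vocal = np.zeros(6000, bool)
        vocal[1000:3000] = True
        for seed in range(5):
            split = decoding_split(6000, vocal, (3000, 4500), seed=seed)
            test = set(range(3000, 4500))
            assert not test & set(split.train)
            assert not test & set(split.val)
            np.testing.assert_array_equal(split.test, np.arange(3000, 4500))

    def test_blocks_overlapping_test_are_excluded_entirely(self):
        vocal = np.zeros(6000, bool)
        vocal[1000:3000] = True
        split = decoding_split(6000, vocal, (3100, 4400), block_len_s=5.0, seed=0)
        allocated = set(split.train) | set(split.val)
        # blocks [3000,3500) and [4000,4500) straddle the interval: fully out
        assert not allocated & set(range(3000, 4500))

    def test_different_seeds_differ(self):
        vocal = np.zeros(6000, bool)
        vocal[1000:3000] = True
        a = decoding_split(6000, vocal, (3000, 4500), seed=1)
        b = decoding_split(6000, vocal, (3000, 4500), seed=2)
        assert not np.array_equal(a.train, b.train)


class TestTuning:
    def test_tuned_value_near_oracle_optimum(self, rng):
        lm, _ = _linear_problem(rng)
        grid = (1e-6, 3e-4, 10.0)  # too small / sensible / divergent step sizes
        cfg = DecoderConfig(model_type="linear", n_lags=10, hyper_grid=grid,
                            n_tune_resamples=3)
        tuned, best_idx = tune_hyperparameter(lm, np.zeros(3000, bool), cfg,
                                              (2000, 2500), 3000, seed=0)
        assert tuned == 3e-4
        assert np.all(best_idx == 1)


class TestEnsembleAndEffectiveR2:
    def test_linear_path_matches_normal_equations(self, rng):
        lm, _ = _linear_problem(rng)
        cfg = DecoderConfig(model_type="linear", n_lags=10, n_models=3)
        ens = fit_decoder_ensemble(lm, np.zeros(3000, bool), cfg, (2000, 2500), 3000,
                                   tuned_hyper=3e-4, seed=0)
        rows_te = lm.rows_for_frames(np.arange(2000, 2500))
        rows_tr = ~rows_te
        A = np.column_stack([np.ones(rows_tr.sum()), lm.X[rows_tr]])
        coef, *_ = np.linalg.lstsq(A, lm.y[rows_tr], rcond=None)
        y_hat = np.column_stack([np.ones(rows_te.sum()), lm.X[rows_te]]) @ coef
        oracle = r_squared(lm.y[rows_te], y_hat)
        assert ens.r2.mean() == pytest.approx(oracle, abs=0.05)

    def test_zero_signal_effective_r2_near_zero(self, rng):
        lm, _ = _linear_problem(rng)
        lm = LagMatrix(X=lm.X, y=rng.normal(size=lm.y.size), frame_index=lm.frame_index,
                       column_map=lm.column_map, n_channels=lm.n_channels,
                       n_lags=lm.n_lags, direction="anticausal")
        cfg = DecoderConfig(model_type="linear", n_lags=10, n_models=3)
        ens = fit_decoder_ensemble(lm, np.zeros(3000, bool), cfg, (2000, 2500), 3000,
                                   tuned_hyper=3e-4, seed=0)
        _, _, eff = effective_r_squared(ens)
        assert eff <= 0.05

    def test_mlp_path_runs_and_learns(self, rng):
        lm, _ = _linear_problem(rng, noise=0.2)
        cfg = DecoderConfig(model_type="mlp", n_lags=10, n_models=2, best_of=2,
                            hidden_units=16, mlp_max_iter=150)
        ens = fit_decoder_ensemble(lm, np.zeros(3000, bool), cfg, (2000, 2500), 3000,
                                   tuned_hyper=1e-3, seed=0)
        _, _, eff = effective_r_squared(ens)
        assert eff > 0.3

    def test_identical_models_effective_equals_single(self, rng):
        y = rng.normal(size=100)
        pred = y + 0.3 * rng.normal(size=100)
        ens = DecoderEnsemble(
            predictions=np.tile(pred, (10, 1)),
            r2=np.full(10, r_squared(y, pred)),
            r=np.full(10, 0.9), y_test=y, model_type="linear", tuned_hyper=1.0,
        )
        best_n, avg, eff = effective_r_squared(ens)
        assert eff == pytest.approx(r_squared(y, pred))
        assert best_n == 10  # ties break toward larger n

    def test_one_perfect_model_among_noise(self, rng):
        y = rng.normal(size=200)
        preds = [y] + [rng.normal(size=200) for _ in range(9)]
        r2s = np.array([r_squared(y, p) for p in preds])
        ens = DecoderEnsemble(predictions=np.array(preds), r2=r2s,
                              r=np.zeros(10), y_test=y, model_type="linear",
                              tuned_hyper=1.0)
        best_n, _, eff = effective_r_squared(ens)
        assert best_n == 1 and eff == pytest.approx(1.0)

    def test_averaging_noisy_models_selects_n_above_one(self, rng):
        y = rng.normal(size=500)
        preds = np.array([y + 0.8 * rng.normal(size=500) for _ in range(20)])
        r2s = np.array([r_squared(y, p) for p in preds])
        ens = DecoderEnsemble(predictions=preds, r2=r2s, r=np.zeros(20), y_test=y,
                              model_type="linear", tuned_hyper=1.0)
        best_n, _, eff = effective_r_squared(ens)
        assert best_n > 1
        assert eff > r2s.max()


class TestBootstrapCurves:
    @pytest.fixture(scope="class")
    def curve_setup(self, small_stimulus, small_cohort):
        _, hfa = small_cohort
        target = Spectrogram(
            values=small_stimulus.spectrogram.values[:, ::4],
            frame_rate=100.0,
            center_frequencies=small_stimulus.spectrogram.center_frequencies[::4],
        )
        # short 2 s blocks so even 30 s excerpts keep >= 2 blocks per stratum
        cfg = DecoderConfig(model_type="linear", n_lags=10, block_len_s=2.0)
        return hfa, target, small_stimulus.vocal_mask, cfg

    def test_electrode_count_curve_properties(self, curve_setup):
        hfa, target, vocal, cfg = curve_setup
        curve = electrode_count_curve(hfa, target, vocal, cfg, (2800, 3600),
                                      counts=(4, 12), n_resamples=3, seed=0)
        assert curve.y_mean[-1] == pytest.approx(100.0)  # full set is the reference
        assert np.all(curve.y_mean > 0) and np.all(curve.y_mean <= 130)
        assert curve.samples.shape == (2, 3)

    def test_oversized_count_dropped_with_warning(self, curve_setup, caplog):
        hfa, target, vocal, cfg = curve_setup
        with caplog.at_level("WARNING"):
            curve = electrode_count_curve(hfa, target, vocal, cfg, (2800, 3600),
                                          counts=(4, 500), n_resamples=2, seed=0)
        assert curve.x.tolist() == [4.0]
        assert any("dropping electrode count" in m for m in caplog.messages)

    def test_duration_curve_properties(self, curve_setup):
        hfa, target, vocal, cfg = curve_setup
        curve = duration_curve(hfa, target, vocal, cfg, (2800, 3600),
                               durations_s=(30.0, 40.0), n_resamples=3, seed=0)
        assert curve.y_mean[-1] == pytest.approx(100.0)  # full duration = reference
        assert np.all(np.isfinite(curve.y_mean))
        assert len(curve.fit_params) == 3
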