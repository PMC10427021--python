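"""STRF fitting, bootstrap significance, and region statistics."""

import numpy as np
import pandas as pd
import pytest

from neurosong import synthetic
from neurosong.audio import log_compress
from neurosong.encoding import (
    StrfConfig,
    bootstrap_strf,
    chi_square_proportions,
    fit_strf_single,
    prediction_accuracy_anova,
)
from neurosong.features import build_lag_matrix, drop_outlier_rows, group_stratified_shuffle_split


def _lag_setup(noise_sd, archetype="onset", seed=5, duration=40.0):
    stim = synthetic.generate_stimulus(duration_s=duration, vocal_interval=(8, 20),
                                       seed=seed, n_bins=16)
    els = synthetic.generate_electrodes({archetype: 1} if archetype != "none" else {},
                                        n_noise=1 if archetype == "none" else 0,
                                        seed=seed, noise_sd=noise_sd,
                                        n_bins=16, n_lags=20)
    hfa = synthetic.simulate_hfa(stim, els, seed=seed)
    spec_log = log_compress(stim.spectrogram).values
    lm = build_lag_matrix(spec_log, hfa.values[:, 0], n_lags=20)
    lm, _ = drop_outlier_rows(lm, hfa.outlier_mask[:, 0])
    return stim, els[0], lm


class TestFitStrf:
    def test_noise_free_recovery(self):
        stim, electrode, lm = _lag_setup(noise_sd=0.0)
        split = group_stratified_shuffle_split(stim.spectrogram.n_frames, 2.0,
                                               stim.vocal_mask, seed=1)
        model, metrics = fit_strf_single(lm, split)
        assert metrics.r >= 0.99
        corr = np.corrcoef(electrode.true_weights.ravel(), model.weights.ravel())[0, 1]
        assert corr >= 0.95

    def test_quadratic_limit_matches_least_squares(self, rng):
        # well-conditioned small instance; huge Huber delta = pure quadratic
        n, F = 600, 40
        X = rng.normal(size=(n, F))
        w_true = rng.normal(size=F)
        y = X @ w_true + 0.5 + 0.05 * rng.normal(size=n)
        from neurosong.encoding import _rmsprop_fit

        cfg = StrfConfig(huber_delta=1e6, max_epochs=6000, learning_rate=3e-3,
                         patience=50, min_epochs=500)
        w, a, _ = _rmsprop_fit(X[:400], y[:400], X[400:], y[400:], cfg)
        A = np.column_stack([np.ones(400), X[:400]])
        coef, *_ = np.linalg.lstsq(A, y[:400], rcond=None)
        assert np.corrcoef(w, coef[1:])[0, 1] >= 0.999

    def test_pure_noise_r_centered_at_zero(self):
        stim, _, lm = _lag_setup(noise_sd=1.0, archetype="none")
        rs = []
        for seed in range(30):
            split = group_stratified_shuffle_split(stim.spectrogram.n_frames, 2.0,
                                                   stim.vocal_mask, seed=seed)
            _, metrics = fit_strf_single(lm, split)
            rs.append(metrics.r)
        assert abs(np.mean(rs)) < 0.05

    def test_divergence_raises_with_guidance(self):
        stim, _, lm = _lag_setup(noise_sd=0.0)
        split = group_stratified_shuffle_split(stim.spectrogram.n_frames, 2.0,
                                               stim.vocal_mask, seed=1)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="learning rate"):
                fit_strf_single(lm, split, StrfConfig(learning_rate=1e308))


class TestBootstrap:
    def test_planted_electrode_significant(self):
        stim, _, lm = _lag_setup(noise_sd=1.0, archetype="onset")
        ens, sig = bootstrap_strf(lm, stim.vocal_mask, n_boot=30, seed=0,
                                  n_frames=stim.spectrogram.n_frames)
        assert sig.is_significant
        assert ens.ci95_r[0] > 0 and ens.mean_r_squared > 0
        assert ens.z_map.shape == (16, 20)

    def test_zero_target_gives_degenerate_z_with_warning(self, caplog):
        stim, _, lm = _lag_setup(noise_sd=0.0, archetype="none")
        with caplog.at_level("WARNING"):
            ens, sig = bootstrap_strf(lm, stim.vocal_mask, n_boot=5, seed=0,
                                      n_frames=stim.spectrogram.n_frames)
        assert not sig.is_significant
        assert np.allclose(ens.z_map, 0.0)
        assert any("zero bootstrap variance" in m for m in caplog.messages)

    def test_mean_strf_peak_at_planted_peak(self):
        # noise-free: the bootstrap-mean STRF must peak where the planted
        # archetype does (the z-map itself is degenerate without noise,
        # since the across-fit sd collapses)
        stim, electrode, lm = _lag_setup(noise_sd=0.0, archetype="onset")
        ens, _ = bootstrap_strf(lm, stim.vocal_mask, n_boot=5, seed=2,
                                n_frames=stim.spectrogram.n_frames)
        true_peak = np.unravel_index(np.argmax(np.abs(electrode.true_weights)),
                                     electrode.true_weights.shape)
        peak = np.unravel_index(np.argmax(np.abs(ens.mean_weights)), ens.mean_weights.shape)
        assert abs(peak[0] - true_peak[0]) <= 1
        assert abs(peak[1] - true_peak[1]) <= 2

    def test_significance_monotone_in_snr(self):
        rates = []
        for noise_sd in (2.5, 0.5):
            hits = 0
            for rep in range(4):
                stim, _, lm = _lag_setup(noise_sd=noise_sd, archetype="rhythmic",
                                         seed=20 + rep)
                _, sig = bootstrap_strf(lm, stim.vocal_mask, n_boot=15, seed=rep,
                                        n_frames=stim.spectrogram.n_frames)
                hits += sig.is_significant
            rates.append(hits / 4)
        assert rates[1] >= rates[0]


class TestChiSquare:
    @pytest.mark.parametrize("k1,n1,k2,n2,expected", [
        (199, 1479, 148, 900, 4.01),   # hemisphere comparison
        (133, 374, 165, 654, 12.34),   # responsive-region comparison
    ])
    def test_reported_comparisons(self, k1, n1, k2, n2, expected):
        stat, df, p = chi_square_proportions(k1, n1, k2, n2)
        assert df == 1
        assert stat == pytest.approx(expected, abs=0.01)

    def test_equal_proportions_zero(self):
        stat, _, p = chi_square_proportions(10, 100, 10, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_proportions(5, 3, 1, 10)


class TestAnova:
    @staticmethod
    def _records(rng, region_shift=0.0, lat_shift=0.0, n=40):
        rows = []
        for lat in ("L", "R"):
            for region in ("STG", "SMC", "IFG", "other"):
                for _ in range(n):
                    r = 0.2 + rng.normal(0, 0.02)
                    if region == "STG":
                        r += region_shift
                    if lat == "R":
                        r += lat_shift
                    rows.append({"r": r, "laterality": lat, "region": region})
        return pd.DataFrame(rows)

    def test_shifted_region_detected_posthoc(self, rng):
        table, tukey = prediction_accuracy_anova(self._records(rng, region_shift=0.2))
        assert table.loc["C(region)", "PR(>F)"] < 1e-6
        summary = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        stg_rows = summary[(summary["group1"] == "STG") | (summary["group2"] == "STG")]
        assert stg_rows["reject"].all()

    def test_balanced_two_level_factor_f_equals_t_squared(self, rng):
        from scipy import stats

        df = self._records(rng, lat_shift=0.05)
        table, _ = prediction_accuracy_anova(df)
        t = stats.ttest_ind(df.loc[df.laterality == "R", "r"],
                            df.loc[df.laterality == "L", "r"])
        # orthogonal balanced design: additive ANOVA F ~= square of two-sample t
        assert table.loc["C(laterality)", "F"] == pytest.approx(t.statistic**2, rel=0.05)

    def test_no_effect_not_significant(self, rng):
        table, _ = prediction_accuracy_anova(self._records(rng))
        assert table.loc["C(region)", "PR(>F)"] > 0.01

    def test_single_level_factor_rejected(self, rng):
        df = self._records(rng)
        with pytest.raises(ValueError):
            prediction_accuracy_anova(df[df.laterality == "L"])
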