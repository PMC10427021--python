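"""Filter/Hilbert/CAR chain: attenuation oracles and envelope recovery."""

import numpy as np
import pytest
from scipy import signal as sig

from neurosong import synthetic
from neurosong.containers import EcogRecording, HfaMatrix
from neurosong.preproc import (
    extract_hfa,
    highpass_drift,
    median_car,
    remove_line_noise,
    robust_scale_series,
    subband_edges,
)

FS = 600.0


def make_rec(data, groups=None, pad_s=0.0):
    data = np.atleast_2d(data.T).T if data.ndim == 1 else data
    n = data.shape[1]
    return EcogRecording(
        data=data, fs=FS, electrode_ids=[f"e{i}" for i in range(n)],
        splitter_group=np.zeros(n, int) if groups is None else np.asarray(groups),
        pad_s=pad_s,
    )


def tone_data(freq, seconds=4.0, n_chan=1):
    t = np.arange(int(seconds * FS)) / FS
    return np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_chan))


class TestLineNoise:
    def test_sixty_hz_attenuated_by_95_percent(self):
        rec = make_rec(tone_data(60.0, seconds=8.0))
        out = remove_line_noise(rec, max_harmonic=290.0)
        core = slice(int(2 * FS), int(6 * FS))  # skip zero-phase filter edges
        rms_in = np.sqrt((rec.data[core] ** 2).mean())
        rms_out = np.sqrt((out.data[core] ** 2).mean())
        assert rms_out <= 0.05 * rms_in

    def test_neighboring_band_untouched(self):
        rec = make_rec(tone_data(90.0))
        out = remove_line_noise(rec, max_harmonic=290.0)
        atten_db = 20 * np.log10(np.sqrt((out.data**2).mean()) / np.sqrt((rec.data**2).mean()))
        assert atten_db > -1.0

    def test_harmonics_above_nyquist_skipped(self, caplog):
        rec = make_rec(tone_data(90.0))
        with caplog.at_level("WARNING"):
            remove_line_noise(rec, max_harmonic=300.0)
        assert any("skipping notch" in m for m in caplog.messages)

    def test_notch_centers_enumeration(self):
        edges = np.arange(60.0, 301.0, 60.0)
        np.testing.assert_allclose(edges, [60, 120, 180, 240, 300])


class TestHighpass:
    def test_constant_offset_removed(self):
        rec = make_rec(np.full((int(4 * FS), 2), 7.3))
        out = highpass_drift(rec)
        assert np.abs(out.data.mean()) < 1e-6

    @pytest.mark.parametrize("freq,min_atten_db", [(0.1, 20.0), (30.0, -1.0)])
    def test_transfer_function(self, freq, min_atten_db):
        rec = make_rec(tone_data(freq, seconds=30.0))
        out = highpass_drift(rec)
        core = slice(int(5 * FS), int(25 * FS))  # ignore filter edges
        atten_db = -20 * np.log10(
            np.sqrt((out.data[core] ** 2).mean()) / np.sqrt((rec.data[core] ** 2).mean())
        )
        assert atten_db >= min_atten_db


class TestMedianCar:
    def test_identical_channels_cancel(self):
        base = tone_data(25.0, n_chan=5)
        out = median_car(make_rec(base))
        assert np.abs(out.data).max() < 1e-12

    def test_deviant_channel_preserved(self):
        base = tone_data(25.0, n_chan=5)
        base[:, 0] += 2.0 * np.sin(2 * np.pi * 40.0 * np.arange(base.shape[0]) / FS)
        out = median_car(make_rec(base))
        assert np.abs(out.data[:, 1:]).max() < 1e-12
        assert out.data[:, 0].std() > 1.0

    def test_groups_referenced_independently(self):
        common = np.sin(2 * np.pi * 20.0 * np.arange(int(2 * FS)) / FS)
        rng = np.random.default_rng(0)
        data = np.column_stack([common + rng.normal(0, 0.01, common.size) for _ in range(6)])
        out = median_car(make_rec(data, groups=[0, 0, 0, 1, 1, 1]))
        # within-group common signal removed in both groups, never mixed across
        assert np.abs(out.data).max() < 0.1
        data2 = data.copy()
        data2[:, 3:] += 5.0  # group-1-only offset must not leak into group 0
        out2 = median_car(make_rec(data2, groups=[0, 0, 0, 1, 1, 1]))
        np.testing.assert_allclose(out2.data[:, :3], out.data[:, :3], atol=1e-9)

    def test_single_electrode_group_warns(self, caplog):
        with caplog.at_level("WARNING"):
            median_car(make_rec(tone_data(25.0, n_chan=3), groups=[0, 0, 1]))
        assert any("single electrode" in m for m in caplog.messages)


class TestRobustScale:
    def test_hand_computed_example(self):
        x = np.arange(11.0)  # median 5, P90=9, P10=1, range 8
        out = robust_scale_series(x)
        assert out[9] == pytest.approx((9 - 5) / 8)
        assert out[5] == pytest.approx(0.0)

    def test_constant_series_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = robust_scale_series(np.full(20, 3.0))
        assert np.allclose(out, 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        np.testing.assert_allclose(
            robust_scale_series(x), robust_scale_series(5.0 * x - 2.0), atol=1e-12
        )


class TestExtractHfa:
    def test_thirteen_subbands(self):
        assert len(subband_edges(70, 150, 20, 5)) == 13
        assert subband_edges(70, 150, 20, 5)[0] == (70.0, 90.0)
        assert subband_edges(70, 150, 20, 5)[-1] == (130.0, 150.0)

    def test_am_carrier_envelope_recovered(self):
        # broadband carrier so every sub-band carries the modulation; a
        # narrowband tone would leave carrier-free sub-bands degenerate
        t = np.arange(int(30 * FS)) / FS
        modulator = 1.0 + 0.95 * np.sin(2 * np.pi * 1.5 * t)
        rng = np.random.default_rng(0)
        sos = sig.butter(4, [70.0, 150.0], btype="band", fs=FS, output="sos")
        carrier = sig.sosfilt(sos, rng.normal(size=t.size))
        carrier /= carrier.std()
        out = extract_hfa(make_rec((modulator * carrier)[:, None]))
        target = 1.0 + 0.95 * np.sin(2 * np.pi * 1.5 * np.arange(out.n_frames) / 100.0)
        assert np.corrcoef(out.values[:, 0], target)[0, 1] >= 0.9

    def test_rhythmic_modulation_survives_subband_width(self):
        # a 6.66 Hz envelope modulation must pass the 20 Hz sub-band chain
        t = np.arange(int(30 * FS)) / FS
        rate = 20.0 / 3.0
        modulator = 1.0 + 0.95 * np.sin(2 * np.pi * rate * t)
        rng = np.random.default_rng(1)
        sos = sig.butter(4, [70.0, 150.0], btype="band", fs=FS, output="sos")
        carrier = sig.sosfilt(sos, rng.normal(size=t.size))
        carrier /= carrier.std()
        out = extract_hfa(make_rec((modulator * carrier)[:, None]))
        ft = np.arange(out.n_frames) / 100.0
        ref_mod = np.sin(2 * np.pi * rate * ft)
        assert np.corrcoef(out.values[:, 0], ref_mod)[0, 1] >= 0.8

    def test_outliers_tagged_beyond_seven_z(self):
        rng = np.random.default_rng(1)
        t = np.arange(int(20 * FS)) / FS
        env = np.ones_like(t)
        env[int(10 * FS) : int(10.2 * FS)] = 60.0  # brief huge artifact
        data = np.column_stack([env * np.sin(2 * np.pi * 110 * t),
                                np.sin(2 * np.pi * 110 * t) + 0.01 * rng.normal(size=t.size)])
        out = extract_hfa(make_rec(data))
        assert out.outlier_mask[:, 0].any()
        assert (np.abs(out.values[out.outlier_mask]) > 7).all()

    def test_end_to_end_raw_simulation_recovery(self):
        stim = synthetic.generate_stimulus(duration_s=20, vocal_interval=(5, 12), seed=2,
                                           n_bins=16)
        els = synthetic.generate_electrodes(
            {"onset": 4, "sustained": 4, "late_onset": 4, "rhythmic": 4},
            n_noise=0, seed=1, noise_sd=0.0, n_bins=16, n_lags=30)
        hfa = synthetic.simulate_hfa(stim, els, seed=1)
        rec = synthetic.simulate_raw_ecog(hfa, fs_out=FS, pad_s=2.0, seed=3)
        rec = remove_line_noise(rec, max_harmonic=290.0)
        rec = highpass_drift(rec)
        out = extract_hfa(rec)
        assert out.n_frames == hfa.n_frames
        for j in range(hfa.n_electrodes):
            assert np.corrcoef(out.values[:, j], hfa.values[:, j])[0, 1] >= 0.7

    def test_frame_count_after_pad_removal(self):
        t = np.arange(int(7 * FS)) / FS
        data = np.column_stack([np.sin(2 * np.pi * 110 * t)] * 2)
        out = extract_hfa(make_rec(data, pad_s=1.0))
        assert out.n_frames == 500  # 7 s minus 2 x 1 s pads at 100 Hz

    def test_band_above_nyquist_rejected(self):
        rec = make_rec(tone_data(50.0))
        with pytest.raises(ValueError):
            extract_hfa(rec, band_hi=400.0)
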