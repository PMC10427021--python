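"""Auditory spectrogram frontend and waveform reconstruction.

The forward path mimics the early auditory pathway the way cochleagram
toolboxes do: a bank of bandpass filters at geometrically spaced center
frequencies, half-wave rectification, envelope smoothing, and downsampling
to a 100 Hz frame rate.  Downstream analyses only consume a nonnegative,
log-spaced time-frequency magnitude, so a Butterworth filterbank is used
rather than a full cochlear model (no phase-locking limit, no lateral
inhibition).

The inverse path maps the log-spaced magnitude back onto a linear-frequency
short-time Fourier grid by interpolation and runs iterative phase
estimation (Griffin-Lim alternating projection) to produce a waveform from
the magnitude-only representation.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sig
from scipy.io import wavfile

from .containers import Spectrogram, Waveform

__all__ = [
    "geometric_center_frequencies",
    "compute_auditory_spectrogram",
    "log_compress",
    "square_magnitudes",
    "invert_spectrogram",
    "sixteenth_note_rate",
    "read_wav",
    "write_wav",
]


def sixteenth_note_rate(tempo_bpm: float) -> float:
    """Rate of 16th notes in Hz for a given tempo: 4 notes per beat.

    rate(100) = 6.66... Hz, i.e. a 150 ms period.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    return 4.0 * tempo_bpm / 60.0


def geometric_center_frequencies(f_min: float, f_max: float, n_bins: int) -> np.ndarray:
    """Center frequencies f_k = f_min * (f_max/f_min)**(k/(n_bins-1)).

    Endpoint-exact geometric spacing: hits both f_min and f_max.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if not 0 < f_min < f_max:
        raise ValueError("require 0 < f_min < f_max")
    k = np.arange(n_bins)
    return f_min * (f_max / f_min) ** (k / (n_bins - 1))


def _resample_to_rate(x: np.ndarray, fs: float, rate: float, n_out: int) -> np.ndarray:
    """Polyphase anti-aliased resample of columns from fs to rate; exact length n_out."""
    frac = Fraction(rate / fs).limit_denominator(10**6)
    y = sig.resample_poly(x, frac.numerator, frac.denominator, axis=0)
    if y.shape[0] >= n_out:
        return y[:n_out]
    pad = np.repeat(y[-1:], n_out - y.shape[0], axis=0)
    return np.concatenate([y, pad], axis=0)


def compute_auditory_spectrogram(
    w: Waveform,
    n_bins: int = 32,
    f_min: float = 188.0,
    f_max: float = 6745.0,
    frame_rate: float = 100.0,
    env_cutoff_hz: float = 30.0,
    filter_order: int = 2,
) -> Spectrogram:
    """Magnitude auditory spectrogram of a waveform.

    Per band: zero-phase Butterworth bandpass at geometrically spaced center
    frequencies (band edges at the geometric midpoints to neighbours),
    half-wave rectification, low-pass envelope smoothing (``env_cutoff_hz``,
    a config stand-in for the unspecified cochlear smoothing constant), and
    polyphase downsampling to ``frame_rate``.  Output frame count is
    round(duration * frame_rate).
    """
    nyq = w.sample_rate / 2.0
    if not f_min < f_max < nyq:
        raise ValueError("require f_min < f_max < Nyquist")
    cf = geometric_center_frequencies(f_min, f_max, n_bins)
    half_step = (f_max / f_min) ** (0.5 / (n_bins - 1))
    n_frames = int(round(w.duration_s * frame_rate))

    env_sos = sig.butter(filter_order, env_cutoff_hz, btype="low", fs=w.sample_rate, output="sos")
    bands = np.empty((w.samples.size, n_bins))
    for k, f in enumerate(cf):
        lo = f / half_step
        hi = min(f * half_step, 0.999 * nyq)
        sos = sig.butter(filter_order, [lo, hi], btype="band", fs=w.sample_rate, output="sos")
        band = sig.sosfiltfilt(sos, w.samples)
        env = np.maximum(band, 0.0)
        bands[:, k] = sig.sosfiltfilt(env_sos, env)

    values = _resample_to_rate(bands, w.sample_rate, frame_rate, n_frames)
    np.clip(values, 0.0, None, out=values)
    return Spectrogram(values=values, frame_rate=frame_rate, center_frequencies=cf, scale="magnitude")


def log_compress(s: Spectrogram, floor: float | None = None) -> Spectrogram:
    """values <- log(values + floor); compresses dynamic range, order-preserving.

    ``floor`` defaults to 1e-5 of the spectrogram maximum so the dynamic
    range is bounded regardless of input gain.
    """
    if s.scale != "magnitude":
        raise ValueError("log_compress expects a magnitude-scale spectrogram")
    if floor is None:
        peak = float(s.values.max()) if s.values.size else 0.0
        floor = 1e-5 * peak if peak > 0 else 1e-12
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    return Spectrogram(
        values=np.log(s.values + floor),
        frame_rate=s.frame_rate,
        center_frequencies=s.center_frequencies,
        scale="log",
    )


def square_magnitudes(s: Spectrogram) -> Spectrogram:
    """Clip at zero and square elementwise; sharpens prominent elements."""
    if s.scale != "magnitude":
        raise ValueError("square_magnitudes expects a magnitude-scale spectrogram")
    return Spectrogram(
        values=np.clip(s.values, 0.0, None) ** 2,
        frame_rate=s.frame_rate,
        center_frequencies=s.center_frequencies,
        scale="magnitude",
    )


def _stft_grid(n_samples: int, fs: float, nperseg: int, hop: int):
    noverlap = nperseg - hop
    f, t, Z = sig.stft(
        np.zeros(n_samples), fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        padded=True, boundary="zeros",
    )
    return f, Z.shape[1]


def invert_spectrogram(
    s: Spectrogram,
    n_iter: int = 500,
    seed: int = 0,
    sample_rate: float = 16000.0,
    nperseg: int = 512,
    return_error: bool = False,
):
    """Griffin-Lim-style inversion of a magnitude auditory spectrogram.

    The log-spaced bins are interpolated onto the linear-frequency STFT grid
    frame by frame, phases are initialized at random (seeded), and the
    alternating projection onto the sets of consistent STFTs and of
    magnitude-matching STFTs runs for ``n_iter`` iterations.  The internal
    magnitude-mismatch error is non-increasing up to numerical tolerance.
    An all-zero spectrogram returns silence.
    """
    if s.scale != "magnitude":
        raise ValueError("inversion expects a magnitude-scale spectrogram")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if sample_rate / 2.0 <= s.center_frequencies[-1]:
        raise ValueError("sample_rate too low for the spectrogram's top bin")

    hop = int(round(sample_rate / s.frame_rate))
    n_samples = s.n_frames * hop
    f_lin, n_slices = _stft_grid(n_samples, sample_rate, nperseg, hop)

    # interpolate auditory bins -> linear STFT magnitude target
    cf = s.center_frequencies
    target = np.zeros((f_lin.size, n_slices))
    in_band = (f_lin >= cf[0]) & (f_lin <= cf[-1])
    frames = np.clip(s.values, 0.0, None)
    for j in range(min(s.n_frames, n_slices)):
        target[in_band, j] = np.interp(f_lin[in_band], cf, frames[j])

    if not np.any(target > 0):
        out = Waveform(samples=np.zeros(n_samples), sample_rate=sample_rate)
        return (out, np.zeros(n_iter)) if return_error else out

    rng = np.random.default_rng(seed)
    noverlap = nperseg - hop
    stft_kw = dict(fs=sample_rate, window="hann", nperseg=nperseg, noverlap=noverlap)
    phase = np.exp(1j * rng.uniform(-np.pi, np.pi, target.shape))
    ref = np.linalg.norm(target)
    errors = np.empty(n_iter)
    x = np.zeros(n_samples)
    for it in range(n_iter):
        _, x = sig.istft(target * phase, **stft_kw)
        _, _, Z = sig.stft(x[:n_samples], padded=True, boundary="zeros", **stft_kw)
        Z = Z[:, : target.shape[1]]
        if Z.shape[1] < target.shape[1]:
            Z = np.pad(Z, ((0, 0), (0, target.shape[1] - Z.shape[1])))
        errors[it] = np.linalg.norm(np.abs(Z) - target) / ref
        phase = np.exp(1j * np.angle(Z))
    _, x = sig.istft(target * phase, **stft_kw)
    x = np.asarray(x[:n_samples], dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.9 * x / peak
    out = Waveform(samples=x, sample_rate=sample_rate)
    return (out, errors) if return_error else out


def read_wav(path: str | Path) -> Waveform:
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data.astype(float), sample_rate=float(fs))


def write_wav(w: Waveform, path: str | Path, dtype: str = "float32") -> None:
    if dtype == "float32":
        wavfile.write(str(path), int(w.sample_rate), w.samples.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(w.samples, -1.0, 1.0) * 32767.0
        wavfile.write(str(path), int(w.sample_rate), scaled.astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")
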