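"""Synthetic song-like stimuli and simulated neural responses.

Emulates the structure of the study conditions so every downstream stage is
testable without the real recordings: a 100 Hz, 32-band nonnegative
auditory spectrogram with vocal/instrumental segments, note-onset events
every 2 bars and a 16th-note (6.66 Hz at 100 bpm) rhythmic amplitude
modulation; per-electrode high-frequency activity generated as
lagged-linear responses through parametric receptive-field archetypes plus
Gaussian noise; and optionally a raw "recording" whose 70-150 Hz carrier
envelope follows the simulated activity, with line noise and 1/f
background, for end-to-end preprocessing tests.

Receptive-field archetypes are Gabor-like patches (Gaussian in
log-frequency x Gaussian or comb in lag), matching qualitatively the four
motifs seen in auditory cortex: transient broadband tuning ~90 ms before
the response (onset), the same at ~210 ms (late onset), persistent
narrowband high-frequency tuning across the 750 ms window (sustained), and
lag-axis periodicity at the 16th-note period of 150 ms (rhythmic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HfaMatrix, Spectrogram
from .audio import geometric_center_frequencies, sixteenth_note_rate

__all__ = [
    "SyntheticStimulus",
    "GroundTruthElectrode",
    "archetype_weights",
    "generate_stimulus",
    "generate_electrodes",
    "simulate_hfa",
    "simulate_raw_ecog",
    "electrode_frame",
]

N_BINS = 32
N_LAGS = 75
LAG_STEP_MS = 10.0
ARCHETYPES = ("onset", "sustained", "late_onset", "rhythmic", "none")


@dataclass
class SyntheticStimulus:
    """Song-like auditory spectrogram with ground-truth annotations."""

    spectrogram: Spectrogram
    vocal_mask: np.ndarray
    event_onsets_s: np.ndarray
    tempo_bpm: float
    seed: int

    def __post_init__(self) -> None:
        self.vocal_mask = np.asarray(self.vocal_mask, dtype=bool)
        self.event_onsets_s = np.asarray(self.event_onsets_s, dtype=float)
        if self.vocal_mask.size != self.spectrogram.n_frames:
            raise ValueError("vocal_mask length must equal frame count")
        if self.event_onsets_s.size and (
            np.any(np.diff(self.event_onsets_s) <= 0)
            or self.event_onsets_s[-1] >= self.spectrogram.duration_s
        ):
            raise ValueError("event onsets must be strictly increasing and < duration")


@dataclass
class GroundTruthElectrode:
    """Simulated electrode with a known receptive field."""

    electrode_id: str
    hemisphere: str
    region: str
    splitter_group: int
    archetype: str
    true_weights: np.ndarray
    noise_sd: float = 1.0
    duplicate_of: str | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if self.archetype == "none" and np.any(self.true_weights != 0):
            raise ValueError("archetype 'none' implies all-zero weights")


def _gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def archetype_weights(
    archetype: str,
    n_bins: int = N_BINS,
    n_lags: int = N_LAGS,
    lag_step_ms: float = LAG_STEP_MS,
) -> np.ndarray:
    """Parametric (bins x lags) receptive-field map for one archetype.

    Lags index time-before-response: column ``l`` is ``l * lag_step_ms`` ms
    before the observed activity.  Onset peaks at ~90 ms, late onset at
    ~210 ms, sustained spans the whole window in the top bins, rhythmic is
    a lag comb with 150 ms spacing.  Maps are scaled to unit peak.
    """
    bins = np.arange(n_bins)
    lags_ms = np.arange(n_lags) * lag_step_ms
    w = np.zeros((n_bins, n_lags))
    if archetype == "none":
        return w
    if archetype == "onset":
        w = np.outer(_gaussian(bins, 0.56 * n_bins, 0.25 * n_bins), _gaussian(lags_ms, 90.0, 20.0))
    elif archetype == "late_onset":
        w = np.outer(_gaussian(bins, 0.56 * n_bins, 0.25 * n_bins), _gaussian(lags_ms, 210.0, 20.0))
    elif archetype == "sustained":
        w = np.outer(_gaussian(bins, n_bins - 1.5, 0.05 * n_bins), np.ones(n_lags))
    elif archetype == "rhythmic":
        period_ms = 1000.0 / sixteenth_note_rate(100.0)  # 150 ms
        comb = np.zeros(n_lags)
        center = 90.0
        while center < lags_ms[-1] + lag_step_ms:
            comb += _gaussian(lags_ms, center, 16.0)
            center += period_ms
        w = np.outer(_gaussian(bins, 0.5 * n_bins, 0.1 * n_bins), comb)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return w / np.abs(w).max()


def generate_stimulus(
    duration_s: float = 190.72,
    tempo_bpm: float = 100.0,
    vocal_interval: tuple[float, float] = (13.0, 80.0),
    seed: int = 0,
    n_bins: int = N_BINS,
    frame_rate: float = 100.0,
    f_min: float = 188.0,
    f_max: float = 6745.0,
) -> SyntheticStimulus:
    """Generate a song-like nonnegative auditory spectrogram.

    Contains (i) a mid-bin background amplitude-modulated at the 16th-note
    rate 4*tempo/60 Hz, (ii) harmonic-stack note events with onsets every
    2 bars, (iii) sustained top-bin energy during the vocal interval, and
    (iv) an additive nonnegative noise floor.  Reproducible given ``seed``.
    """
    if duration_s <= 10:
        raise ValueError("duration_s must exceed 10 s")
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    start_s, end_s = vocal_interval
    if not 0 <= start_s < end_s <= duration_s:
        raise ValueError("vocal_interval must satisfy 0 <= start < end <= duration")

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    cf = geometric_center_frequencies(f_min, f_max, n_bins)
    values = np.zeros((n_frames, n_bins))

    # (i) rhythmic background in mid bins
    rate_hz = sixteenth_note_rate(tempo_bpm)
    modulation = 0.5 * (1.0 + np.sin(2.0 * np.pi * rate_hz * t))
    mid_profile = _gaussian(np.arange(n_bins), 0.5 * n_bins, 0.12 * n_bins)
    values += 0.8 * np.outer(modulation, mid_profile)

    # (ii) harmonic-stack note events every 2 bars
    bar_s = 4.0 * 60.0 / tempo_bpm
    onsets = np.arange(1.0, duration_s - 1.0, 2.0 * bar_s)
    bins_idx = np.arange(n_bins)
    f0 = 220.0
    harmonic_profile = np.zeros(n_bins)
    for h in range(1, 9):
        fh = f0 * h
        if cf[0] <= fh <= cf[-1]:
            bin_pos = np.interp(fh, cf, bins_idx)
            harmonic_profile += _gaussian(bins_idx, bin_pos, 0.7)
    decay_s = 0.25
    for onset in onsets:
        rel = t - onset
        env = np.exp(-np.clip(rel, 0.0, None) / decay_s) * (rel >= 0)
        values += 1.5 * np.outer(env, harmonic_profile)

    # (iii) sustained vocal energy in the top ~4 bins
    vocal_mask = (t >= start_s) & (t < end_s)
    vocal_profile = np.zeros(n_bins)
    vocal_profile[-4:] = 1.0
    vib = 0.85 + 0.15 * np.sin(2.0 * np.pi * 3.0 * t)  # slow vibrato-like fluctuation
    values += 1.2 * np.outer(vocal_mask * vib, vocal_profile)

    # (iv) nonnegative broadband noise floor (percussive/strumming texture);
    # keeps every band informative so receptive fields are identifiable
    values += rng.uniform(0.02, 0.8, size=values.shape)

    spec = Spectrogram(values=values, frame_rate=frame_rate, center_frequencies=cf, scale="magnitude")
    return SyntheticStimulus(
        spectrogram=spec,
        vocal_mask=vocal_mask,
        event_onsets_s=onsets,
        tempo_bpm=tempo_bpm,
        seed=seed,
    )


_DEFAULT_REGION = {
    "onset": ("STG", "posterior"),
    "late_onset": ("STG", "anterior"),
    "sustained": ("STG", "mid"),  # also SMC, alternated below
    "rhythmic": ("STG", "mid"),
    "none": ("other", ""),
}


def generate_electrodes(
    n_per_archetype: dict[str, int] | None = None,
    n_noise: int = 40,
    seed: int = 0,
    noise_sd: float = 1.0,
    n_duplicates: int = 0,
    n_bins: int = N_BINS,
    n_lags: int = N_LAGS,
) -> list[GroundTruthElectrode]:
    """Build a ground-truth electrode cohort.

    Default cohort is 60 responsive electrodes (15 per archetype) plus
    ``n_noise`` zero-weight electrodes.  Hemispheres alternate L/R; the
    default region policy places onset archetypes in (posterior) STG,
    sustained in STG and SMC, rhythmic in (mid) STG, late onset in STG, and
    noise electrodes in 'other'/IFG labels.  ``n_duplicates`` appends exact
    copies of the first responsive electrodes (same weights, independent
    noise) for redundancy tests, linked via ``duplicate_of``.
    """
    if n_per_archetype is None:
        n_per_archetype = {"onset": 15, "sustained": 15, "late_onset": 15, "rhythmic": 15}
    if any(v < 0 for v in n_per_archetype.values()) or n_noise < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    electrodes: list[GroundTruthElectrode] = []
    idx = 0
    for archetype, count in n_per_archetype.items():
        base = archetype_weights(archetype, n_bins=n_bins, n_lags=n_lags)
        for j in range(count):
            hemi = "L" if idx % 2 else "R"
            region = _DEFAULT_REGION[archetype][0]
            if archetype == "sustained" and j % 3 == 2:
                region = "SMC"
            gain = rng.uniform(0.8, 1.2)
            electrodes.append(
                GroundTruthElectrode(
                    electrode_id=f"e{idx:03d}",
                    hemisphere=hemi,
                    region=region,
                    splitter_group=idx % 2,
                    archetype=archetype,
                    true_weights=gain * base,
                    noise_sd=noise_sd,
                )
            )
            idx += 1
    for j in range(n_noise):
        hemi = "L" if idx % 2 else "R"
        region = "IFG" if j % 4 == 0 else "other"
        electrodes.append(
            GroundTruthElectrode(
                electrode_id=f"e{idx:03d}",
                hemisphere=hemi,
                region=region,
                splitter_group=idx % 2,
                archetype="none",
                true_weights=np.zeros((n_bins, n_lags)),
                noise_sd=noise_sd,
            )
        )
        idx += 1
    responsive = [e for e in electrodes if e.archetype != "none"]
    for j in range(min(n_duplicates, len(responsive))):
        src = responsive[j]
        electrodes.append(
            GroundTruthElectrode(
                electrode_id=f"e{idx:03d}",
                hemisphere=src.hemisphere,
                region=src.region,
                splitter_group=idx % 2,
                archetype=src.archetype,
                true_weights=src.true_weights.copy(),
                noise_sd=src.noise_sd,
                duplicate_of=src.electrode_id,
            )
        )
        idx += 1
    return electrodes


def _lagged_response(spec_log: np.ndarray, w: np.ndarray) -> np.ndarray:
    """y(t) = sum_{b,l} w[b,l] * S[t-l, b]; first n_lags-1 frames use zero history."""
    n_frames, n_bins = spec_log.shape
    n_lags = w.shape[1]
    y = np.zeros(n_frames)
    for l in range(n_lags):
        contrib = spec_log @ w[:, l]
        y[l:] += contrib[: n_frames - l] if l else contrib
    return y


def simulate_hfa(
    stimulus: SyntheticStimulus,
    electrodes: list[GroundTruthElectrode],
    nonlinearity: str = "none",
    seed: int = 0,
    signal_scale: float = 1.0,
) -> HfaMatrix:
    """Simulate per-electrode HFA as a lagged-linear response plus noise.

    y_e(t) = a_e + sum_{b,l} w_e[b,l] * S_log[b, t-l] + eps,
    eps ~ Normal(0, noise_sd).  The linear drive is standardized to zero
    mean and ``signal_scale`` standard deviation per electrode so noise_sd
    is an SNR dial in z-like units.  With ``nonlinearity='compressive'`` a
    tanh with unit slope at 0 is applied to the drive before noise.  The
    first n_lags-1 frames (incomplete lag context) are tagged in the
    outlier mask.
    """
    if not electrodes:
        raise ValueError("electrode list must not be empty")
    n_lags = electrodes[0].true_weights.shape[1]
    if stimulus.spectrogram.n_frames < n_lags:
        raise ValueError("stimulus must have at least n_lags frames")
    if nonlinearity not in ("none", "compressive"):
        raise ValueError("nonlinearity must be 'none' or 'compressive'")

    from .audio import log_compress  # local import to avoid cycle at module load

    spec_log = log_compress(stimulus.spectrogram).values
    rng = np.random.default_rng(seed)
    n_frames = stimulus.spectrogram.n_frames
    values = np.empty((n_frames, len(electrodes)))
    for j, e in enumerate(electrodes):
        if np.any(e.true_weights != 0):
            drive = _lagged_response(spec_log, e.true_weights)
            sd = drive[n_lags - 1 :].std()
            drive = (drive - drive[n_lags - 1 :].mean()) / (sd if sd > 0 else 1.0)
            drive *= signal_scale
        else:
            drive = np.zeros(n_frames)
        if nonlinearity == "compressive":
            drive = 1.5 * np.tanh(drive / 1.5)  # unit slope at 0, saturates at +/-1.5
        noise = rng.normal(0.0, e.noise_sd, size=n_frames) if e.noise_sd > 0 else 0.0
        values[:, j] = e.intercept + drive + noise
    mask = np.zeros(values.shape, dtype=bool)
    mask[: n_lags - 1, :] = True
    return HfaMatrix(
        values=values,
        frame_rate=stimulus.spectrogram.frame_rate,
        electrode_ids=[e.electrode_id for e in electrodes],
        outlier_mask=mask,
    )


def simulate_raw_ecog(
    hfa: HfaMatrix,
    fs_out: float = 1200.0,
    line_noise_amp: float = 0.5,
    background_amp: float = 0.15,
    pad_s: float = 10.0,
    seed: int = 0,
    env_gain: float = 0.6,
    carrier: str = "noise",
):
    """Render HFA targets as a raw multichannel recording.

    Each channel is a broadband 70-150 Hz carrier whose amplitude envelope
    follows the (upsampled) target HFA mapped through
    ``max(1 + env_gain * z, 0.05)``, plus a 60 Hz line component with
    harmonics, plus 1/f-like background.  ``carrier='noise'`` (default)
    uses bandpassed white noise — realistic, with intrinsic envelope
    fluctuation; ``carrier='sine'`` uses a deterministic 110 Hz tone whose
    envelope is exact, useful for degenerate checks.  Symmetric padding of
    ``pad_s`` seconds is prepended/appended so filter edge artifacts in
    preprocessing fall outside the stimulus window.  Faithful envelope
    recovery by the bandpass-Hilbert chain additionally needs several
    electrodes per splitter group (the median reference distorts tiny
    groups).
    """
    from .containers import EcogRecording
    from scipy import signal as sig

    if fs_out < 2 * 150.0:
        raise ValueError("fs_out must be at least 300 Hz to represent the 70-150 Hz carrier")
    if carrier not in ("noise", "sine"):
        raise ValueError("carrier must be 'noise' or 'sine'")
    rng = np.random.default_rng(seed)
    n_frames, n_elec = hfa.values.shape
    duration_s = n_frames / hfa.frame_rate
    n_pad = int(round(pad_s * fs_out))
    n_samples = int(round(duration_s * fs_out)) + 2 * n_pad
    t = np.arange(n_samples) / fs_out

    carrier_sos = sig.butter(4, [70.0, 150.0], btype="band", fs=fs_out, output="sos")
    pink_b, pink_a = sig.butter(1, 5.0, btype="low", fs=fs_out)

    # upsample each envelope to fs_out, with edge-held padding
    frame_t = np.arange(n_frames) / hfa.frame_rate
    core_t = np.arange(int(round(duration_s * fs_out))) / fs_out
    data = np.empty((n_samples, n_elec))
    line = np.zeros(n_samples)
    for harm in (60.0, 120.0, 180.0, 240.0, 300.0):
        if harm < fs_out / 2:
            line += np.sin(2.0 * np.pi * harm * t + rng.uniform(0, 2 * np.pi))
    for j in range(n_elec):
        env_core = np.interp(core_t, frame_t, hfa.values[:, j])
        env = np.concatenate([np.full(n_pad, env_core[0]), env_core, np.full(n_pad, env_core[-1])])
        env = np.maximum(1.0 + env_gain * env, 0.05)
        if carrier == "noise":
            wave = sig.sosfilt(carrier_sos, rng.normal(size=n_samples))
            wave /= wave.std()
        else:
            wave = np.sqrt(2.0) * np.sin(2.0 * np.pi * 110.0 * t + rng.uniform(0, 2 * np.pi))
        background = sig.lfilter(pink_b, pink_a, rng.normal(size=n_samples))
        bg_sd = background.std()
        if bg_sd > 0:
            background /= bg_sd
        data[:, j] = env * wave + line_noise_amp * line + background_amp * background
    return EcogRecording(
        data=data,
        fs=fs_out,
        electrode_ids=list(hfa.electrode_ids),
        splitter_group=np.arange(n_elec) % 2,
        pad_s=pad_s,
    )


def electrode_frame(electrodes: list[GroundTruthElectrode]) -> pd.DataFrame:
    """Electrode metadata as the TSV-ready table used across the pipeline."""
    return pd.DataFrame(
        {
            "electrode_id": [e.electrode_id for e in electrodes],
            "hemisphere": [e.hemisphere for e in electrodes],
            "region": [e.region for e in electrodes],
            "splitter_group": [e.splitter_group for e in electrodes],
            "archetype": [e.archetype for e in electrodes],
            "duplicate_of": [e.duplicate_of or "" for e in electrodes],
        }
    )
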