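"""Raw intracranial recordings -> z-scaled 100 Hz high-frequency activity.

Chain: notch filters at the line frequency and harmonics (Butterworth,
fourth order, 2 Hz bandwidth), 1 Hz high-pass for slow drifts, then a
bandpass-Hilbert estimate of HFA: thirteen 20-Hz sub-bands spanning
70-150 Hz in 5 Hz steps, each bandpassed, median common-average-referenced
per splitter-box group, Hilbert-enveloped and robust-scaled before
averaging.  Pads are removed, the result is polyphase-downsampled to
100 Hz, re-expressed in robust z-units, and samples beyond |z| > 7 are
tagged as outliers.

All IIR filters are applied forward-backward (zero phase) so response
latencies survive for the lag axis of receptive-field models.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sig

from .containers import EcogRecording, HfaMatrix

__all__ = [
    "remove_line_noise",
    "highpass_drift",
    "median_car",
    "robust_scale_series",
    "subband_edges",
    "extract_hfa",
]

logger = logging.getLogger(__name__)


def remove_line_noise(
    rec: EcogRecording,
    base: float = 60.0,
    max_harmonic: float = 300.0,
    bw: float = 2.0,
    order: int = 4,
) -> EcogRecording:
    """Zero-phase band-stop at ``base`` and harmonics up to ``max_harmonic``."""
    nyq = rec.fs / 2.0
    if base >= nyq:
        raise ValueError("line-noise base frequency must be below Nyquist")
    data = rec.data
    for center in np.arange(base, max_harmonic + 0.5 * base, base):
        if center >= nyq:
            logger.warning("skipping notch at %.0f Hz (>= Nyquist)", center)
            continue
        sos = sig.butter(order, [center - bw / 2, center + bw / 2], btype="bandstop", fs=rec.fs, output="sos")
        data = sig.sosfiltfilt(sos, data, axis=0)
    return EcogRecording(data=data, fs=rec.fs, electrode_ids=list(rec.electrode_ids),
                         splitter_group=rec.splitter_group, pad_s=rec.pad_s)


def highpass_drift(rec: EcogRecording, cutoff: float = 1.0, order: int = 4) -> EcogRecording:
    """Zero-phase high-pass removing DC and sub-``cutoff`` drifts."""
    if cutoff >= rec.fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = sig.butter(order, cutoff, btype="high", fs=rec.fs, output="sos")
    data = sig.sosfiltfilt(sos, rec.data, axis=0)
    return EcogRecording(data=data, fs=rec.fs, electrode_ids=list(rec.electrode_ids),
                         splitter_group=rec.splitter_group, pad_s=rec.pad_s)


def median_car(rec: EcogRecording) -> EcogRecording:
    """Median common average reference, separately per splitter group.

    Per time sample, the cross-electrode median within each group is
    subtracted.  Single-electrode groups are left unreferenced with a
    warning (no meaningful median).
    """
    data = rec.data.copy()
    for group in np.unique(rec.splitter_group):
        cols = np.flatnonzero(rec.splitter_group == group)
        if cols.size < 2:
            logger.warning("splitter group %s has a single electrode; left unreferenced", group)
            continue
        data[:, cols] -= np.median(data[:, cols], axis=1, keepdims=True)
    return EcogRecording(data=data, fs=rec.fs, electrode_ids=list(rec.electrode_ids),
                         splitter_group=rec.splitter_group, pad_s=rec.pad_s)


def robust_scale_series(x: np.ndarray, lo_pct: float = 10.0, hi_pct: float = 90.0) -> np.ndarray:
    """(x - median) / (P_hi - P_lo), percentiles by linear interpolation.

    A zero interpercentile range divides by 1 with a warning.  Operates
    along axis 0 for 2-D input.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples to scale robustly")
    med = np.median(x, axis=0)
    lo, hi = np.percentile(x, [lo_pct, hi_pct], axis=0)
    rng = hi - lo
    if np.any(rng == 0):
        logger.warning("zero interpercentile range; dividing by 1")
        rng = np.where(rng == 0, 1.0, rng)
    return (x - med) / rng


def subband_edges(band_lo: float = 70.0, band_hi: float = 150.0,
                  sub_bw: float = 20.0, step: float = 5.0) -> list[tuple[float, float]]:
    """Sub-band (lo, hi) pairs: 70-90, 75-95, ... 130-150 for the defaults."""
    edges = []
    lo = band_lo
    while lo + sub_bw <= band_hi + 1e-9:
        edges.append((lo, lo + sub_bw))
        lo += step
    return edges


def extract_hfa(
    rec: EcogRecording,
    band_lo: float = 70.0,
    band_hi: float = 150.0,
    sub_bw: float = 20.0,
    step: float = 5.0,
    frame_rate: float = 100.0,
    outlier_z: float = 7.0,
    filter_order: int = 4,
) -> HfaMatrix:
    """Bandpass-Hilbert HFA estimate at ``frame_rate`` with outlier tags.

    Per sub-band: zero-phase Butterworth bandpass -> median CAR per
    splitter group -> Hilbert envelope -> robust scaling; the scaled
    envelopes are averaged, pads removed, polyphase-downsampled, and the
    averaged series re-expressed in robust z-units so the outlier threshold
    has a defined scale.  The 20 Hz default sub-band width admits envelope
    modulations up to 10 Hz.
    """
    if band_hi >= rec.fs / 2:
        raise ValueError("band_hi must be below Nyquist")
    n_samples, n_elec = rec.data.shape
    acc = np.zeros((n_samples, n_elec))
    bands = subband_edges(band_lo, band_hi, sub_bw, step)
    for lo, hi in bands:
        sos = sig.butter(filter_order, [lo, hi], btype="band", fs=rec.fs, output="sos")
        sub = sig.sosfiltfilt(sos, rec.data, axis=0)
        sub = median_car(EcogRecording(data=sub, fs=rec.fs, electrode_ids=list(rec.electrode_ids),
                                       splitter_group=rec.splitter_group, pad_s=rec.pad_s)).data
        env = np.abs(sig.hilbert(sub, axis=0))
        acc += robust_scale_series(env)
    hfa_full = acc / len(bands)

    n_pad = int(round(rec.pad_s * rec.fs))
    core = hfa_full[n_pad : n_samples - n_pad if n_pad else n_samples]
    duration_s = core.shape[0] / rec.fs
    n_frames = int(round(duration_s * frame_rate))
    from .audio import _resample_to_rate

    values = _resample_to_rate(core, rec.fs, frame_rate, n_frames)
    values = robust_scale_series(values)
    mask = np.abs(values) > outlier_z
    return HfaMatrix(values=values, frame_rate=frame_rate,
                     electrode_ids=list(rec.electrode_ids), outlier_mask=mask)
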