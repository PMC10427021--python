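"""Decomposition of receptive fields into shared components.

Significant STRFs (electrodes x coefficients) are decomposed with ICA:
a probe run with 10 sources, retention of the components whose
back-projection accounts for more than 5% of variance (pvaf), and a final
run asking for exactly that many sources.  Component signs are fixed so
the most salient map coefficient is positive, and an electrode is said to
carry a component when its mixing coefficient is positive.

Rhythmic tuning is detected separately: the temporal modulation spectrum
of each STRF (lag-axis Fourier magnitude per spectral bin, 1-16 Hz) is
summarized by its maximum in the 6-7 Hz window, the 16th-note rate of the
song, and thresholded (default 0.3).  Spectra are computed on maps
normalized to unit peak magnitude so the threshold has a scale-free
meaning (modulation amplitude relative to the map's peak).

A sliding-window correlation between a component map and the log
spectrogram localizes the musical elements driving that component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .features import build_lag_matrix

__all__ = [
    "IcaDecomposition",
    "pvaf",
    "fix_sign",
    "ica_components",
    "temporal_modulation_spectrum",
    "max_modulation_6to7",
    "rhythmic_assignment",
    "component_flags",
    "match_components",
    "sliding_component_correlation",
]

logger = logging.getLogger(__name__)


def pvaf(strfs: np.ndarray, backprojection: np.ndarray) -> float:
    """Percent variance accounted for by one component's back-projection.

    pvaf = 100 - 100 * mean(var(STRF - backproj)) / mean(var(STRF)),
    variance taken across coefficients per electrode, mean across
    electrodes.  100 for an exact reconstruction, 0 for a zero
    back-projection of centered data.
    """
    strfs = np.asarray(strfs, dtype=float)
    backprojection = np.asarray(backprojection, dtype=float)
    if strfs.shape != backprojection.shape:
        raise ValueError("shapes must match")
    total = np.var(strfs, axis=1).mean()
    if total == 0:
        raise ValueError("zero total variance")
    resid = np.var(strfs - backprojection, axis=1).mean()
    return float(100.0 - 100.0 * resid / total)


def fix_sign(component: np.ndarray, mixing_column: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (component, mixing) jointly so the max-|value| map coefficient is positive.

    The back-projection (outer product) is invariant under the flip.
    """
    component = np.asarray(component, dtype=float)
    mixing_column = np.asarray(mixing_column, dtype=float)
    peak = component[np.argmax(np.abs(component))]
    if peak < 0:
        return -component, -mixing_column
    return component.copy(), mixing_column.copy()


@dataclass
class IcaDecomposition:
    """Retained ICA components of a set of STRF maps.

    components: (k, n_features) maps in coefficient space; mixing:
    (n_electrodes, k) per-electrode coefficients; centered data is
    approximated by mixing @ components.
    """

    components: np.ndarray
    mixing: np.ndarray
    pvaf: np.ndarray
    k: int
    seed: int
    probe_pvaf: np.ndarray  # pvaf of the k_probe probe components
    feature_mean: np.ndarray

    def backprojection(self, i: int) -> np.ndarray:
        return np.outer(self.mixing[:, i], self.components[i])


def _run_fastica(data: np.ndarray, k: int, seed: int, max_tries: int = 3,
                 require_convergence: bool = True):
    """FastICA with features as samples; retries on non-convergence.

    With ``require_convergence`` False the last attempt is returned even if
    the unmixing iteration hit its limit — appropriate for the probe run,
    where surplus noise sources rarely settle but the strong components do.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    sources = mixing = None
    for attempt in range(max_tries):
        ica = FastICA(n_components=k, random_state=seed + attempt, max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(data)
        mixing = ica.mixing_
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return sources, mixing
        logger.warning("FastICA attempt %d did not converge; retrying with a new seed", attempt + 1)
    if require_convergence:
        raise RuntimeError("FastICA did not converge")
    logger.warning("using non-converged FastICA solution with %d sources", k)
    return sources, mixing


def ica_components(
    strf_maps: np.ndarray,
    k_probe: int = 10,
    pvaf_min: float = 5.0,
    seed: int = 0,
) -> IcaDecomposition:
    """Two-stage ICA of STRF maps with pvaf-based component selection.

    ``strf_maps`` is (electrodes, features).  Data is centered per
    feature; a probe ICA with ``k_probe`` sources is run, the components
    with pvaf > ``pvaf_min`` are counted (k*), and a final ICA with k*
    sources is fitted.  Signs are fixed per component.
    """
    strf_maps = np.asarray(strf_maps, dtype=float)
    n_elec, n_feat = strf_maps.shape
    if n_elec < k_probe:
        raise ValueError("need at least k_probe electrodes")
    mean = strf_maps.mean(axis=0)
    centered = strf_maps - mean

    # features as samples, electrodes as variables: sources are component maps
    sources, mixing = _run_fastica(centered.T, k_probe, seed, require_convergence=False)
    probe_pvaf = np.array([
        pvaf(centered, np.outer(mixing[:, i], sources[:, i])) for i in range(k_probe)
    ])
    k_star = int(np.sum(probe_pvaf > pvaf_min))
    if k_star == 0:
        logger.warning("no probe component exceeded pvaf %.1f; keeping the best one", pvaf_min)
        k_star = 1

    sources, mixing = _run_fastica(centered.T, k_star, seed + 101)
    comps = np.empty((k_star, n_feat))
    mix = np.empty((n_elec, k_star))
    pvafs = np.empty(k_star)
    for i in range(k_star):
        comps[i], mix[:, i] = fix_sign(sources[:, i], mixing[:, i])
        pvafs[i] = pvaf(centered, np.outer(mix[:, i], comps[i]))
    order = np.argsort(pvafs)[::-1]
    return IcaDecomposition(
        components=comps[order],
        mixing=mix[:, order],
        pvaf=pvafs[order],
        k=k_star,
        seed=seed,
        probe_pvaf=probe_pvaf,
        feature_mean=mean,
    )


def temporal_modulation_spectrum(
    strf: np.ndarray,
    rates_hz: np.ndarray | None = None,
    lag_rate_hz: float = 100.0,
    rate_resolution_hz: float = 0.25,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Lag-axis Fourier magnitude of a (bins x lags) map at 1-16 Hz.

    With ``normalize`` (default) the map is scaled to unit peak |value| so
    the 0.3 rhythm threshold is scale-free (modulation amplitude relative
    to the map's peak); without it the spectrum is linear in the map.
    Each bin's lag series is zero-padded to ``rate_resolution_hz``
    resolution; magnitudes are scaled as sinusoid amplitudes
    (2|FFT|/n_lags).  Returns (rates, spectrum) with spectrum shaped
    (bins, rates).
    """
    strf = np.asarray(strf, dtype=float)
    n_bins, n_lags = strf.shape
    peak = np.abs(strf).max()
    w = strf / peak if (normalize and peak > 0) else strf
    if rates_hz is None:
        rates_hz = np.arange(1.0, 16.0 + rate_resolution_hz / 2, rate_resolution_hz)
    n_fft = max(int(round(lag_rate_hz / rate_resolution_hz)), n_lags)
    spectrum_full = np.abs(np.fft.rfft(w, n=n_fft, axis=1)) * 2.0 / n_lags
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / lag_rate_hz)
    idx = np.array([int(np.argmin(np.abs(freqs - r))) for r in rates_hz])
    return np.asarray(rates_hz), spectrum_full[:, idx]


def max_modulation_6to7(strf: np.ndarray, lag_rate_hz: float = 100.0) -> float:
    """Maximum modulation value across all bins within the 6-7 Hz window."""
    rates, spec = temporal_modulation_spectrum(strf, lag_rate_hz=lag_rate_hz)
    window = (rates >= 6.0) & (rates <= 7.0)
    return float(spec[:, window].max())


def rhythmic_assignment(max_values: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Flag electrodes whose 6-7 Hz modulation maximum exceeds the threshold."""
    return np.asarray(max_values, dtype=float) > threshold


def component_flags(decomposition: IcaDecomposition) -> np.ndarray:
    """(n_electrodes, k) booleans: electrode carries component iff mixing > 0."""
    return decomposition.mixing > 0


def match_components(
    components: np.ndarray,
    references: dict[str, np.ndarray],
) -> dict[str, tuple[int, float]]:
    """Greedy 1-1 match of components to reference maps by |correlation|.

    Returns {name: (component index, |r|)}; used to label recovered
    components against planted archetypes on synthetic cohorts.
    """
    comps = np.asarray(components, dtype=float)
    remaining = list(range(comps.shape[0]))
    out: dict[str, tuple[int, float]] = {}
    pairs = []
    for name, ref in references.items():
        refv = np.asarray(ref, dtype=float).ravel()
        for i in range(comps.shape[0]):
            c = comps[i]
            if c.std() == 0 or refv.std() == 0:
                r = 0.0
            else:
                r = abs(float(np.corrcoef(c, refv)[0, 1]))
            pairs.append((r, name, i))
    pairs.sort(reverse=True)
    used_names: set[str] = set()
    for r, name, i in pairs:
        if name in used_names or i not in remaining:
            continue
        out[name] = (i, r)
        used_names.add(name)
        remaining.remove(i)
    return out


def sliding_component_correlation(
    component_map: np.ndarray,
    spec_log_values: np.ndarray,
) -> np.ndarray:
    """Pearson r between a (bins x lags) map and each spectrogram window.

    At frame t the map is correlated with the preceding window
    spec[t-(n_lags-1) .. t] (lag l against frame t-l).  Frames without a
    full window, or zero-variance windows, yield 0.
    """
    component_map = np.asarray(component_map, dtype=float)
    n_bins, n_lags = component_map.shape
    spec_log_values = np.asarray(spec_log_values, dtype=float)
    if spec_log_values.shape[0] < n_lags:
        raise ValueError("spectrogram needs at least n_lags frames")
    if spec_log_values.shape[1] != n_bins:
        raise ValueError("bin count mismatch")
    lm = build_lag_matrix(spec_log_values, np.zeros(spec_log_values.shape[0]), n_lags=n_lags)
    X = lm.X  # rows t, columns (bin, lag) matching component_map.ravel()
    c = component_map.ravel()
    c = c - c.mean()
    c_norm = np.linalg.norm(c)
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc, axis=1) * c_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc @ c) / denom, 0.0)
    out = np.zeros(spec_log_values.shape[0])
    out[lm.frame_index] = r
    return out
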