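"""Song-excerpt identification from decoded spectrograms.

The song is tiled into non-overlapping test segments (twelve 15 s segments
for a 190.72 s song); each segment is decoded by models trained with that
segment held out, and the concatenated decode is compared with the
original: both are cut into 5 s excerpts, a Pearson correlation is
computed for every decoded-original excerpt pair, and each decoded
excerpt's rank of its true counterpart among all originals measures
identifiability (38/38 = the true excerpt is the best match).  A
permutation null relabels the original excerpts 1,000 times to calibrate
the mean normalized rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import HfaMatrix, Spectrogram
from .decoding import DecoderConfig, decode_spectrogram
from .encoding import pearson_r

__all__ = [
    "segment_bounds",
    "decode_all_segments",
    "ExcerptCorrelation",
    "excerpt_correlation_matrix",
    "RankResult",
    "identification_ranks",
    "permutation_null",
]

logger = logging.getLogger(__name__)


def segment_bounds(n_frames: int, segment_len_s: float = 15.0, n_segments: int = 12,
                   frame_rate: float = 100.0) -> list[tuple[int, int]]:
    """Non-overlapping test segments tiling the song from t=0.

    The default twelve 15 s segments cover the first 180 s; any remaining
    tail is appended to the final segment so the whole song is decoded
    (the tail is held out together with the last segment).
    """
    seg_len = int(round(segment_len_s * frame_rate))
    bounds = [(i * seg_len, (i + 1) * seg_len) for i in range(n_segments)]
    if bounds[-1][1] > n_frames:
        raise ValueError("segments exceed the available frames")
    if bounds[-1][1] < n_frames:
        bounds[-1] = (bounds[-1][0], n_frames)
    return bounds


def decode_all_segments(
    hfa: HfaMatrix,
    target: Spectrogram,
    cfg: DecoderConfig,
    vocal_mask: np.ndarray | None = None,
    segment_len_s: float = 15.0,
    n_segments: int = 12,
    seed: int = 0,
) -> Spectrogram:
    """Decode the whole song through tiled held-out test segments.

    Each segment is decoded by an ensemble trained with that segment held
    out; predictions are concatenated in stimulus order.  Frames with no
    decoded value (the final lag window tail of the last segment) repeat
    the last prediction so the output aligns frame-exactly with the
    original.
    """
    bounds = segment_bounds(hfa.n_frames, segment_len_s, n_segments, hfa.frame_rate)
    for (a0, a1), (b0, b1) in zip(bounds[:-1], bounds[1:]):
        if a1 > b0:
            raise ValueError("segments overlap")
    seeds = np.random.SeedSequence((seed, 3)).generate_state(len(bounds)) % (2**31)
    predicted = np.zeros((hfa.n_frames, target.n_bins))
    covered = np.zeros(hfa.n_frames, dtype=bool)
    for i, (start, stop) in enumerate(bounds):
        dec = decode_spectrogram(
            hfa, target, cfg, (start, stop), vocal_mask=vocal_mask, seed=int(seeds[i])
        )
        predicted[dec.test_frames] = dec.predicted
        covered[dec.test_frames] = True
    if not covered.all():
        last = int(np.flatnonzero(covered).max())
        predicted[~covered] = predicted[last]
    return Spectrogram(
        values=np.clip(predicted, 0.0, None),
        frame_rate=target.frame_rate,
        center_frequencies=target.center_frequencies,
        scale="magnitude",
    )


@dataclass
class ExcerptCorrelation:
    """Square matrix of decoded-row x original-column excerpt correlations."""

    matrix: np.ndarray
    excerpt_len_s: float
    segment_len_s: float = 15.0

    @property
    def n_excerpts(self) -> int:
        return self.matrix.shape[0]


def excerpt_correlation_matrix(
    decoded: Spectrogram,
    original: Spectrogram,
    excerpt_len_s: float = 5.0,
    segment_len_s: float = 15.0,
) -> ExcerptCorrelation:
    """2-D Pearson correlations between all decoded/original excerpt pairs.

    Excerpts are consecutive ``excerpt_len_s`` windows from t=0; each cell
    correlates the flattened (frames x bins) arrays.  A trailing partial
    excerpt is dropped with a warning.  190.72 s at 5 s gives 38 excerpts.
    """
    if decoded.n_bins != original.n_bins:
        raise ValueError("decoded and original must share the bin axis")
    n_frames = min(decoded.n_frames, original.n_frames)
    exc_len = int(round(excerpt_len_s * decoded.frame_rate))
    n_exc = n_frames // exc_len
    if n_frames % exc_len:
        logger.warning("dropping trailing partial excerpt (%d frames)", n_frames % exc_len)
    m = np.empty((n_exc, n_exc))
    dec_flat = [decoded.values[i * exc_len : (i + 1) * exc_len].ravel() for i in range(n_exc)]
    orig_flat = [original.values[j * exc_len : (j + 1) * exc_len].ravel() for j in range(n_exc)]
    for i in range(n_exc):
        for j in range(n_exc):
            m[i, j] = pearson_r(dec_flat[i], orig_flat[j])
    return ExcerptCorrelation(matrix=m, excerpt_len_s=excerpt_len_s, segment_len_s=segment_len_s)


@dataclass
class RankResult:
    ranks: np.ndarray  # 1..n per excerpt (fractional on ties)
    mean_normalized_rank: float
    n_top1: int
    n_excerpts: int


def identification_ranks(corr: ExcerptCorrelation) -> RankResult:
    """Rank of the true excerpt's correlation within each decoded row.

    rank_i = 1 + #{j != i : m[i,j] < m[i,i]} with exact ties counted as
    half (fractional/average rank).  A rank of n means the diagonal entry
    is the row maximum; mean_normalized_rank = mean(rank_i / n).
    """
    m = corr.matrix
    if m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    n = m.shape[0]
    ranks = np.empty(n)
    for i in range(n):
        others = np.delete(m[i], i)
        ranks[i] = 1.0 + np.sum(others < m[i, i]) + 0.5 * np.sum(others == m[i, i])
    n_top1 = int(np.sum(ranks == n))
    return RankResult(
        ranks=ranks,
        mean_normalized_rank=float(ranks.mean() / n),
        n_top1=n_top1,
        n_excerpts=n,
    )


def permutation_null(
    corr: ExcerptCorrelation,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation null of the mean normalized rank.

    Per iteration the original-excerpt columns are relabeled by a uniform
    random permutation and the mean normalized rank recomputed.  The
    observed value is deemed significant when it exceeds the empirical
    97.5 percentile of the null.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    m = corr.matrix
    n = m.shape[0]
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        permuted = ExcerptCorrelation(matrix=m[:, perm], excerpt_len_s=corr.excerpt_len_s)
        null[p] = identification_ranks(permuted).mean_normalized_rank
    observed = identification_ranks(corr).mean_normalized_rank
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {
        "observed_mean_normalized_rank": observed,
        "null_mean": float(null.mean()),
        "null_ci95": (float(lo), float(hi)),
        "null_samples": null,
        "significant": bool(observed > hi),
    }
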