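"""Lagged feature matrices and leakage-safe grouped splits.

Encoding models predict neural activity at frame t from the preceding
750 ms of the log spectrogram (causal lags); decoding models predict a
spectrogram bin at frame t from the following 500 ms of multichannel HFA
(anticausal lags).  Both directions share one lag-matrix builder.

Splits allocate indivisible blocks of consecutive frames (2 s for
encoding, 5 s for decoding) to train/validation/test sets at a 60-20-20
ratio, stratified by the vocal/instrumental labeling of each block, with a
fresh shuffle per seed (shuffle-split, akin to bootstrapping across
iterations).  Feature scaling is a robust scaler (median, 2-98 percentile
range) fitted on training rows only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import RobustScaler

__all__ = [
    "LagMatrix",
    "SplitSpec",
    "build_lag_matrix",
    "drop_outlier_rows",
    "group_stratified_shuffle_split",
    "fit_feature_scaler",
    "apply_scaler",
]


@dataclass
class LagMatrix:
    """Observations x (channels * lags) design matrix with aligned target.

    ``column_map`` lists (channel, lag_ms) per column, lag-major within
    channel: column c*n_lags + l holds channel c at lag l*lag_step_ms.
    ``frame_index`` gives the stimulus frame of each row's target.
    """

    X: np.ndarray
    y: np.ndarray
    frame_index: np.ndarray
    column_map: list[tuple[int, float]]
    n_channels: int
    n_lags: int
    direction: str = "causal"

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.frame_index.shape[0]:
            raise ValueError("X, y and frame_index must have equal row counts")
        if self.X.shape[1] != self.n_channels * self.n_lags:
            raise ValueError("feature count must equal n_channels * n_lags")
        if len(self.column_map) != self.X.shape[1]:
            raise ValueError("column_map must cover every column")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows_for_frames(self, frames: np.ndarray) -> np.ndarray:
        """Boolean row mask selecting rows whose target frame is in ``frames``."""
        lookup = np.zeros(int(self.frame_index.max()) + 1, dtype=bool)
        frames = np.asarray(frames, dtype=int)
        frames = frames[frames <= self.frame_index.max()]
        lookup[frames] = True
        return lookup[self.frame_index]


def build_lag_matrix(
    features: np.ndarray,
    y_series: np.ndarray,
    n_lags: int = 75,
    lag_step_ms: float = 10.0,
    direction: str = "causal",
) -> LagMatrix:
    """Build the lagged design matrix pairing each target frame with a window.

    ``features`` is (frames, channels) — spectrogram bins for encoding, HFA
    electrodes for decoding.  Causal: row for frame t holds features[t-l]
    for l = 0..n_lags-1, so the first n_lags-1 frames have no observation.
    Anticausal: row for frame t holds features[t+l], dropping the last
    n_lags-1 frames.  32 bins at 75 lags gives 2,400 features.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if features.ndim != 2:
        raise ValueError("features must be 2-D (frames x channels)")
    y_series = np.asarray(y_series, dtype=float).ravel()
    n_frames, n_channels = features.shape
    if y_series.size != n_frames:
        raise ValueError("y_series length must equal frame count")
    if n_frames < n_lags:
        raise ValueError("need at least n_lags frames")
    if direction not in ("causal", "anticausal"):
        raise ValueError("direction must be 'causal' or 'anticausal'")

    # windows[i] = features[i : i+n_lags]; shape (rows, n_lags, channels)
    windows = np.lib.stride_tricks.sliding_window_view(features, n_lags, axis=0)
    # sliding_window_view yields (rows, channels, n_lags) with window index last
    if direction == "causal":
        # row t = n_lags-1+i: lag l is features[t-l] = window[..., n_lags-1-l]
        X = windows[..., ::-1].reshape(windows.shape[0], -1)
        frame_index = np.arange(n_lags - 1, n_frames)
    else:
        # row t = i: lag l is features[t+l] = window[..., l]
        X = windows.reshape(windows.shape[0], -1)
        frame_index = np.arange(0, n_frames - n_lags + 1)
    y = y_series[frame_index]
    column_map = [(c, l * lag_step_ms) for c in range(n_channels) for l in range(n_lags)]
    return LagMatrix(
        X=np.ascontiguousarray(X),
        y=y,
        frame_index=frame_index,
        column_map=column_map,
        n_channels=n_channels,
        n_lags=n_lags,
        direction=direction,
    )


def drop_outlier_rows(lm: LagMatrix, mask: np.ndarray) -> tuple[LagMatrix, float]:
    """Remove rows whose target frame is tagged; returns (matrix, removed fraction)."""
    mask = np.asarray(mask, dtype=bool).ravel()
    keep = ~mask[lm.frame_index]
    if not np.any(keep):
        raise ValueError("outlier mask removes every observation")
    removed_fraction = 1.0 - keep.mean()
    out = LagMatrix(
        X=lm.X[keep],
        y=lm.y[keep],
        frame_index=lm.frame_index[keep],
        column_map=list(lm.column_map),
        n_channels=lm.n_channels,
        n_lags=lm.n_lags,
        direction=lm.direction,
    )
    return out, float(removed_fraction)


@dataclass
class SplitSpec:
    """Frame-index sets for train/validation/test with block bookkeeping."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    block_len_s: float
    ratios: tuple[float, float, float]
    seed: int
    block_of_frame: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def as_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "val": self.val.tolist(),
            "test": self.test.tolist(),
            "block_len_s": self.block_len_s,
            "ratios": list(self.ratios),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(
            train=np.asarray(d["train"], dtype=int),
            val=np.asarray(d["val"], dtype=int),
            test=np.asarray(d["test"], dtype=int),
            block_len_s=float(d["block_len_s"]),
            ratios=tuple(d["ratios"]),
            seed=int(d["seed"]),
        )


def _allocate(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder allocation of n blocks to three sets, each >= 1."""
    raw = [r * n for r in ratios]
    counts = [math.floor(v) for v in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    # every set needs at least one block
    for i in range(3):
        while counts[i] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1
    return tuple(counts)  # type: ignore[return-value]


def group_stratified_shuffle_split(
    n_frames: int,
    block_len_s: float,
    vocal_mask: np.ndarray,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    frame_rate: float = 100.0,
) -> SplitSpec:
    """Group-stratified shuffle split over indivisible blocks of frames.

    Frames are tiled into consecutive blocks of ``block_len_s`` seconds
    (the trailing partial block is kept as a normal block).  A block is
    labeled vocal if at least half of its frames are vocal.  Within each
    stratum, blocks are shuffled with the seed and allocated to meet the
    ratios; different seeds give different allocations.
    """
    block_len = int(round(block_len_s * frame_rate))
    if block_len < 1:
        raise ValueError("block length must cover at least one frame")
    vocal_mask = np.asarray(vocal_mask, dtype=bool).ravel()
    if vocal_mask.size != n_frames:
        raise ValueError("vocal_mask length must equal n_frames")
    n_blocks = math.ceil(n_frames / block_len)
    block_of_frame = np.minimum(np.arange(n_frames) // block_len, n_blocks - 1)
    block_vocal = np.array([
        vocal_mask[b * block_len : min((b + 1) * block_len, n_frames)].mean() >= 0.5
        for b in range(n_blocks)
    ])

    rng = np.random.default_rng(seed)
    sets: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for stratum in (False, True):
        blocks = np.flatnonzero(block_vocal == stratum)
        if blocks.size == 0:
            continue
        if blocks.size < 3:
            raise ValueError(
                f"stratum {'vocal' if stratum else 'instrumental'} has fewer than 3 blocks"
            )
        order = rng.permutation(blocks)
        n_tr, n_va, n_te = _allocate(blocks.size, ratios)
        sets["train"].extend(order[:n_tr])
        sets["val"].extend(order[n_tr : n_tr + n_va])
        sets["test"].extend(order[n_tr + n_va :])

    def frames_of(block_ids: list[int]) -> np.ndarray:
        ids = np.asarray(sorted(block_ids), dtype=int)
        return np.flatnonzero(np.isin(block_of_frame, ids))

    return SplitSpec(
        train=frames_of(sets["train"]),
        val=frames_of(sets["val"]),
        test=frames_of(sets["test"]),
        block_len_s=block_len_s,
        ratios=ratios,
        seed=seed,
        block_of_frame=block_of_frame,
    )


def fit_feature_scaler(X_train: np.ndarray) -> RobustScaler:
    """Robust scaler (median, 2-98 percentile range) fitted on training rows only."""
    scaler = RobustScaler(quantile_range=(2.0, 98.0))
    scaler.fit(X_train)
    return scaler


def apply_scaler(scaler: RobustScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)
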