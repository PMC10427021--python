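"""Shared in-memory containers and on-disk formats.

Arrays travel in NPZ files with named datasets, tabular metadata in TSV
(pandas), metrics and manifests in JSON.  All containers are plain
dataclasses over numpy arrays so every pipeline stage can be used as a
library function without touching disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "Spectrogram",
    "EcogRecording",
    "HfaMatrix",
    "save_npz",
    "load_npz",
    "write_electrode_table",
    "read_electrode_table",
    "write_json",
    "read_json",
]


@dataclass
class Waveform:
    """Mono audio signal.

    samples are arbitrary units, nominally within +/-1 after normalization;
    sample_rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Spectrogram:
    """Time-frequency magnitude representation.

    values: (frames, n_bins); frame_rate in Hz; center_frequencies in Hz,
    strictly increasing (geometric spacing); scale is 'magnitude'
    (nonnegative) or 'log'.
    """

    values: np.ndarray
    frame_rate: float
    center_frequencies: np.ndarray
    scale: str = "magnitude"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (frames x bins)")
        if self.values.shape[1] != self.center_frequencies.size:
            raise ValueError("bin count does not match center_frequencies")
        if np.any(np.diff(self.center_frequencies) <= 0):
            raise ValueError("center_frequencies must be strictly increasing")
        if self.scale not in ("magnitude", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "magnitude" and self.values.size and self.values.min() < 0:
            raise ValueError("magnitude-scale spectrogram must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class EcogRecording:
    """Raw multichannel intracranial recording.

    data: (samples, electrodes) in microvolts; fs in Hz; pad_s seconds of
    padding retained before and after the stimulus window (symmetric).
    splitter_group partitions electrodes into amplifier groups that are
    referenced separately.
    """

    data: np.ndarray
    fs: float
    electrode_ids: list[str]
    splitter_group: np.ndarray
    pad_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.splitter_group = np.asarray(self.splitter_group, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples x electrodes)")
        if self.data.shape[1] != len(self.electrode_ids):
            raise ValueError("electrode_ids length does not match channel count")
        if self.splitter_group.size != self.data.shape[1]:
            raise ValueError("splitter_group length does not match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]


@dataclass
class HfaMatrix:
    """High-frequency-activity time series, robust z-units at 100 Hz.

    values: (frames, electrodes); outlier_mask True where a sample is
    excluded from modeling (artifact tag or missing lag context).
    """

    values: np.ndarray
    frame_rate: float
    electrode_ids: list[str]
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("HFA values must be 2-D (frames x electrodes)")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.values.shape, dtype=bool)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.outlier_mask.shape != self.values.shape:
            raise ValueError("outlier_mask shape must match values")
        if self.values.shape[1] != len(self.electrode_ids):
            raise ValueError("electrode_ids length does not match column count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# on-disk formats


def save_npz(path: str | Path, **arrays) -> None:
    """Write named arrays (and scalars) to an uncompressed NPZ container."""
    np.savez(str(path), **arrays)


def load_npz(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(str(path), allow_pickle=False) as data:
        return {k: data[k] for k in data.files}


ELECTRODE_COLUMNS = ["electrode_id", "hemisphere", "region", "splitter_group"]


def write_electrode_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"electrode table missing columns {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_electrode_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"electrode_id": str})
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"electrode table missing columns {missing}")
    return df


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyJSONEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
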