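"""Analysis-window extraction, [0, 1] normalization and sliding-window segmentation.

The classifier operates in the real-time setting: only samples strictly
before the alarm onset are used.  One channel of a record is turned into a
sequence of T overlapping 200-sample windows by

1. taking the last ``window_seconds`` of signal before ``onset_index``,
2. min-max normalizing that whole window to [0, 1] (a single affine map per
   channel, so inter-segment amplitude structure such as an asystole flatline
   survives), and
3. cutting it into 200-sample segments with 25 % overlap (stride 150).

No filtering or denoising is applied anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InsufficientDataError, MissingModalityError, SchemaError
from .io import ChannelRole, WaveformRecord

__all__ = [
    "PreprocessConfig",
    "SegmentBatch",
    "extract_analysis_window",
    "normalize",
    "segment",
    "prepare_modality",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Windowing parameters.

    window_seconds
        Pre-alarm span fed to the model.  16 s at 250 Hz gives 4000 samples
        -> 26 segments; long enough to contain the >=4 s events that define
        asystole and ventricular flutter.
    segment_samples
        Sliding-window length n (200 samples = 0.8 s).
    overlap_fraction
        Fractional overlap between consecutive windows (0.25 -> stride 150).
    """

    window_seconds: float = 16.0
    segment_samples: int = 200
    overlap_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise SchemaError("window_seconds must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise SchemaError("overlap_fraction must lie in [0, 1)")
        if self.stride < 1:
            raise SchemaError("stride rounds to zero; decrease overlap_fraction")

    @property
    def stride(self) -> int:
        return int(round(self.segment_samples * (1 - self.overlap_fraction)))


@dataclass
class SegmentBatch:
    """Ordered sequence of normalized segments for one channel of one record."""

    record_id: str
    channel_role: ChannelRole
    segments: np.ndarray  # (T, n), values in [0, 1]
    stride: int
    window_seconds: float

    def __len__(self) -> int:
        return self.segments.shape[0]


def extract_analysis_window(
    record: WaveformRecord, channel_role: ChannelRole, window_seconds: float
) -> np.ndarray:
    """Last ``floor(window_seconds * fs)`` samples strictly before the alarm onset."""
    if channel_role not in record.channels:
        raise MissingModalityError(
            f"record {record.record_id!r} has no {channel_role.value} channel"
        )
    w = int(np.floor(window_seconds * record.fs))
    if w > record.onset_index:
        raise InsufficientDataError(
            f"record {record.record_id!r}: {w} samples requested but only "
            f"{record.onset_index} precede the alarm"
        )
    x = record.channels[channel_role]
    return np.asarray(x[record.onset_index - w : record.onset_index], dtype=np.float64)


def normalize(x: np.ndarray) -> np.ndarray:
    """Min-max map onto [0, 1]; a constant signal maps to all zeros."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise SchemaError("cannot normalize an empty array")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def segment_count(length: int, n: int, stride: int) -> int:
    return (length - n) // stride + 1


def segment(x: np.ndarray, n: int = 200, overlap_fraction: float = 0.25) -> np.ndarray:
    """Cut ``x`` into (T, n) sliding windows; trailing samples that do not
    fill a whole window are dropped."""
    x = np.asarray(x)
    if not (0 <= overlap_fraction < 1):
        raise SchemaError("overlap_fraction must lie in [0, 1)")
    stride = int(round(n * (1 - overlap_fraction)))
    if stride < 1:
        raise SchemaError("stride rounds to zero")
    if len(x) < n:
        raise InsufficientDataError(f"signal of length {len(x)} shorter than window {n}")
    return sliding_window_view(x, n)[::stride].copy()


def prepare_modality(
    record: WaveformRecord,
    channel_role: ChannelRole,
    config: PreprocessConfig = PreprocessConfig(),
) -> SegmentBatch:
    """extract_analysis_window -> normalize -> segment, in that order."""
    window = extract_analysis_window(record, channel_role, config.window_seconds)
    segments = segment(normalize(window), config.segment_samples, config.overlap_fraction)
    return SegmentBatch(
        record_id=record.record_id,
        channel_role=channel_role,
        segments=segments,
        stride=config.stride,
        window_seconds=config.window_seconds,
    )
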