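"""Resampling, channel-wise normalization, and sliding-window tensors.

Everything here is deterministic.  The normalizer is intended to be fitted
on score-task recordings only and applied to both tasks, so that improv
reconstruction errors measure deviation from the training distribution
rather than trivial scale differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Recording


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/sd pooled over a reference set of recordings."""

    mean: np.ndarray
    sd: np.ndarray
    channel_ids: tuple
    reference: str = ""

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            bad = [self.channel_ids[i] for i in np.flatnonzero(self.sd <= 0)]
            raise DegenerateChannelError(f"zero-variance channel(s): {bad}")


@dataclass
class WindowTensor:
    """Stack of sliding windows with provenance back to (subject, task, start).

    data: (n_windows, window_len, n_channels); provenance is a DataFrame
    with one row per window: subject_id, task, start (0-based sample index
    into the source recording).
    """

    data: np.ndarray
    provenance: pd.DataFrame
    channel_ids: tuple
    stride: int = 1

    def __post_init__(self) -> None:
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("provenance rows must match window count")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def window_len(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def subset(self, index: np.ndarray) -> "WindowTensor":
        return WindowTensor(
            data=self.data[index],
            provenance=self.provenance.iloc[index].reset_index(drop=True),
            channel_ids=self.channel_ids,
            stride=self.stride,
        )


def resample_to_length(recording: Recording, target_len: int) -> Recording:
    """Per-channel linear interpolation onto target_len points over the same span.

    Endpoints are preserved exactly; the sampling rate is rescaled so the
    recording duration is unchanged.
    """
    T = recording.n_samples
    if T < 2:
        raise ValueError("resampling needs at least 2 input samples")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len == T:
        return recording.with_data(recording.data.copy())
    x_old = np.linspace(0.0, 1.0, T)
    x_new = np.linspace(0.0, 1.0, target_len)
    out = np.empty((target_len, recording.n_channels))
    for c in range(recording.n_channels):
        out[:, c] = np.interp(x_new, x_old, recording.data[:, c])
    new_rate = recording.rate_hz * (target_len - 1) / (T - 1)
    return recording.with_data(out, rate_hz=new_rate)


def fit_normalizer(recordings: Sequence[Recording]) -> ChannelStats:
    """Pool all time points of all recordings; per-channel mean and sd (ddof=0)."""
    if not recordings:
        raise ValueError("need at least one recording")
    ids = tuple(recordings[0].channel_ids)
    for rec in recordings:
        if tuple(rec.channel_ids) != ids:
            raise ValueError("inconsistent channel sets across recordings")
    pooled = np.concatenate([rec.data for rec in recordings], axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    ref = f"{len(recordings)} recording(s), {pooled.shape[0]} pooled samples"
    return ChannelStats(mean=mean, sd=sd, channel_ids=ids, reference=ref)


def apply_normalizer(recording: Recording, stats: ChannelStats) -> Recording:
    """(x - mean) / sd per channel."""
    if tuple(recording.channel_ids) != stats.channel_ids:
        raise ValueError("recording channels do not match normalizer channels")
    return recording.with_data((recording.data - stats.mean) / stats.sd)


def invert_normalizer(recording: Recording, stats: ChannelStats) -> Recording:
    """Inverse of :func:`apply_normalizer`."""
    if tuple(recording.channel_ids) != stats.channel_ids:
        raise ValueError("recording channels do not match normalizer channels")
    return recording.with_data(recording.data * stats.sd + stats.mean)


def sliding_windows(
    recordings: Iterable[Recording], window_len: int, stride: int = 1
) -> WindowTensor:
    """Extract windows [i, i+W) at i = 0, stride, 2*stride, ... per recording.

    Windows never span recording (hence subject) boundaries.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("need at least one recording")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ids = tuple(recordings[0].channel_ids)
    blocks = []
    rows = []
    for rec in recordings:
        if tuple(rec.channel_ids) != ids:
            raise ValueError("inconsistent channel sets across recordings")
        T = rec.n_samples
        if T < window_len:
            raise ValueError(
                f"recording {rec.subject_id}/{rec.task} has {T} samples < window {window_len}"
            )
        starts = np.arange(0, T - window_len + 1, stride)
        # stride-tricks view then copy: (n, W, C) without a python loop
        view = np.lib.stride_tricks.sliding_window_view(rec.data, window_len, axis=0)
        blocks.append(np.ascontiguousarray(view[starts].transpose(0, 2, 1)))
        rows.extend(
            {"subject_id": rec.subject_id, "task": rec.task, "start": int(s)} for s in starts
        )
    return WindowTensor(
        data=np.concatenate(blocks, axis=0),
        provenance=pd.DataFrame(rows),
        channel_ids=ids,
        stride=stride,
    )
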