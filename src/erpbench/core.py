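"""Core domain containers and time-axis conventions.

Conventions used throughout the package:

* voltages are microvolts (μV), channel x sample matrices;
* sample 0 of an epoch axis sits at the event onset, latencies are
  milliseconds;
* analysis windows are half-open ``[start, end)``: the sample at ``start``
  is included, the sample at ``end`` is excluded. At 500 Hz this makes the
  −200..1000 ms trimmed epoch exactly 600 samples long.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .montage import Montage

__all__ = [
    "Condition",
    "EventMarker",
    "Recording",
    "EpochSet",
    "ERPWaveform",
    "time_window_to_samples",
    "select_channels",
]

Condition = Literal["gain", "loss"]


@dataclass(frozen=True)
class EventMarker:
    """A feedback event: sample index in the recording plus its condition."""

    sample_index: int
    condition: Condition

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError("event sample_index must be >= 0")
        if self.condition not in ("gain", "loss"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class Recording:
    """Continuous multichannel voltage trace with events and montage.

    ``data`` is ``(n_channels, n_samples)`` in μV; ``fs`` in Hz.
    """

    data: np.ndarray
    fs: float
    events: list[EventMarker]
    montage: Montage
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            if ev.sample_index >= n:
                raise ValueError(
                    f"event at sample {ev.sample_index} beyond recording "
                    f"length {n}"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Trials x channels x samples cube time-locked to feedback events.

    ``times`` is the per-sample latency axis in ms relative to event onset
    (uniform step ``1000/fs``). ``accepted`` marks trials that survived
    rejection; ``channel_violations`` is a per-trial x per-channel record of
    which channel breached which ever criterion (any criterion, boolean).
    """

    data: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    fs: float
    montage: Montage
    subject_id: str = "subject"
    accepted: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_violations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        n_trials, n_ch, n_samp = self.data.shape
        if self.times.shape != (n_samp,):
            raise ValueError("times length must match sample dimension")
        step = 1000.0 / self.fs
        if n_samp > 1 and not np.allclose(np.diff(self.times), step, atol=1e-6):
            raise ValueError("times must be uniform with step 1000/fs ms")
        if self.conditions.shape != (n_trials,):
            raise ValueError("one condition label per trial required")
        if self.accepted is None:
            self.accepted = np.ones(n_trials, dtype=bool)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.channel_violations is None:
            self.channel_violations = np.zeros((n_trials, n_ch), dtype=bool)
        self.channel_violations = np.asarray(self.channel_violations, dtype=bool)
        if self.channel_violations.shape != (n_trials, n_ch):
            raise ValueError("channel_violations must be trials x channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def accepted_of(self, condition: str) -> np.ndarray:
        """Indices of accepted trials of the given condition."""
        return np.nonzero(self.accepted & (self.conditions == condition))[0]


@dataclass
class ERPWaveform:
    """Channels x samples average for one condition (or the gain-loss
    difference), with the number of trials averaged (0 for a difference)."""

    data: np.ndarray
    times: np.ndarray
    condition: str
    montage: Montage
    n_trials: int = 0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (self.montage.n_channels, self.times.size):
            raise ValueError("ERP data must be channels x samples matching times")
        if not np.isfinite(self.data).all():
            raise ValueError("ERP contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.montage.index(name)]


def time_window_to_samples(
    t_start_ms: float, t_end_ms: float, fs: float
) -> tuple[int, int]:
    """Convert a half-open ms window to (first sample index, sample count).

    Sample indices are relative to the event onset (sample 0 at 0 ms). The
    sample at ``t_start_ms`` is included and the one at ``t_end_ms`` is
    excluded, so ``n_samples = (t_end - t_start) * fs / 1000`` exactly.
    Window endpoints must fall on the sample grid.

    >>> time_window_to_samples(-200, 1000, 500)
    (-100, 600)
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not t_start_ms < t_end_ms:
        raise ValueError(
            f"empty or inverted window [{t_start_ms}, {t_end_ms}) ms"
        )
    start_f = t_start_ms * fs / 1000.0
    n_f = (t_end_ms - t_start_ms) * fs / 1000.0
    start = round(start_f)
    n = round(n_f)
    if abs(start_f - start) > 1e-6 or abs(n_f - n) > 1e-6:
        raise ValueError(
            f"window [{t_start_ms}, {t_end_ms}) ms is not aligned to the "
            f"{1000.0 / fs:g} ms sample grid at fs={fs:g} Hz"
        )
    return int(start), int(n)


def select_channels(recording: Recording, names: Sequence[str]) -> Recording:
    """Restrict a recording to the named channels, in the given order."""
    missing = [n for n in names if n not in recording.montage.channel_names]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    idx = [recording.montage.index(n) for n in names]
    return Recording(
        data=recording.data[idx].copy(),
        fs=recording.fs,
        events=list(recording.events),
        montage=recording.montage.subset(list(names)),
        subject_id=recording.subject_id,
    )
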