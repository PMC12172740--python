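"""Epoching, baseline correction, trial rejection, bad channels, ERPs.

The processing follows a two-pass scheme. The first pass is a throwaway
run (re-reference, band-pass, epoch, baseline, flag trials) whose only
output is the per-channel trial-rejection rate: a channel responsible for
rejecting more than 40% of trials is marked bad. The second pass starts
again from the raw recording, re-references, filters, interpolates the bad
channels, epochs to −500..1300 ms, baseline-corrects on −200..0 ms, rejects
trials, averages per condition, forms the gain−loss difference, and trims
the ERPs to −200..1000 ms (600 samples at 500 Hz).

Trial rejection statistics are computed per channel over the full epoch
window after baseline correction, and every threshold comparison is a
strict ``>`` ("exceeds").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import EpochSet, ERPWaveform, Recording, time_window_to_samples
from .filters import FilterSpec, apply_zero_phase, design_butterworth_bandpass, design_notch
from .spatial import (
    InterpolationModel,
    detect_flat_channels,
    interpolate,
    rereference_linked_mastoids,
)

__all__ = [
    "RejectionCriteria",
    "BadChannelPolicy",
    "SubjectResult",
    "segment_epochs",
    "baseline_correct",
    "flag_trials",
    "detect_bad_channels_two_pass",
    "run_second_pass",
    "average_erp",
    "difference_erp",
    "subject_inclusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RejectionCriteria:
    """Thresholds of the trial-rejection rules; ``None`` disables a rule.

    * ``gradient_uv_per_ms`` — maximal sample-to-sample voltage change,
      expressed per millisecond;
    * ``minmax_uv`` — peak-to-peak (max − min) amplitude over the epoch;
    * ``absolute_uv`` — symmetric absolute-amplitude bound (±threshold).
    """

    gradient_uv_per_ms: float | None = 10.0
    minmax_uv: float | None = 100.0
    absolute_uv: float | None = None

    def __post_init__(self) -> None:
        for name in ("gradient_uv_per_ms", "minmax_uv", "absolute_uv"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when enabled")
        if all(
            getattr(self, n) is None
            for n in ("gradient_uv_per_ms", "minmax_uv", "absolute_uv")
        ):
            raise ValueError("at least one rejection criterion must be enabled")


@dataclass(frozen=True)
class BadChannelPolicy:
    """How bad channels are found before interpolation.

    ``two_pass_rejection_rate``: the throwaway first pass described above,
    epoching −500..1500 ms, with ``rate_threshold`` the strict rejection-rate
    bound. ``flat_detection``: channels flat for longer than
    ``flat_min_duration_s`` (the more widespread automatic alternative).
    """

    method: str = "two_pass_rejection_rate"  # or "flat_detection"
    rate_threshold: float = 0.40
    first_pass_epoch_ms: tuple[float, float] = (-500.0, 1500.0)
    flat_min_duration_s: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in ("two_pass_rejection_rate", "flat_detection"):
            raise ValueError(f"unknown bad-channel policy {self.method!r}")
        if not 0 < self.rate_threshold < 1:
            raise ValueError("rate_threshold must lie in (0, 1)")


def segment_epochs(
    recording: Recording, window_ms: tuple[float, float] = (-500.0, 1300.0)
) -> EpochSet:
    """Cut one epoch per event; events whose window leaves the recording
    are dropped (count logged). Raises if no epoch fits."""
    if not recording.events:
        raise ValueError("recording has no events to epoch")
    first, n_samp = time_window_to_samples(window_ms[0], window_ms[1], recording.fs)
    segments = []
    conditions = []
    dropped = 0
    for ev in recording.events:
        lo = ev.sample_index + first
        hi = lo + n_samp
        if lo < 0 or hi > recording.n_samples:
            dropped += 1
            continue
        segments.append(recording.data[:, lo:hi])
        conditions.append(ev.condition)
    if dropped:
        logger.info(
            "%s: dropped %d events outside the recording", recording.subject_id, dropped
        )
    if not segments:
        raise ValueError("no event window fits inside the recording")
    times = (np.arange(n_samp) + first) * 1000.0 / recording.fs
    return EpochSet(
        data=np.stack(segments),
        times=times,
        conditions=np.array(conditions),
        fs=recording.fs,
        montage=recording.montage,
        subject_id=recording.subject_id,
    )


def _window_slice(times: np.ndarray, fs: float, window_ms: tuple[float, float]) -> slice:
    first, n = time_window_to_samples(window_ms[0], window_ms[1], fs)
    start = first - round(times[0] * fs / 1000.0)
    if start < 0 or start + n > times.size:
        raise ValueError(
            f"window {window_ms} ms lies outside the epoch axis "
            f"[{times[0]:g}, {times[-1]:g}] ms"
        )
    return slice(start, start + n)


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    sl = _window_slice(epochs.times, epochs.fs, baseline_ms)
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EpochSet(
        data=epochs.data - base,
        times=epochs.times.copy(),
        conditions=epochs.conditions.copy(),
        fs=epochs.fs,
        montage=epochs.montage,
        subject_id=epochs.subject_id,
        accepted=epochs.accepted.copy(),
        channel_violations=epochs.channel_violations.copy(),
    )


def flag_trials(epochs: EpochSet, criteria: RejectionCriteria) -> EpochSet:
    """Mark trials whose any channel strictly exceeds an enabled criterion.

    Statistics per channel over the full epoch window: gradient
    ``max |x[i+1]-x[i]| * fs/1000`` (μV/ms), min-max ``max - min`` (μV),
    absolute ``max |x|`` (μV).
    """
    data = epochs.data
    violations = np.zeros(data.shape[:2], dtype=bool)
    if criteria.gradient_uv_per_ms is not None:
        grad = np.abs(np.diff(data, axis=2)).max(axis=2) * epochs.fs / 1000.0
        violations |= grad > criteria.gradient_uv_per_ms
    if criteria.minmax_uv is not None:
        minmax = data.max(axis=2) - data.min(axis=2)
        violations |= minmax > criteria.minmax_uv
    if criteria.absolute_uv is not None:
        violations |= np.abs(data).max(axis=2) > criteria.absolute_uv
    return EpochSet(
        data=data.copy(),
        times=epochs.times.copy(),
        conditions=epochs.conditions.copy(),
        fs=epochs.fs,
        montage=epochs.montage,
        subject_id=epochs.subject_id,
        accepted=~violations.any(axis=1),
        channel_violations=violations,
    )


def _default_band_filter(fs: float) -> FilterSpec:
    return design_butterworth_bandpass(0.1, 30.0, 4, fs)


def detect_bad_channels_two_pass(
    recording: Recording,
    band_filter: FilterSpec | None = None,
    notch_filter: FilterSpec | None | str = "default",
    criteria: RejectionCriteria | None = None,
    policy: BadChannelPolicy | None = None,
) -> list[str]:
    """First processing pass: find channels with excessive rejection rates.

    The pass re-references to linked mastoids, band-pass filters (plus the
    optional notch), epochs to the first-pass window, baseline-corrects,
    flags trials, and computes per channel the fraction of trials in which
    that channel violated a criterion. Channels strictly above the rate
    threshold are returned; the input recording is left unmodified. With a
    ``flat_detection`` policy, flat-run detection on the raw recording is
    used instead.
    """
    policy = policy or BadChannelPolicy()
    if policy.method == "flat_detection":
        return detect_flat_channels(recording, policy.flat_min_duration_s)
    criteria = criteria or RejectionCriteria()
    band_filter = band_filter or _default_band_filter(recording.fs)
    if notch_filter == "default":
        notch_filter = design_notch(60.0, recording.fs)

    work = rereference_linked_mastoids(recording)
    work = apply_zero_phase(work, band_filter)
    if notch_filter is not None:
        work = apply_zero_phase(work, notch_filter)
    epochs = segment_epochs(work, policy.first_pass_epoch_ms)
    epochs = baseline_correct(epochs)
    epochs = flag_trials(epochs, criteria)

    rates = epochs.channel_violations.mean(axis=0)
    bad = [
        name
        for name, rate in zip(recording.montage.channel_names, rates)
        if rate > policy.rate_threshold
    ]
    return bad


@dataclass
class SubjectResult:
    """Outcome of the second pass for one subject."""

    subject_id: str
    bad_channels: list[str]
    epochs: EpochSet | None
    erps: dict[str, ERPWaveform] | None
    included: bool
    accepted_counts: dict[str, int] = field(default_factory=dict)
    n_trials_total: int = 0
    error: str | None = None

    def to_record(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "bad_channels": self.bad_channels,
            "included": self.included,
            "accepted_counts": self.accepted_counts,
            "n_trials_total": self.n_trials_total,
            "error": self.error,
        }


def run_second_pass(
    recording: Recording,
    bad_channels: list[str],
    variant_config,
    min_trials_per_condition: int = 15,
) -> SubjectResult:
    """Run the full second pass on the raw recording.

    ``variant_config`` is any object exposing ``band_filter(fs)``,
    ``notch_filter(fs)`` (may return ``None``), ``interpolation_model()``
    and ``criteria()`` — see :class:`erpbench.variants.VariantConfig`.
    Stage errors are wrapped with the stage name.
    """
    stage = "re-reference"
    try:
        work = rereference_linked_mastoids(recording)
        stage = "filter"
        work = apply_zero_phase(work, variant_config.band_filter(recording.fs))
        notch = variant_config.notch_filter(recording.fs)
        if notch is not None:
            work = apply_zero_phase(work, notch)
        stage = "interpolate"
        if bad_channels:
            work = work.copy_with(
                data=interpolate(
                    work.montage, work.data, bad_channels,
                    variant_config.interpolation_model(),
                )
            )
        stage = "segment"
        epochs = segment_epochs(work, (-500.0, 1300.0))
        stage = "baseline"
        epochs = baseline_correct(epochs, (-200.0, 0.0))
        stage = "reject"
        epochs = flag_trials(epochs, variant_config.criteria())
    except Exception as exc:
        raise RuntimeError(f"second pass failed at stage {stage!r}: {exc}") from exc

    counts = {
        cond: int(epochs.accepted_of(cond).size) for cond in ("gain", "loss")
    }
    included = subject_inclusion(epochs, min_trials_per_condition)
    erps = None
    if counts["gain"] >= 1 and counts["loss"] >= 1:
        gain = average_erp(epochs, "gain")
        loss = average_erp(epochs, "loss")
        diff = difference_erp(gain, loss)
        erps = {
            "gain": _trim_erp(gain),
            "loss": _trim_erp(loss),
            "difference": _trim_erp(diff),
        }
    return SubjectResult(
        subject_id=recording.subject_id,
        bad_channels=list(bad_channels),
        epochs=epochs,
        erps=erps,
        included=included,
        accepted_counts=counts,
        n_trials_total=epochs.n_trials,
    )


def _trim_erp(
    erp: ERPWaveform, window_ms: tuple[float, float] = (-200.0, 1000.0)
) -> ERPWaveform:
    fs = 1000.0 / (erp.times[1] - erp.times[0])
    sl = _window_slice(erp.times, fs, window_ms)
    return ERPWaveform(
        data=erp.data[:, sl],
        times=erp.times[sl],
        condition=erp.condition,
        montage=erp.montage,
        n_trials=erp.n_trials,
        subject_id=erp.subject_id,
    )


def average_erp(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Arithmetic mean over accepted trials of one condition."""
    idx = epochs.accepted_of(condition)
    if idx.size == 0:
        raise ValueError(f"no accepted {condition!r} trials to average")
    return ERPWaveform(
        data=epochs.data[idx].mean(axis=0),
        times=epochs.times.copy(),
        condition=condition,
        montage=epochs.montage,
        n_trials=int(idx.size),
        subject_id=epochs.subject_id,
    )


def difference_erp(gain: ERPWaveform, loss: ERPWaveform) -> ERPWaveform:
    """Pointwise gain − loss reward-positivity waveform."""
    if gain.times.shape != loss.times.shape or not np.allclose(
        gain.times, loss.times
    ):
        raise ValueError("gain and loss ERPs must share the same time axis")
    return ERPWaveform(
        data=gain.data - loss.data,
        times=gain.times.copy(),
        condition="difference",
        montage=gain.montage,
        n_trials=0,
        subject_id=gain.subject_id,
    )


def subject_inclusion(epochs: EpochSet, min_trials_per_condition: int = 15) -> bool:
    """A subject is kept iff each condition retains enough accepted trials."""
    return all(
        epochs.accepted_of(cond).size >= min_trials_per_condition
        for cond in ("gain", "loss")
    )
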