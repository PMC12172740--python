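"""Reward-positivity ERP features at a designated channel (default FCz).

Four per-subject scores are computed from trimmed (−200..1000 ms) ERPs:

* **peak time** — latency of the maximum of the difference waveform inside
  a 200–400 ms search window (ties broken toward the earlier sample);
* **mean peak** — average voltage within ±46 ms of the peak latency
  (47 samples at 500 Hz for an interior peak; clipped at the axis edges);
* **max peak** — largest signed voltage within 200–400 ms;
* **base to peak** — max peak minus the minimum of the trough immediately
  prior to the peak (nearest local-minimum segment before the peak; if the
  rise is monotone from stimulus onset, the global minimum of [0, peak]).

For the conditional (gain and loss) waveforms, the mean-peak latency anchor
is the subject's own difference-ERP peak, so all three scopes share one
peak location per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ERPWaveform

__all__ = [
    "FeatureSet",
    "find_peak_time",
    "mean_peak",
    "max_peak",
    "base_to_peak",
    "extract_feature_table",
]

DEFAULT_SEARCH_MS = (200.0, 400.0)


@dataclass(frozen=True)
class FeatureSet:
    subject_id: str
    scope: str  # gain | loss | difference
    peak_time_ms: float
    mean_peak_uv: float
    max_peak_uv: float
    base_to_peak_uv: float


def _window_mask(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) ms outside ERP axis")
    return mask


def find_peak_time(
    erp: ERPWaveform,
    channel: str = "FCz",
    search_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
) -> float:
    """Latency (ms) of the maximum within the search window; ties earliest."""
    x = erp.channel(channel)
    mask = _window_mask(erp.times, *search_ms)
    idx = np.flatnonzero(mask)
    return float(erp.times[idx[np.argmax(x[idx])]])


def mean_peak(
    erp: ERPWaveform,
    channel: str = "FCz",
    peak_ms: float | None = None,
    half_width_ms: float = 46.0,
) -> float:
    """Mean voltage over ±``half_width_ms`` around the peak latency.

    If ``peak_ms`` is not given it is located on this waveform. The window
    is intersected with the time axis, so a peak near an edge averages over
    fewer samples.
    """
    if peak_ms is None:
        peak_ms = find_peak_time(erp, channel)
    x = erp.channel(channel)
    mask = (erp.times >= peak_ms - half_width_ms) & (
        erp.times <= peak_ms + half_width_ms
    )
    if not mask.any():
        raise ValueError(f"peak at {peak_ms} ms not on the ERP axis")
    return float(x[mask].mean())


def max_peak(
    erp: ERPWaveform,
    channel: str = "FCz",
    window_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
) -> float:
    """Largest signed voltage within the window."""
    x = erp.channel(channel)
    mask = _window_mask(erp.times, *window_ms)
    return float(x[mask].max())


def base_to_peak(
    erp: ERPWaveform,
    channel: str = "FCz",
    window_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
) -> float:
    """Max peak minus the trough immediately preceding it.

    The trough search runs over [0 ms, peak latency]. The "immediately
    prior" trough is the deepest point of the local-minimum segment nearest
    to the peak; when the waveform rises monotonically from onset (no
    interior local minimum), the global minimum of the stretch is used. A
    peak at 0 ms yields 0 by convention.
    """
    x = erp.channel(channel)
    mask = _window_mask(erp.times, *window_ms)
    idx = np.flatnonzero(mask)
    peak_idx = idx[np.argmax(x[idx])]
    peak_val = float(x[peak_idx])

    pre_mask = (erp.times >= 0.0) & (erp.times <= erp.times[peak_idx])
    pre_idx = np.flatnonzero(pre_mask)
    if pre_idx.size <= 1:
        return 0.0
    seg = x[pre_idx]

    # walk backwards from the peak; stop at the bottom of the descent
    i = seg.size - 1
    while i > 0 and seg[i - 1] <= seg[i]:
        i -= 1
    if i == 0:
        # monotone rise from onset: no interior local minimum
        trough_val = float(seg.min())
    else:
        trough_val = float(seg[i])
    return peak_val - trough_val


def extract_feature_table(
    erps_by_subject: dict[str, dict[str, ERPWaveform]],
    channel: str = "FCz",
    search_ms: tuple[float, float] = DEFAULT_SEARCH_MS,
) -> pd.DataFrame:
    """One row per subject x scope with the four features.

    ``erps_by_subject`` maps subject id to a dict with keys ``gain``,
    ``loss`` and ``difference`` (subjects with missing waveforms are
    skipped). The mean-peak anchor for all three scopes is the subject's
    difference-ERP peak.
    """
    rows: list[dict] = []
    for subject_id, erps in erps_by_subject.items():
        if erps is None or any(k not in erps for k in ("gain", "loss", "difference")):
            continue
        anchor = find_peak_time(erps["difference"], channel, search_ms)
        for scope in ("gain", "loss", "difference"):
            erp = erps[scope]
            rows.append(
                {
                    "subject_id": subject_id,
                    "scope": scope,
                    "peak_time_ms": anchor,
                    "mean_peak_uv": mean_peak(erp, channel, peak_ms=anchor),
                    "max_peak_uv": max_peak(erp, channel, search_ms),
                    "base_to_peak_uv": base_to_peak(erp, channel, search_ms),
                }
            )
    return pd.DataFrame(rows)
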