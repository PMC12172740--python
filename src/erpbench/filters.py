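"""Filter design and zero-phase application for the four filter families.

Four designs are covered, mirroring the defaults of the analysis tools whose
pipelines this package emulates:

* ``butterworth_iir`` — band-pass Butterworth of a stated order (the order is
  the design order per pass; a band-pass transform doubles the pole count,
  and forward-backward application squares the magnitude response);
* ``fir_hamming`` — linear-phase windowed-sinc band-pass with a Hamming
  window, order chosen by the optimal-order rule ``3.3 / (df / fs)`` with
  ``df`` the lowest pass-band edge;
* ``fir_kaiser`` — Kaiser-window band-pass with the standard Kaiser order
  estimate ``ceil((A − 7.95) / (2.285 · Δω))`` (A stop-band attenuation in
  dB, Δω the transition width in rad/sample), order bumped to even;
* ``notch_iir`` — second-order IIR notch (default Q = 35) for line noise.

All filters are applied zero phase (forward-backward), which preserves peak
latencies; the effective magnitude response is therefore ``|H|²``. Long FIR
kernels are applied by FFT convolution rather than direct filtering, which
is numerically identical for linear-phase taps and orders of magnitude
faster at the 16k-tap orders involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .core import EpochSet, Recording

__all__ = [
    "FilterSpec",
    "design_butterworth_bandpass",
    "design_fir_hamming",
    "design_fir_kaiser",
    "design_notch",
    "apply_zero_phase",
    "magnitude_response",
]


@dataclass
class FilterSpec:
    """A designed filter: family, band, order, and realized coefficients."""

    family: str  # butterworth_iir | fir_hamming | fir_kaiser | notch_iir
    band: tuple[float, ...]  # (low, high) for band-pass, (center,) for notch
    order: int
    fs: float
    design_params: dict[str, Any] = field(default_factory=dict)
    sos: np.ndarray | None = None  # IIR second-order sections
    taps: np.ndarray | None = None  # FIR impulse response

    @property
    def is_fir(self) -> bool:
        return self.taps is not None

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "band": list(self.band),
            "order": self.order,
            "fs": self.fs,
            "design_params": self.design_params,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        p = json.loads(text)
        return design(p["family"], tuple(p["band"]), p["fs"], **p["design_params"])


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for fs={fs} Hz: need "
            f"0 < low < high < Nyquist"
        )


def design_butterworth_bandpass(
    low: float, high: float, order: int, fs: float
) -> FilterSpec:
    """Band-pass Butterworth IIR of the given design order (per pass)."""
    _check_band(low, high, fs)
    if order <= 0:
        raise ValueError("order must be positive")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    poles = np.concatenate([np.roots([1.0, s[4], s[5]]) for s in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("designed Butterworth filter is unstable")
    return FilterSpec(
        family="butterworth_iir",
        band=(low, high),
        order=order,
        fs=fs,
        design_params={"order": order},
        sos=sos,
    )


def design_fir_hamming(
    low: float, high: float, fs: float, max_order: int = 100_000
) -> FilterSpec:
    """Hamming-window FIR band-pass with the optimal-order rule.

    The order is ``round(3.3 / (low / fs))`` with the low edge acting as the
    narrowest transition ``df``; for a 0.1–30 Hz band at 500 Hz this yields
    the familiar order 16500.
    """
    _check_band(low, high, fs)
    order = round(3.3 / (low / fs))
    if order > max_order:
        raise ValueError(
            f"FIR order {order} exceeds cap {max_order}; consider decimating "
            f"or raising the high-pass edge"
        )
    numtaps = order + 1 if (order % 2 == 0) else order + 2  # odd taps: type I
    taps = signal.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=fs
    )
    return FilterSpec(
        family="fir_hamming",
        band=(low, high),
        order=order,
        fs=fs,
        design_params={},
        taps=taps,
    )


def _kaiser_beta(atten_db: float) -> float:
    if atten_db > 50:
        return 0.1102 * (atten_db - 8.7)
    if atten_db > 21:
        return 0.5842 * (atten_db - 21) ** 0.4 + 0.07886 * (atten_db - 21)
    return 0.0


def design_fir_kaiser(
    low: float,
    high: float,
    fs: float,
    atten_db: float = 60.0,
    transition_hz: float = 0.1,
) -> FilterSpec:
    """Kaiser-window FIR band-pass with the standard order estimate.

    ``order = ceil((atten_db − 7.95) / (2.285 · 2π · transition_hz / fs))``,
    incremented to the next even integer if odd. With (60 dB, 0.1 Hz) at
    500 Hz this gives order 18128.
    """
    _check_band(low, high, fs)
    if atten_db <= 8:
        raise ValueError("attenuation must exceed 8 dB for the Kaiser estimate")
    if transition_hz <= 0:
        raise ValueError("transition width must be positive")
    delta_omega = 2 * math.pi * transition_hz / fs
    order = math.ceil((atten_db - 7.95) / (2.285 * delta_omega))
    if order % 2:
        order += 1
    beta = _kaiser_beta(atten_db)
    taps = signal.firwin(
        order + 1, [low, high], pass_zero=False, window=("kaiser", beta), fs=fs
    )
    return FilterSpec(
        family="fir_kaiser",
        band=(low, high),
        order=order,
        fs=fs,
        design_params={"atten_db": atten_db, "transition_hz": transition_hz},
        taps=taps,
    )


def design_notch(center_hz: float, fs: float, q: float = 35.0) -> FilterSpec:
    """Second-order IIR notch at ``center_hz`` (default Q = 35)."""
    if not 0 < center_hz < fs / 2:
        raise ValueError(f"notch center {center_hz} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(center_hz, q, fs=fs)
    sos = signal.tf2sos(b, a)
    return FilterSpec(
        family="notch_iir",
        band=(center_hz,),
        order=2,
        fs=fs,
        design_params={"q": q},
        sos=sos,
    )


def design(family: str, band: tuple[float, ...], fs: float, **params) -> FilterSpec:
    """Design a filter by family name (dispatch helper for configs)."""
    if family == "butterworth_iir":
        return design_butterworth_bandpass(band[0], band[1], params.get("order", 4), fs)
    if family == "fir_hamming":
        return design_fir_hamming(band[0], band[1], fs)
    if family == "fir_kaiser":
        return design_fir_kaiser(
            band[0], band[1], fs,
            params.get("atten_db", 60.0), params.get("transition_hz", 0.1),
        )
    if family == "notch_iir":
        return design_notch(band[0], fs, params.get("q", 35.0))
    raise ValueError(f"unknown filter family {family!r}")


def _zero_phase_array(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    n = x.shape[-1]
    if spec.is_fir:
        ntaps = spec.taps.size
        if n <= ntaps:
            raise ValueError(
                f"signal of {n} samples too short for zero-phase FIR of "
                f"{ntaps} taps; need more than {ntaps} samples"
            )
        pad = min(ntaps, n - 1)
        # odd reflection at both edges, then forward-backward FFT convolution
        left = 2 * x[..., :1] - x[..., pad:0:-1]
        right = 2 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
        xp = np.concatenate([left, x, right], axis=-1)
        h = spec.taps[None, :] if xp.ndim == 2 else spec.taps
        y = signal.fftconvolve(xp, h, mode="same", axes=-1)
        y = signal.fftconvolve(y[..., ::-1], h, mode="same", axes=-1)[..., ::-1]
        return y[..., pad : pad + n]
    # IIR: forward-backward second-order sections
    eff_order = 2 * spec.sos.shape[0]
    min_len = 3 * eff_order
    if n <= min_len:
        raise ValueError(
            f"signal of {n} samples too short for zero-phase IIR padding; "
            f"need more than {min_len} samples"
        )
    padlen = min(3 * eff_order, n - 1)
    return signal.sosfiltfilt(spec.sos, x, axis=-1, padtype="odd", padlen=padlen)


def apply_zero_phase(obj, spec: FilterSpec):
    """Apply a filter forward-backward (zero net phase) along time.

    Accepts a :class:`Recording`, an :class:`EpochSet` or a plain array with
    time on the last axis, and returns the same type. Channels are filtered
    independently; events and metadata are untouched.
    """
    if isinstance(obj, Recording):
        return obj.copy_with(data=_zero_phase_array(obj.data, spec))
    if isinstance(obj, EpochSet):
        return EpochSet(
            data=_zero_phase_array(obj.data, spec),
            times=obj.times.copy(),
            conditions=obj.conditions.copy(),
            fs=obj.fs,
            montage=obj.montage,
            subject_id=obj.subject_id,
            accepted=obj.accepted.copy(),
            channel_violations=obj.channel_violations.copy(),
        )
    return _zero_phase_array(np.asarray(obj, dtype=float), spec)


def magnitude_response(
    spec: FilterSpec, freqs: np.ndarray, zero_phase: bool = False
) -> np.ndarray:
    """Gain in dB at the given frequencies (Hz).

    By default the single-pass response is returned; with ``zero_phase=True``
    the dB values are doubled, matching forward-backward application.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= spec.fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, Nyquist)")
    if spec.is_fir:
        _, h = signal.freqz(spec.taps, worN=freqs, fs=spec.fs)
    else:
        _, h = signal.sosfreqz(spec.sos, worN=freqs, fs=spec.fs)
    db = 20 * np.log10(np.maximum(np.abs(h), 1e-300))
    return 2 * db if zero_phase else db
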