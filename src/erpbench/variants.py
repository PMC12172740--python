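"""Pipeline variant registry.

A variant bundles the concrete choices that differed between the analysis
tools being emulated: filter family and parameters, presence of the 60 Hz
notch, channel-repair method, trial-rejection criteria, and the bad-channel
policy. Four built-in variants are registered:

========== =============== ===== ================= ==========================
name        band-pass       notch repair            rejection
========== =============== ===== ================= ==========================
reference   Butterworth 4   yes   spherical spline  gradient 10 μV/ms + 100 μV
eeglab      Hamming FIR     no    spherical spline  absolute ±50 μV
brainstorm  Kaiser FIR      yes   inverse distance  peak-to-peak 100 μV
fieldtrip   Butterworth 4   no    inverse distance  min-max 100 μV
========== =============== ===== ================= ==========================

All variants band-pass 0.1–30 Hz and share the two-pass bad-channel policy;
``with_flat_policy`` derives the modified pipelines that detect flat
channels instead (optionally with the min-max threshold raised to 200 μV).
Variant configs can be read from YAML; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .filters import (
    FilterSpec,
    design_butterworth_bandpass,
    design_fir_hamming,
    design_fir_kaiser,
    design_notch,
)
from .pipeline import BadChannelPolicy, RejectionCriteria
from .spatial import InterpolationModel

__all__ = [
    "VariantConfig",
    "REGISTRY",
    "get_variant",
    "variant_from_dict",
    "load_variants_yaml",
]


@dataclass(frozen=True)
class VariantConfig:
    """Concrete configuration of one preprocessing pipeline variant."""

    name: str
    filter_family: str = "butterworth_iir"
    band_hz: tuple[float, float] = (0.1, 30.0)
    butterworth_order: int = 4
    kaiser_atten_db: float = 60.0
    kaiser_transition_hz: float = 0.1
    notch_enabled: bool = True
    notch_hz: float = 60.0
    notch_q: float = 35.0
    interpolation: str = "spherical_spline"
    gradient_uv_per_ms: float | None = 10.0
    minmax_uv: float | None = 100.0
    absolute_uv: float | None = None
    bad_channel_method: str = "two_pass_rejection_rate"
    rate_threshold: float = 0.40
    flat_min_duration_s: float = 5.0

    def band_filter(self, fs: float) -> FilterSpec:
        low, high = self.band_hz
        if self.filter_family == "butterworth_iir":
            return design_butterworth_bandpass(low, high, self.butterworth_order, fs)
        if self.filter_family == "fir_hamming":
            return design_fir_hamming(low, high, fs)
        if self.filter_family == "fir_kaiser":
            return design_fir_kaiser(
                low, high, fs, self.kaiser_atten_db, self.kaiser_transition_hz
            )
        raise ValueError(f"unknown filter family {self.filter_family!r}")

    def notch_filter(self, fs: float) -> FilterSpec | None:
        if not self.notch_enabled:
            return None
        return design_notch(self.notch_hz, fs, self.notch_q)

    def interpolation_model(self) -> InterpolationModel:
        return InterpolationModel(method=self.interpolation)

    def criteria(self) -> RejectionCriteria:
        return RejectionCriteria(
            gradient_uv_per_ms=self.gradient_uv_per_ms,
            minmax_uv=self.minmax_uv,
            absolute_uv=self.absolute_uv,
        )

    def policy(self) -> BadChannelPolicy:
        return BadChannelPolicy(
            method=self.bad_channel_method,
            rate_threshold=self.rate_threshold,
            flat_min_duration_s=self.flat_min_duration_s,
        )

    def with_flat_policy(self, minmax_uv: float | None = None) -> "VariantConfig":
        """Derived variant using flat-channel detection (and optionally a
        raised min-max threshold)."""
        out = replace(
            self,
            name=f"{self.name}_flat"
            + ("" if minmax_uv in (None, self.minmax_uv) else f"_{minmax_uv:g}"),
            bad_channel_method="flat_detection",
        )
        if minmax_uv is not None and self.minmax_uv is not None:
            out = replace(out, minmax_uv=minmax_uv)
        return out


REGISTRY: dict[str, VariantConfig] = {
    "reference": VariantConfig(
        name="reference",
        filter_family="butterworth_iir",
        notch_enabled=True,
        interpolation="spherical_spline",
        gradient_uv_per_ms=10.0,
        minmax_uv=100.0,
    ),
    "eeglab_like": VariantConfig(
        name="eeglab_like",
        filter_family="fir_hamming",
        notch_enabled=False,
        interpolation="spherical_spline",
        gradient_uv_per_ms=None,
        minmax_uv=None,
        absolute_uv=50.0,
    ),
    "brainstorm_like": VariantConfig(
        name="brainstorm_like",
        filter_family="fir_kaiser",
        notch_enabled=True,
        interpolation="inverse_distance",
        gradient_uv_per_ms=None,
        minmax_uv=100.0,
    ),
    "fieldtrip_like": VariantConfig(
        name="fieldtrip_like",
        filter_family="butterworth_iir",
        notch_enabled=False,
        interpolation="inverse_distance",
        gradient_uv_per_ms=None,
        minmax_uv=100.0,
    ),
}


def get_variant(name: str) -> VariantConfig:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


_FIELD_NAMES = {f.name for f in fields(VariantConfig)}


def variant_from_dict(payload: dict) -> VariantConfig:
    """Build a variant from a mapping, rejecting unknown keys (fail fast)."""
    unknown = set(payload) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown variant config keys: {sorted(unknown)}")
    if "band_hz" in payload:
        payload = {**payload, "band_hz": tuple(payload["band_hz"])}
    return VariantConfig(**payload)


def load_variants_yaml(path: str | Path) -> dict[str, VariantConfig]:
    """Read a YAML mapping of variant name -> config overrides."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("variants YAML must be a mapping of name -> config")
    out = {}
    for name, cfg in doc.items():
        cfg = dict(cfg or {})
        cfg.setdefault("name", name)
        out[name] = variant_from_dict(cfg)
    return out
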