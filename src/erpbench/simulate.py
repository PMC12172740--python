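"""Synthetic feedback-ERP cohort generator with known ground truth.

Emulates the statistical structure of a gambling-task EEG study: 32-channel
recordings at 500 Hz in which gain/loss feedback events evoke stereotyped
ERP components riding on 1/f background noise. Every quantity downstream
stages estimate (component latencies, amplitudes, injected artifacts) is
recorded in a manifest, so recovery can be checked against truth rather
than against published figures.

The default template places conditional components at 212 ms and 370 ms
post-feedback in both conditions and a gain-specific (difference) component
peaking at 310 ms with 4.8 μV at FCz, with a fronto-central topography
maximal at FCz — the canonical reward-positivity morphology. Trials come in
six blocks of twenty, each trial independently gain with probability 0.5.

Injectable artifacts cover what the preprocessing must reject: frontal
biphasic blinks, high-amplitude broadband transients, flat channels, and
60 Hz line noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import EventMarker, Recording
from .montage import Montage, standard_montage_32

__all__ = [
    "ErpComponent",
    "ErpTemplate",
    "ArtifactConfig",
    "SubjectManifest",
    "CohortManifest",
    "default_template",
    "generate_subject",
    "inject_artifacts",
    "generate_cohort",
]

EPOCH_SPAN_MS = (-500.0, 1300.0)  # must contain every template latency


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian temporal component of the evoked response.

    ``scope`` is which trials receive it: ``gain``, ``loss``, ``both``, or
    ``difference`` (added to gain trials only, so the gain-loss difference
    equals the component). ``width_ms`` is the Gaussian SD; ``amplitude_uv``
    is the peak amplitude at FCz, scaled elsewhere by the topography.
    """

    scope: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.scope not in ("gain", "loss", "both", "difference"):
            raise ValueError(f"unknown component scope {self.scope!r}")
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")


@dataclass(frozen=True)
class ErpTemplate:
    """Evoked-response ground truth: temporal components x spatial gain.

    The topography is ``exp(-d²/2σ²)`` in angular distance ``d`` from FCz
    (σ default 0.7 rad), hence exactly 1 at FCz.
    """

    components: tuple[ErpComponent, ...]
    topography_sigma_rad: float = 0.7

    def applies(self, component: ErpComponent, condition: str) -> bool:
        if component.scope == "both":
            return True
        if component.scope == "difference":
            return condition == "gain"
        return component.scope == condition

    def waveform_at_fcz(self, times_ms: np.ndarray, condition: str) -> np.ndarray:
        """Noise-free FCz time course for one condition (or 'difference')."""
        times_ms = np.asarray(times_ms, dtype=float)
        out = np.zeros_like(times_ms)
        for comp in self.components:
            if condition == "difference":
                include = comp.scope == "difference"
            else:
                include = self.applies(comp, condition)
            if include:
                out += comp.amplitude_uv * np.exp(
                    -0.5 * ((times_ms - comp.latency_ms) / comp.width_ms) ** 2
                )
        return out

    def topography(self, montage: Montage) -> np.ndarray:
        """Per-channel spatial gain in [0, 1], equal to 1 at FCz.

        The mastoids (TP9/TP10) are forced to zero: the ground truth is
        defined in linked-mastoid reference space, so re-referencing leaves
        the injected components untouched and recovery can be checked
        against the template directly.
        """
        fcz = montage.positions[montage.index("FCz")]
        cosang = np.clip(montage.positions @ fcz, -1.0, 1.0)
        d = np.arccos(cosang)
        topo = np.exp(-0.5 * (d / self.topography_sigma_rad) ** 2)
        for lab in ("TP9", "TP10"):
            if lab in montage.channel_names:
                topo[montage.index(lab)] = 0.0
        return topo

    def difference_peak(self) -> tuple[float, float]:
        """(latency ms, FCz amplitude μV) of the difference component peak."""
        diffs = [c for c in self.components if c.scope == "difference"]
        if not diffs:
            raise ValueError("template has no difference-scope component")
        main = max(diffs, key=lambda c: abs(c.amplitude_uv))
        return main.latency_ms, main.amplitude_uv


def default_template() -> ErpTemplate:
    """Reward-positivity morphology: conditional peaks at 212/370 ms, a
    gain-specific difference component at 310 ms with 4.8 μV at FCz."""
    return ErpTemplate(
        components=(
            ErpComponent("both", 212.0, 30.0, 6.5),
            ErpComponent("both", 370.0, 30.0, 14.0),
            ErpComponent("difference", 310.0, 20.0, 4.8),
        )
    )


@dataclass(frozen=True)
class ArtifactConfig:
    """Rates and amplitudes of injectable artifacts (all >= 0)."""

    blink_rate_per_min: float = 2.0
    blink_amplitude_uv: float = 80.0
    n_flat_channels: int = 0
    flat_duration_s: float = 6.0
    transient_rate_per_min: float = 0.5
    transient_amplitude_uv: float = 150.0
    line_noise_amplitude_uv: float = 2.0
    line_noise_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "blink_rate_per_min", "blink_amplitude_uv", "n_flat_channels",
            "flat_duration_s", "transient_rate_per_min",
            "transient_amplitude_uv", "line_noise_amplitude_uv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SubjectManifest:
    subject_id: str
    seed: int
    component_latencies_ms: list[float]
    component_amplitudes_uv: list[float]
    component_scopes: list[str]
    artifact_log: list[dict] = field(default_factory=list)
    n_events: int = 0


@dataclass
class CohortManifest:
    master_seed: int
    n_subjects: int
    subjects: list[SubjectManifest] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    rms: float,
    corner_hz: float = 0.5,
    exponent: float = 1.0,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent, flat
    below ``corner_hz``, scaled to the requested per-channel RMS."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    n_fft = n_samples
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    shape = np.ones_like(freqs)
    above = freqs > corner_hz
    shape[above] = (corner_hz / freqs[above]) ** (exponent / 2.0)
    shape[0] = 0.0  # no DC
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=-1) * shape[None, :]
    pink = np.fft.irfft(spectrum, n=n_fft, axis=-1)
    current_rms = pink.std(axis=-1, keepdims=True)
    current_rms[current_rms == 0] = 1.0
    return pink * (rms / current_rms)


def generate_subject(
    template: ErpTemplate | None = None,
    artifact_config: ArtifactConfig | None = None,
    n_blocks: int = 6,
    trials_per_block: int = 20,
    fs: float = 500.0,
    seed: int = 0,
    noise_rms_uv: float = 10.0,
    amplitude_jitter: float = 0.2,
    montage: Montage | None = None,
    subject_id: str = "sub-01",
) -> tuple[Recording, SubjectManifest]:
    """Simulate one subject's continuous recording plus its manifest entry.

    Trials are laid out with inter-onset spacing of at least the epoch span
    so adjacent epochs never overlap; each trial is independently gain with
    probability 0.5 and its components receive multiplicative amplitude
    jitter (SD ``amplitude_jitter`` of the peak).
    """
    template = template or default_template()
    artifact_config = artifact_config or ArtifactConfig()
    montage = montage or standard_montage_32()
    rng = np.random.default_rng(seed)

    for comp in template.components:
        if not EPOCH_SPAN_MS[0] < comp.latency_ms < EPOCH_SPAN_MS[1]:
            raise ValueError(
                f"component latency {comp.latency_ms} ms outside the epoch "
                f"span {EPOCH_SPAN_MS}"
            )

    n_trials = n_blocks * trials_per_block
    span_s = (EPOCH_SPAN_MS[1] - EPOCH_SPAN_MS[0]) / 1000.0
    gaps_s = span_s + 0.2 + rng.uniform(0.0, 0.4, size=n_trials)
    onsets_s = 5.0 + np.cumsum(gaps_s) - gaps_s[0]
    n_samples = int(round((onsets_s[-1] + span_s + 5.0) * fs))
    onset_samples = np.round(onsets_s * fs).astype(int)

    conditions = np.where(rng.random(n_trials) < 0.5, "gain", "loss")
    topo = template.topography(montage)

    data = _pink_noise(rng, montage.n_channels, n_samples, fs, noise_rms_uv)

    # support of each component: +/- 7 SD keeps the truncation error below
    # float32 resolution of the stored voltages
    for onset, cond in zip(onset_samples, conditions):
        for comp in template.components:
            if not template.applies(comp, str(cond)):
                continue
            amp = comp.amplitude_uv * (1.0 + amplitude_jitter * rng.standard_normal())
            half = int(math.ceil(7 * comp.width_ms * fs / 1000.0))
            center = onset + int(round(comp.latency_ms * fs / 1000.0))
            lo, hi = max(center - half, 0), min(center + half + 1, n_samples)
            if lo >= hi:
                continue
            t_ms = (np.arange(lo, hi) - onset) * 1000.0 / fs
            bump = amp * np.exp(
                -0.5 * ((t_ms - comp.latency_ms) / comp.width_ms) ** 2
            )
            data[:, lo:hi] += topo[:, None] * bump[None, :]

    events = [
        EventMarker(int(s), str(c)) for s, c in zip(onset_samples, conditions)
    ]
    recording = Recording(
        data=data, fs=fs, events=events, montage=montage, subject_id=subject_id
    )

    artifact_seed = int(rng.integers(0, 2**31 - 1))
    recording, artifact_log = inject_artifacts(
        recording, artifact_config, seed=artifact_seed
    )

    manifest = SubjectManifest(
        subject_id=subject_id,
        seed=int(seed),
        component_latencies_ms=[c.latency_ms for c in template.components],
        component_amplitudes_uv=[c.amplitude_uv for c in template.components],
        component_scopes=[c.scope for c in template.components],
        artifact_log=artifact_log,
        n_events=len(events),
    )
    return recording, manifest


def inject_artifacts(
    recording: Recording, config: ArtifactConfig, seed: int = 0
) -> tuple[Recording, list[dict]]:
    """Add blinks, transients, flat stretches and line noise to a recording.

    Returns a new recording and a log with one entry per injection (kind,
    channels, start sample, duration, amplitude). All rates zero → the data
    pass through bit-identical with an empty log.
    """
    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    fs = recording.fs
    n_ch, n_samp = data.shape
    duration_min = n_samp / fs / 60.0
    log: list[dict] = []
    montage = recording.montage

    # frontal weighting for blinks: fall-off from the frontal pole midpoint
    frontal_ref = np.array([0.0, math.sin(math.radians(90.0)), 0.0])
    cosang = np.clip(montage.positions @ frontal_ref, -1.0, 1.0)
    blink_topo = np.exp(-0.5 * (np.arccos(cosang) / 0.6) ** 2)

    if config.blink_rate_per_min > 0 and config.blink_amplitude_uv > 0:
        n_blinks = rng.poisson(config.blink_rate_per_min * duration_min)
        width = int(0.15 * fs)  # 300 ms biphasic blink
        t = np.arange(-width, width + 1) / fs
        shape = np.exp(-0.5 * (t / 0.05) ** 2) - 0.3 * np.exp(
            -0.5 * ((t - 0.12) / 0.06) ** 2
        )
        for _ in range(n_blinks):
            center = int(rng.integers(width, n_samp - width - 1))
            seg = slice(center - width, center + width + 1)
            data[:, seg] += (
                config.blink_amplitude_uv * blink_topo[:, None] * shape[None, :]
            )
            log.append(
                {
                    "kind": "blink",
                    "channels": list(montage.channel_names),
                    "start_sample": center - width,
                    "duration_samples": 2 * width + 1,
                    "amplitude_uv": config.blink_amplitude_uv,
                }
            )

    if config.transient_rate_per_min > 0 and config.transient_amplitude_uv > 0:
        n_trans = rng.poisson(config.transient_rate_per_min * duration_min)
        width = int(0.1 * fs)  # 100 ms broadband burst
        for _ in range(n_trans):
            ch = int(rng.integers(0, n_ch))
            start = int(rng.integers(0, n_samp - width))
            burst = rng.standard_normal(width)
            burst *= config.transient_amplitude_uv / np.abs(burst).max()
            data[ch, start : start + width] += burst
            log.append(
                {
                    "kind": "transient",
                    "channels": [montage.channel_names[ch]],
                    "start_sample": start,
                    "duration_samples": width,
                    "amplitude_uv": config.transient_amplitude_uv,
                }
            )

    if config.n_flat_channels > 0:
        flat_len = int(config.flat_duration_s * fs)
        if flat_len >= n_samp:
            flat_len = n_samp - 1
        chans = rng.choice(n_ch, size=min(config.n_flat_channels, n_ch), replace=False)
        for ch in chans:
            start = int(rng.integers(0, n_samp - flat_len))
            data[ch, start : start + flat_len] = data[ch, start]
            log.append(
                {
                    "kind": "flat",
                    "channels": [montage.channel_names[int(ch)]],
                    "start_sample": start,
                    "duration_samples": flat_len,
                    "amplitude_uv": 0.0,
                }
            )

    if config.line_noise_amplitude_uv > 0:
        t = np.arange(n_samp) / fs
        phase = rng.uniform(0, 2 * math.pi)
        data += config.line_noise_amplitude_uv * np.sin(
            2 * math.pi * config.line_noise_hz * t + phase
        )[None, :]
        log.append(
            {
                "kind": "line_noise",
                "channels": list(montage.channel_names),
                "start_sample": 0,
                "duration_samples": n_samp,
                "amplitude_uv": config.line_noise_amplitude_uv,
            }
        )

    out = recording.copy_with(data=data)
    return out, log


def generate_cohort(
    n_subjects: int,
    template: ErpTemplate | None = None,
    artifact_config: ArtifactConfig | None = None,
    master_seed: int = 0,
    **subject_kwargs,
) -> tuple[list[Recording], CohortManifest]:
    """Simulate a cohort; per-subject seeds derive from the master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    manifest = CohortManifest(master_seed=int(master_seed), n_subjects=n_subjects)
    recordings: list[Recording] = []
    for i, seed in enumerate(seeds):
        rec, sub = generate_subject(
            template=template,
            artifact_config=artifact_config,
            seed=int(seed),
            subject_id=f"sub-{i + 1:02d}",
            **subject_kwargs,
        )
        recordings.append(rec)
        manifest.subjects.append(sub)
    return recordings, manifest
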