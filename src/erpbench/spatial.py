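"""Sensor-space operations: re-referencing, flat channels, interpolation.

Two channel-repair methods are provided, matching the two families used by
the emulated tools:

* spherical-spline interpolation (Perrin-type): a smoothing spline on the
  unit sphere built from a truncated Legendre series with stiffness ``m``
  (default 4) and a small ridge term for conditioning;
* inverse-distance weighting over the montage neighborhood: the repaired
  channel is the weighted mean of its good neighbors, with weight
  ``1 / angular_distance**power``.

Both are linear operators in the data, so repairing an average equals
averaging repaired trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .core import Recording
from .montage import Montage

__all__ = [
    "InterpolationModel",
    "rereference_linked_mastoids",
    "rereference_average",
    "detect_flat_channels",
    "spherical_spline_interpolate",
    "inverse_distance_interpolate",
    "interpolate",
]


@dataclass(frozen=True)
class InterpolationModel:
    """Parameters of the two channel-repair methods."""

    method: str = "spherical_spline"  # or "inverse_distance"
    m: int = 4  # spline stiffness
    n_legendre_terms: int = 50
    ridge: float = 1e-5
    idw_max_angle: float = 0.6  # radians
    idw_power: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("spherical_spline", "inverse_distance"):
            raise ValueError(f"unknown interpolation method {self.method!r}")
        if self.m < 2:
            raise ValueError("spline stiffness m must be >= 2")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


def rereference_linked_mastoids(recording: Recording) -> Recording:
    """Subtract the instantaneous mean of TP9 and TP10 from every channel."""
    names = recording.montage.channel_names
    for lab in ("TP9", "TP10"):
        if lab not in names:
            raise KeyError(f"mastoid channel {lab} missing; cannot re-reference")
    i9 = recording.montage.index("TP9")
    i10 = recording.montage.index("TP10")
    ref = 0.5 * (recording.data[i9] + recording.data[i10])
    return recording.copy_with(data=recording.data - ref[None, :])


def rereference_average(recording: Recording) -> Recording:
    """Common-average reference (config alternative to linked mastoids)."""
    return recording.copy_with(
        data=recording.data - recording.data.mean(axis=0, keepdims=True)
    )


def detect_flat_channels(
    recording: Recording, min_duration_s: float = 5.0, eps: float = 1e-8
) -> list[str]:
    """Channels containing a flat run strictly longer than ``min_duration_s``.

    A run is a stretch of consecutive sample-to-sample differences all below
    ``eps`` in magnitude (absolute, μV scale); its duration is the time
    spanned by those differences. The comparison with the threshold is
    strict.
    """
    if min_duration_s >= recording.duration_s:
        raise ValueError("min_duration_s must be shorter than the recording")
    flat: list[str] = []
    min_diffs = min_duration_s * recording.fs  # run length in diff counts
    for ch, name in enumerate(recording.montage.channel_names):
        is_flat = np.abs(np.diff(recording.data[ch])) < eps
        if not is_flat.any():
            continue
        # longest run of True values
        padded = np.concatenate([[False], is_flat, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_lengths = edges[1::2] - edges[0::2]
        if run_lengths.size and run_lengths.max() > min_diffs:
            flat.append(name)
    return flat


def _spline_g(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Perrin basis function g(cos θ) as a truncated Legendre series."""
    cosang = np.clip(cosang, -1.0, 1.0)
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        coef = (2 * n + 1) / (n**m * (n + 1) ** m)
        g += coef * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def spherical_spline_interpolate(
    montage: Montage,
    data: np.ndarray,
    bad_channels: list[str],
    model: InterpolationModel | None = None,
) -> np.ndarray:
    """Replace bad channels by their spherical-spline estimate.

    ``data`` is ``(channels, samples)`` (or ``(..., channels, samples)``);
    good channels pass through untouched. The spline coefficients are solved
    over the good channels with a ridge term on the Gram matrix and a
    constant (mean-field) term, then evaluated at the bad positions.
    """
    model = model or InterpolationModel()
    if not bad_channels:
        return np.array(data, dtype=float, copy=True)
    bad_idx = np.array([montage.index(b) for b in bad_channels])
    good_idx = np.array(
        [i for i in range(montage.n_channels) if i not in set(bad_idx)]
    )
    if good_idx.size < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")

    pos = montage.positions
    cos_gg = pos[good_idx] @ pos[good_idx].T
    cos_bg = pos[bad_idx] @ pos[good_idx].T
    G = _spline_g(cos_gg, model.m, model.n_legendre_terms)
    Gb = _spline_g(cos_bg, model.m, model.n_legendre_terms)

    ng = good_idx.size
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + model.ridge * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "spherical spline system singular even after ridge regularization"
        ) from exc

    out = np.array(data, dtype=float, copy=True)
    v = out[..., good_idx, :]
    rhs = np.concatenate([v, np.zeros_like(v[..., :1, :])], axis=-2)
    coefs = np.einsum("ij,...js->...is", A_inv, rhs)
    c, c0 = coefs[..., :ng, :], coefs[..., ng:, :]
    out[..., bad_idx, :] = np.einsum("bg,...gs->...bs", Gb, c) + c0
    return out


def inverse_distance_interpolate(
    montage: Montage,
    data: np.ndarray,
    bad_channels: list[str],
    model: InterpolationModel | None = None,
) -> np.ndarray:
    """Replace bad channels by the inverse-distance mean of good neighbors.

    Neighbors are good channels within ``idw_max_angle`` radians; weights
    are ``1/d**idw_power`` with ``d`` the great-circle angular distance.
    """
    model = model or InterpolationModel(method="inverse_distance")
    if not bad_channels:
        return np.array(data, dtype=float, copy=True)
    bad_set = {montage.index(b) for b in bad_channels}
    dist = montage.angular_distances()
    out = np.array(data, dtype=float, copy=True)
    new_rows = {}
    for b in bad_set:
        neighbors = [
            j
            for j in range(montage.n_channels)
            if j != b and j not in bad_set and dist[b, j] < model.idw_max_angle
        ]
        if not neighbors:
            raise ValueError(
                f"channel {montage.channel_names[b]} has no good neighbor "
                f"within {model.idw_max_angle} rad"
            )
        w = 1.0 / dist[b, neighbors] ** model.idw_power
        w = w / w.sum()
        new_rows[b] = np.einsum("g,...gs->...s", w, out[..., neighbors, :])
    for b, row in new_rows.items():
        out[..., b, :] = row
    return out


def interpolate(
    montage: Montage,
    data: np.ndarray,
    bad_channels: list[str],
    model: InterpolationModel,
) -> np.ndarray:
    """Dispatch to the repair method named in ``model``."""
    if model.method == "spherical_spline":
        return spherical_spline_interpolate(montage, data, bad_channels, model)
    return inverse_distance_interpolate(montage, data, bad_channels, model)
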