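"""Minimal BrainVision (.vhdr/.vmrk/.eeg) reader and writer.

The dialect written here is the simplest loss-free one: binary IEEE float32,
multiplexed channel layout, resolution 1.0 μV per channel, and stimulus
markers whose 1-based positions index samples. Feedback conditions map to
marker codes through a configurable table (default ``"S  1"`` = gain,
``"S  2"`` = loss). The reader accepts any file in this dialect (including
files written by other software as long as they use float32 multiplexed
binary data) and scales voltages by the per-channel resolution from the
header.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import EventMarker, Recording
from .montage import Montage, standard_montage_32

__all__ = ["read_brainvision", "write_brainvision", "DEFAULT_MARKER_MAP"]

logger = logging.getLogger(__name__)

DEFAULT_MARKER_MAP: dict[str, str] = {"S  1": "gain", "S  2": "loss"}


def write_brainvision(recording: Recording, base_path: str | Path) -> tuple[Path, Path, Path]:
    """Write a recording as a BrainVision triplet; returns the three paths.

    ``base_path`` is the path without extension; ``.vhdr``, ``.vmrk`` and
    ``.eeg`` siblings are created. Data are stored as float32 μV
    (resolution 1.0), so round-tripping is exact to float32 precision.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    stem = base.name

    sampling_interval_us = 1e6 / recording.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(recording.montage.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    inv_map = {"gain": "S  1", "loss": "S  2"}
    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, ev in enumerate(recording.events, start=2):
        code = inv_map[ev.condition]
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,{code},{ev.sample_index + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
            continue
        if current is None or "=" not in line:
            continue
        key, _, value = line.partition("=")
        current[key.strip()] = value.strip()
    return sections


def read_brainvision(
    header_path: str | Path,
    montage: Montage | None = None,
    marker_map: Mapping[str, str] = DEFAULT_MARKER_MAP,
) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording`.

    Markers with codes absent from ``marker_map`` are dropped with a logged
    warning reporting the count. If no montage is given, channel positions
    are taken from the standard 32-channel montage; the header's labels must
    then all be known there.
    """
    vhdr = Path(header_path)
    sections = _parse_ini(vhdr.read_text(encoding="utf-8", errors="replace"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    chsec = sections.get("Channel Infos", {})

    for key in ("DataFile", "NumberOfChannels", "SamplingInterval"):
        if key not in common:
            raise ValueError(f"header missing required field {key}")
    fmt = binary.get("BinaryFormat", "")
    if fmt != "IEEE_FLOAT_32":
        raise ValueError(f"unsupported BinaryFormat {fmt!r} (only IEEE_FLOAT_32)")
    orientation = common.get("DataOrientation", "MULTIPLEXED")
    if orientation != "MULTIPLEXED":
        raise ValueError(f"unsupported DataOrientation {orientation!r}")

    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    names: list[str] = []
    resolutions: list[float] = []
    for i in range(1, n_channels + 1):
        entry = chsec.get(f"Ch{i}")
        if entry is None:
            raise ValueError(f"header missing Channel Infos entry Ch{i}")
        parts = entry.split(",")
        names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    eeg_path = vhdr.parent / common["DataFile"]
    if not eeg_path.exists():
        raise FileNotFoundError(f"data file {eeg_path} referenced by header not found")
    raw = np.fromfile(eeg_path, dtype="<f4")
    if raw.size % n_channels:
        raise ValueError(
            f"data file length {raw.size} not a multiple of {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(float)
    data *= np.asarray(resolutions)[:, None]

    events: list[EventMarker] = []
    dropped = 0
    marker_file = common.get("MarkerFile")
    if marker_file:
        vmrk_path = vhdr.parent / marker_file
        if not vmrk_path.exists():
            raise FileNotFoundError(f"marker file {vmrk_path} referenced by header not found")
        msec = _parse_ini(vmrk_path.read_text(encoding="utf-8", errors="replace"))
        for key, value in msec.get("Marker Infos", {}).items():
            parts = value.split(",")
            if len(parts) < 3 or parts[0] != "Stimulus":
                continue
            code = parts[1]
            pos = int(parts[2]) - 1
            if code in marker_map:
                events.append(EventMarker(pos, marker_map[code]))  # type: ignore[arg-type]
            else:
                dropped += 1
    if dropped:
        logger.warning("dropped %d markers with codes not in marker map", dropped)
    events.sort(key=lambda e: e.sample_index)

    if montage is None:
        montage = standard_montage_32().subset(names)
    return Recording(
        data=data, fs=fs, events=events, montage=montage, subject_id=vhdr.stem
    )
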