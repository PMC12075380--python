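"""Reading and writing recordings and tables.

Recordings are written as BrainVision triplets (.vhdr/.vmrk/.eeg,
multiplexed INT_16 at 0.1 uV resolution, trial markers as Stimulus
codes) and as plain EDF (16-bit, 1-s data records; EDF carries no event
markers, so events are round-tripped only through BrainVision). Reading
both formats is delegated to mne.

Behavioral logs use the CSV dialect
``subject,session,condition,trial,truth,response,rt_ms``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_edf",
    "read_edf",
    "write_behavior_csv",
    "read_behavior_csv",
]

_BV_RESOLUTION_UV = 0.1


def write_brainvision(recording: Recording, stem: str | Path) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet; returns the .vhdr path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    name = stem.name
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    scaled = np.round(recording.data / _BV_RESOLUTION_UV)
    if np.abs(scaled).max(initial=0) > 32767:
        raise ValueError("amplitude exceeds INT_16 range at 0.1 uV resolution")
    scaled.astype("<i2").T.tofile(eeg)  # multiplexed: sample-major

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={1e6 / recording.sfreq:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(recording.ch_names, start=1):
        lines.append(f"Ch{i}={ch},,{_BV_RESOLUTION_UV:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, code) in enumerate(recording.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{code},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Load a BrainVision triplet, restoring uV data and Stimulus events."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if "Stimulus" in desc:
            code = desc.split("/")[-1].strip()
            events.append((int(round(onset * raw.info["sfreq"])), code))
    return Recording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=events,
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a minimal 16-bit EDF file (1-s data records, uV units).

    The final partial second, if any, is zero-padded to a whole record.
    Requires an integer sampling rate. Event markers are not stored in
    this format; use BrainVision for marker round-trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = recording.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    ns = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))

    padded = np.zeros((ns, n_records * fs))
    padded[:, : recording.n_samples] = recording.data
    # integer physical bounds so the printed header matches the scaling
    phys_max = float(np.ceil(max(float(np.abs(padded).max()), 1.0)))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field("1", 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(ch, 16) for ch in recording.ch_names),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(int(phys_min), 8) for _ in range(ns)),
            b"".join(_edf_field(int(phys_max), 8) for _ in range(ns)),
            b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
            b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(fs, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())  # signal-major within each record
    return path


def read_edf(path: str | Path) -> Recording:
    """Load an EDF file; data in uV, no events."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        events=[],
    )


def write_behavior_csv(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["subject", "session", "condition", "trial", "truth", "response", "rt_ms"]
    log[cols].to_csv(path, index=False)
    return path


def read_behavior_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
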