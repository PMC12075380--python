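"""Core in-memory containers: continuous recordings and trial epochs.

Amplitudes are microvolts throughout. Epochs span -1,000 ... +2,000 ms
around the cue-arrow onset; the three task phase windows (attention,
encoding, retention) are expressed as sample ranges relative to the
epoch start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Phase windows in seconds relative to arrow onset (= epoch time 0).
#: On the trial clock, which starts 1 s before the arrow, these are the
#: 1,000-1,500, 1,500-2,000 and 2,000-3,000 ms intervals.
PHASE_WINDOWS_S: dict[str, tuple[float, float]] = {
    "attention": (0.0, 0.5),
    "encoding": (0.5, 1.0),
    "retention": (1.0, 2.0),
}

EPOCH_TMIN_S = -1.0
EPOCH_TMAX_S = 2.0

CONDITIONS = ("2T", "4T")
CONDITION_LOAD = {"2T": 2, "4T": 4}


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels, one per data row.
    events : list of (int, str)
        ``(sample_index, code)`` event markers, sorted by sample index.
        Codes are ``"arrow_2T"`` / ``"arrow_4T"`` for trial onsets.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel names"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        self.events = sorted(self.events, key=lambda e: e[0])
        for s, _ in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass
class EpochSet:
    """Trial-aligned epochs with condition labels and phase windows.

    ``data`` has shape (n_trials, n_channels, n_times) where n_times is
    3 s x sfreq. ``kept`` is False for trials rejected by the +/-100 uV
    rule; rejected trials stay in ``data`` so indices remain stable.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    condition: np.ndarray  # (n_trials,) of "2T"/"4T"
    kept: np.ndarray  # (n_trials,) bool
    tmin: float = EPOCH_TMIN_S

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        n_expected = int(round((EPOCH_TMAX_S - EPOCH_TMIN_S) * self.sfreq))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != 3 s x sfreq = {n_expected}"
            )
        if len(self.condition) != self.data.shape[0] or len(self.kept) != self.data.shape[0]:
            raise ValueError("condition/kept length mismatch")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count does not match names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def phase_window_samples(self) -> dict[str, tuple[int, int]]:
        """Phase windows as half-open sample ranges within the epoch."""
        out = {}
        for name, (t0, t1) in PHASE_WINDOWS_S.items():
            a = int(round((t0 - self.tmin) * self.sfreq))
            b = int(round((t1 - self.tmin) * self.sfreq))
            out[name] = (a, b)
        return out

    def channel_index(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        idx = []
        for n in names:
            try:
                idx.append(self.ch_names.index(n))
            except ValueError:
                raise KeyError(f"electrode {n!r} not present in epochs") from None
        return np.asarray(idx, dtype=int)

    def kept_by_condition(self, condition: str) -> np.ndarray:
        """Indices of kept trials for one condition."""
        return np.flatnonzero((self.condition == condition) & self.kept)
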