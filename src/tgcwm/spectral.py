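"""FFT band power per task phase, frequency band and scalp region.

Power in a band is the sum of one-sided squared spectral magnitudes over
the band's frequency bins, normalized so that the sum over ALL bins
equals the mean-square amplitude of the analysis window (Parseval).
Phase windows (0.5-1 s) are shorter than the 2-s analysis segment the
0.5 Hz grid requires, so they are zero-padded to 2 s; zero-padding does
not change the total power under this normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .core import EpochSet
from .montage import RegionMap

__all__ = ["BandScheme", "DEFAULT_BANDS", "spectrum", "band_power", "aggregate"]

#: half-open [low, high) band edges in Hz — a partition of 0.5-80 Hz
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 80.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands with half-open [low, high) edges."""

    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in DEFAULT_BANDS.items()
    )

    def __post_init__(self) -> None:
        prev_hi = None
        for name, lo, hi in self.bands:
            if not (0 < lo < hi):
                raise ValueError(f"band {name!r}: edges must be positive and increasing")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError(f"band {name!r} overlaps the previous band")
            prev_hi = hi

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "BandScheme":
        return cls(tuple((k, lo, hi) for k, (lo, hi) in d.items()))

    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


def _taper(x: np.ndarray, kind: str | None) -> np.ndarray:
    """Apply a power-normalized taper along the last axis."""
    if kind is None or kind == "boxcar":
        return x
    w = get_window(kind, x.shape[-1])
    w = w / np.sqrt(np.mean(w**2))  # preserve mean-square power
    return x * w


def spectrum(
    segment: np.ndarray,
    sampling_rate: float,
    analysis_s: float = 2.0,
    taper: str | None = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a segment on a fixed frequency grid.

    The segment is tapered, then zero-padded (or truncated) to
    ``analysis_s`` seconds, giving a grid step of 1/analysis_s Hz
    (0.5 Hz for the default 2-s window). Returned powers sum to the
    mean-square of the tapered segment, so Parseval holds exactly.

    Works on any array whose last axis is time; returns (freqs, power)
    with power matching the input's leading shape.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] == 0:
        raise ValueError("empty segment")
    n_fft = int(round(analysis_s * sampling_rate))
    x = _taper(segment, taper)
    length = min(x.shape[-1], n_fft)  # effective (non-padded) length
    if x.shape[-1] > n_fft:
        x = x[..., :n_fft]
    F = np.fft.rfft(x, n=n_fft, axis=-1)
    power = np.abs(F) ** 2 / (n_fft * length)
    # fold the negative frequencies into the positive bins
    power[..., 1:] *= 2.0
    if n_fft % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    return freqs, power


def band_power(
    freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Sum of spectral power over bins with low <= f < high (uV^2)."""
    lo, hi = band
    if lo >= freqs[-1]:
        raise ValueError(f"band {band} outside the spectrum range")
    mask = (freqs >= lo) & (freqs < hi)
    return power[..., mask].sum(axis=-1)


def aggregate(
    epochs: EpochSet,
    scheme: BandScheme | None = None,
    regions: RegionMap | None = None,
    subject: str = "S01",
    session: str = "pre",
    taper: str | None = "hann",
) -> pd.DataFrame:
    """Per-cell mean band power over kept epochs and region electrodes.

    Returns a tidy table with one row per (subject, session, condition,
    phase, region, band): conditions x 3 phases x len(regions) x
    len(bands) rows per session.
    """
    scheme = scheme or BandScheme()
    regions = regions or RegionMap(montage=epochs.ch_names)
    windows = epochs.phase_window_samples()
    rows = []
    for cond in sorted(set(epochs.condition)):
        idx = epochs.kept_by_condition(cond)
        if idx.size == 0:
            raise ValueError(f"no kept epochs for condition {cond!r}")
        for phase, (a, b) in windows.items():
            seg = epochs.data[idx][:, :, a:b]  # (trials, channels, time)
            freqs, power = spectrum(seg, epochs.sfreq, taper=taper)
            for region, electrodes in regions.items():
                ch_idx = epochs.channel_index(electrodes)
                region_power = power[:, ch_idx, :].mean(axis=(0, 1))
                for band in scheme.names():
                    rows.append(
                        dict(
                            subject=subject,
                            session=session,
                            condition=cond,
                            phase=phase,
                            region=region,
                            band=band,
                            power=float(
                                band_power(freqs, region_power, scheme.edges(band))
                            ),
                        )
                    )
    return pd.DataFrame(rows)
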