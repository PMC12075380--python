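"""Theta-gamma cross-frequency coupling: phase-amplitude and phase-phase.

Phase-amplitude coupling is quantified with the modulation index (MI):
theta phase (Hilbert) is divided into N = 18 bins of 20 degrees, the mean
gamma amplitude per bin is normalized to a distribution P_i, and

    MI = (1 / log N) * sum_i P_i * log(P_i / (1/N)),

the Kullback-Leibler divergence of P from uniform, normalized to [0, 1]:
0 for a flat amplitude distribution (no coupling), 1 when all amplitude
falls in a single phase bin.

Phase-phase coupling is the n:m phase-locking value
|mean_t exp(i (n phi_fast - m phi_slow))|, default 1:6 for a ~6 Hz theta
against ~36 Hz gamma. The n:m estimator choice is a package convention
(recorded in output metadata), not a field standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import EpochSet
from .montage import RegionMap

__all__ = [
    "AnalyticSignal",
    "N_BINS",
    "phase_bin_edges",
    "analytic",
    "phase_amplitude_distribution",
    "mi_from_distribution",
    "modulation_index",
    "phase_phase_coupling",
    "couple_regions",
]

N_BINS = 18  # 20-degree phase bins

THETA_BAND = (4.0, 8.0)
GAMMA_SUBBANDS = {"low_gamma": (30.0, 60.0), "high_gamma": (60.0, 80.0)}

#: windows shorter than 2 theta cycles at the 4 Hz band edge are flagged
MIN_CONFIDENT_S = 0.5


@dataclass
class AnalyticSignal:
    """Instantaneous phase in [-pi, pi) and non-negative amplitude
    envelope of a band-limited series."""

    phase: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase/amplitude length mismatch")
        if (self.amplitude < 0).any():
            raise ValueError("amplitude must be non-negative")

    def __getitem__(self, sl) -> "AnalyticSignal":
        return AnalyticSignal(self.phase[sl], self.amplitude[sl])


def phase_bin_edges(n_bins: int = N_BINS) -> np.ndarray:
    """Half-open bin edges from -pi to pi."""
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def analytic(
    series: np.ndarray, band: tuple[float, float], sampling_rate: float
) -> AnalyticSignal:
    """Band-pass (4th-order Butterworth, zero-phase) + Hilbert transform."""
    series = np.asarray(series, dtype=float)
    lo, hi = band
    if hi >= sampling_rate / 2:
        raise ValueError(f"band {band} exceeds Nyquist at fs={sampling_rate}")
    min_len = 3.0 * sampling_rate / lo
    if series.shape[-1] < min_len:
        raise ValueError(
            f"series too short for band {band}: need >= 3 cycles of {lo} Hz "
            f"({int(np.ceil(min_len))} samples at fs={sampling_rate})"
        )
    sos = butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, series, axis=-1)
    z = hilbert(filtered, axis=-1)
    phase = np.angle(z)  # [-pi, pi)
    return AnalyticSignal(phase=phase, amplitude=np.abs(z))


def phase_amplitude_distribution(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_BINS
) -> np.ndarray:
    """Normalized mean-amplitude-per-phase-bin distribution P_i.

    Empty bins get mass 0 (the 0*log 0 := 0 limit convention applies in
    the MI). Normalization is mean amplitude per bin divided by the sum
    of the bin means.
    """
    phase = np.ravel(phase)
    amplitude = np.ravel(amplitude)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    total = amplitude.sum()
    if total <= 0:
        raise ValueError("modulation index undefined for all-zero amplitude")
    # map [-pi, pi] onto bins 0..n_bins-1 (pi folds into the last bin)
    idx = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return means / means.sum()


def mi_from_distribution(p: np.ndarray) -> float:
    """MI of a phase-bin mass distribution: KL divergence from uniform
    over len(p) bins, normalized by log(len(p)). Zero-mass bins
    contribute 0 (the 0 log 0 limit)."""
    p = np.asarray(p, dtype=float)
    n_bins = p.size
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a probability distribution")
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    mi = kl / np.log(n_bins)
    return float(min(max(mi, 0.0), 1.0))


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_BINS
) -> float:
    """Normalized KL divergence of the phase-binned amplitude
    distribution from uniform; in [0, 1]."""
    return mi_from_distribution(
        phase_amplitude_distribution(phase, amplitude, n_bins)
    )


def phase_phase_coupling(
    phase_slow: np.ndarray, phase_fast: np.ndarray, n: int = 1, m: int = 6
) -> float:
    """n:m phase-locking value |mean exp(i (n phi_fast - m phi_slow))|."""
    phase_slow = np.ravel(phase_slow)
    phase_fast = np.ravel(phase_fast)
    if phase_slow.size == 0:
        raise ValueError("zero-length phase input")
    if phase_slow.shape != phase_fast.shape:
        raise ValueError("phase arrays must have equal length")
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive integers")
    return float(np.abs(np.mean(np.exp(1j * (n * phase_fast - m * phase_slow)))))


def couple_regions(
    epochs: EpochSet,
    regions: RegionMap,
    pairs: list[tuple[str, str]],
    subject: str = "S01",
    session: str = "pre",
    theta_band: tuple[float, float] = THETA_BAND,
    gamma_bands: dict[str, tuple[float, float]] | None = None,
    nm: tuple[int, int] = (1, 6),
) -> pd.DataFrame:
    """MI and PPC for (phase-region, amplitude-region) pairs.

    Per epoch, theta phase comes from the phase-region's electrode-
    averaged signal and gamma amplitude/phase from the amplitude-region's
    electrode-averaged signal, each band-passed and Hilbert-transformed
    over the full 3-s epoch (avoiding edge effects inside windows), then
    sliced into the three phase windows. MI and PPC are computed per
    epoch and averaged over kept epochs.

    Returns a tidy table: 3 windows x len(gamma_bands) x 2 measures rows
    per (condition, pair), with a low_confidence flag for windows shorter
    than two 4-Hz theta cycles.
    """
    gamma_bands = gamma_bands or GAMMA_SUBBANDS
    windows = epochs.phase_window_samples()
    n, m = nm
    rows = []
    for phase_region, amp_region in pairs:
        ph_idx = epochs.channel_index(regions[phase_region])
        amp_idx = epochs.channel_index(regions[amp_region])
        for cond in sorted(set(epochs.condition)):
            trials = epochs.kept_by_condition(cond)
            if trials.size == 0:
                raise ValueError(f"no kept epochs for condition {cond!r}")
            phase_sig = epochs.data[trials][:, ph_idx, :].mean(axis=1)
            amp_sig = epochs.data[trials][:, amp_idx, :].mean(axis=1)
            theta = analytic(phase_sig, theta_band, epochs.sfreq)
            for gname, gband in gamma_bands.items():
                gamma = analytic(amp_sig, gband, epochs.sfreq)
                for wname, (a, b) in windows.items():
                    low_conf = (b - a) / epochs.sfreq < MIN_CONFIDENT_S
                    mi_vals = [
                        modulation_index(
                            theta.phase[t, a:b], gamma.amplitude[t, a:b]
                        )
                        for t in range(len(trials))
                    ]
                    ppc_vals = [
                        phase_phase_coupling(
                            theta.phase[t, a:b], gamma.phase[t, a:b], n=n, m=m
                        )
                        for t in range(len(trials))
                    ]
                    base = dict(
                        subject=subject,
                        session=session,
                        condition=cond,
                        phase=wname,
                        phase_region=phase_region,
                        amp_region=amp_region,
                        theta_band=f"{theta_band[0]:g}-{theta_band[1]:g}",
                        gamma_band=gname,
                        nm=f"{n}:{m}",
                        low_confidence=low_conf,
                        n_epochs=int(trials.size),
                    )
                    rows.append(
                        dict(base, measure="PAC_MI", value=float(np.mean(mi_vals)))
                    )
                    rows.append(
                        dict(base, measure="PPC", value=float(np.mean(ppc_vals)))
                    )
    return pd.DataFrame(rows)
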