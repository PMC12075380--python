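"""Continuous-EEG cleaning and epoching.

Fixed pipeline order: 2-s segment rejection (5x mean RMS rule) ->
zero-phase band-pass 0.5-95 Hz + notches at 50/100 Hz -> optional
ICA-based artifact-component removal -> epoching at -1,000...+2,000 ms
around arrow markers with a +/-100 uV amplitude rejection.

"Segment intensity" is the RMS over all channels and samples of a 2-s
segment; a segment is removed when its RMS is strictly greater than
5x the mean segment RMS. The +/-100 uV check runs after filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import EPOCH_TMAX_S, EPOCH_TMIN_S, Recording, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "reject_segments",
    "filter_chain",
    "remove_artifact_components",
    "make_epochs",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    bandpass_hz: tuple[float, float] = (0.5, 95.0)
    notch_hz: tuple[float, ...] = (50.0, 100.0)
    seg_len_s: float = 2.0
    seg_factor: float = 5.0
    epoch_ms: tuple[float, float] = (-1000.0, 2000.0)
    reject_uv: float = 100.0
    ica: bool = False
    provenance: list[str] = field(default_factory=list)


def reject_segments(
    recording: Recording,
    segment_s: float = 2.0,
    factor: float = 5.0,
) -> tuple[Recording, pd.DataFrame]:
    """Excise high-intensity segments from the continuous record.

    Returns the spliced recording and a per-segment log with columns
    (segment_index, start_s, rms, threshold, removed). Events falling
    inside removed segments are dropped; surviving events are re-indexed
    to the spliced timeline. A trailing partial segment is never scanned.
    """
    fs = recording.sfreq
    seg_len = int(round(segment_s * fs))
    n_segments = recording.n_samples // seg_len
    if n_segments < 1:
        raise ValueError("recording shorter than one segment")

    segs = recording.data[:, : n_segments * seg_len].reshape(
        recording.n_channels, n_segments, seg_len
    )
    rms = np.sqrt(np.mean(segs**2, axis=(0, 2)))
    threshold = factor * rms.mean()
    removed = rms > threshold  # strict: exactly 5x is retained

    log = pd.DataFrame(
        {
            "segment_index": np.arange(n_segments),
            "start_s": np.arange(n_segments) * segment_s,
            "rms": rms,
            "threshold": threshold,
            "removed": removed,
        }
    )
    if removed.all():
        raise ValueError("all segments removed by the intensity rule")
    if not removed.any():
        return recording, log

    keep_mask = np.ones(recording.n_samples, dtype=bool)
    for s in np.flatnonzero(removed):
        keep_mask[s * seg_len : (s + 1) * seg_len] = False
    # re-index events onto the spliced timeline
    new_index = np.cumsum(keep_mask) - 1
    events = [
        (int(new_index[s]), code)
        for s, code in recording.events
        if keep_mask[s]
    ]
    out = Recording(
        data=recording.data[:, keep_mask],
        sfreq=fs,
        ch_names=list(recording.ch_names),
        events=events,
    )
    return out, log


def filter_chain(
    recording: Recording,
    bandpass_hz: tuple[float, float] = (0.5, 95.0),
    notch_hz: tuple[float, ...] = (50.0, 100.0),
) -> Recording:
    """Zero-phase band-pass plus power-line notches.

    4th-order Butterworth band-pass and 2nd-order IIR notches, each
    applied forward-backward (sosfiltfilt) so downstream phase estimates
    are undistorted.
    """
    fs = recording.sfreq
    nyq = fs / 2.0
    lo, hi = bandpass_hz
    if hi >= nyq:
        raise ValueError(
            f"band-pass upper edge {hi} Hz requires sampling rate > {2 * hi} Hz"
        )
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    for f0 in notch_hz:
        if f0 >= nyq:
            continue
        b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
        sos_n = signal.tf2sos(b, a)
        data = signal.sosfiltfilt(sos_n, data, axis=1)
    return Recording(
        data=data, sfreq=fs, ch_names=list(recording.ch_names),
        events=list(recording.events),
    )


def remove_artifact_components(
    recording: Recording,
    n_components: int | None = None,
    frontal_prefixes: tuple[str, ...] = ("Fp", "AF"),
    random_state: int = 0,
) -> Recording:
    """ICA-based removal of stereotyped artifact components.

    Decomposition is delegated to mne's ICA. Components are flagged by
    two automatic criteria: blink-like (topography dominated by frontal
    electrodes and spectrum dominated by <4 Hz power) and muscle-like
    (spectrum dominated by >20 Hz power, i.e. >60% of component power).
    Flagged components are zeroed and the record reconstructed. On any
    decomposition failure the input passes through unchanged with a
    logged warning.
    """
    import mne

    if recording.n_channels < 20:
        raise ValueError("ICA stage requires >= 20 channels")
    try:
        info = mne.create_info(
            list(recording.ch_names), recording.sfreq, ch_types="eeg"
        )
        raw = mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
        k = n_components or min(15, recording.n_channels - 1)
        ica = mne.preprocessing.ICA(
            n_components=k, method="fastica", random_state=random_state,
            verbose="error",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica.fit(raw, verbose="error")
            sources = ica.get_sources(raw).get_data()
        topo = ica.get_components()  # (n_channels, n_components)
        frontal_idx = [
            i for i, ch in enumerate(recording.ch_names)
            if ch.startswith(frontal_prefixes)
        ]
        exclude = []
        freqs = np.fft.rfftfreq(sources.shape[1], d=1.0 / recording.sfreq)
        for c in range(sources.shape[0]):
            psd = np.abs(np.fft.rfft(sources[c])) ** 2
            total = psd.sum() or 1.0
            low_frac = psd[freqs < 4.0].sum() / total
            high_frac = psd[freqs > 20.0].sum() / total
            w = np.abs(topo[:, c])
            frontal_frac = w[frontal_idx].sum() / (w.sum() or 1.0) if frontal_idx else 0.0
            frontal_share = len(frontal_idx) / recording.n_channels
            is_blink = low_frac > 0.6 and frontal_frac > 2.0 * frontal_share
            is_muscle = high_frac > 0.6
            if is_blink or is_muscle:
                exclude.append(c)
        ica.exclude = exclude
        clean = ica.apply(raw.copy(), verbose="error")
        data = clean.get_data() * 1e6
    except Exception as exc:  # decomposition failure -> pass-through
        logger.warning("ICA stage failed (%s); passing recording through", exc)
        return recording
    return Recording(
        data=data, sfreq=recording.sfreq, ch_names=list(recording.ch_names),
        events=list(recording.events),
    )


def make_epochs(recording: Recording, reject_uv: float = 100.0) -> EpochSet:
    """Cut -1...+2 s epochs around arrow markers.

    Trials whose window would read outside the recording are dropped and
    logged; trials with any sample exceeding ``reject_uv`` in absolute
    value on any channel are retained in the array but masked out.
    Raises if any condition present in the markers ends with zero kept
    epochs.
    """
    if not recording.events:
        raise ValueError("recording has no event markers")
    fs = recording.sfreq
    pre = int(round(-EPOCH_TMIN_S * fs))
    post = int(round(EPOCH_TMAX_S * fs))
    epochs, conds = [], []
    n_boundary = 0
    for s, code in recording.events:
        if not code.startswith("arrow_"):
            continue
        a, b = s - pre, s + post
        if a < 0 or b > recording.n_samples:
            n_boundary += 1
            continue
        epochs.append(recording.data[:, a:b])
        conds.append(code.split("_", 1)[1])
    if n_boundary:
        logger.info("dropped %d boundary trials", n_boundary)
    if not epochs:
        raise ValueError("no complete epochs could be cut")
    data = np.stack(epochs)
    condition = np.asarray(conds)
    kept = np.max(np.abs(data), axis=(1, 2)) <= reject_uv
    for cond in np.unique(condition):
        if not kept[condition == cond].any():
            raise ValueError(f"zero kept epochs in condition {cond!r}")
    return EpochSet(
        data=data, sfreq=fs, ch_names=list(recording.ch_names),
        condition=condition, kept=kept,
    )


def preprocess(
    recording: Recording, config: PreprocessConfig | None = None
) -> tuple[EpochSet, dict]:
    """Full chain; returns epochs plus a provenance dict with the
    rejection log and stage order."""
    cfg = config or PreprocessConfig()
    rec, log = reject_segments(recording, cfg.seg_len_s, cfg.seg_factor)
    rec = filter_chain(rec, cfg.bandpass_hz, cfg.notch_hz)
    stages = ["reject_segments", "filter_chain"]
    if cfg.ica:
        rec = remove_artifact_components(rec)
        stages.append("remove_artifact_components")
    epochs = make_epochs(rec, cfg.reject_uv)
    stages.append("make_epochs")
    provenance = {
        "stages": stages,
        "segments_removed": int(log["removed"].sum()),
        "rejection_log": log,
        "n_epochs": int(epochs.n_trials),
        "n_kept": int(epochs.kept.sum()),
    }
    return epochs, provenance
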