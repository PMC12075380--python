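"""Synthetic EEG and behavior with known ground-truth theta-gamma coupling.

The generator emulates the study conditions of a lateralized visual
change-detection experiment: 64-channel 10-10 EEG in which frontal theta
(4-8 Hz) phase modulates occipital gamma (30-80 Hz) amplitude at a
controllable depth, on top of 1/f (pink) background and white measurement
noise, with occasional high-amplitude artifact segments; plus binomial
hit/false-alarm behavior with lognormal reaction times.

The phase-amplitude coupled channel model is the standard modulated-envelope
construction

    x(t) = A_th sin(2 pi f_th t)
         + A_g [(1 - d) + d (1 + cos(2 pi f_th t)) / 2] sin(2 pi f_g t)
         + noise,

with modulation depth d in [0, 1]: d = 0 gives a constant gamma envelope
(no coupling), d = 1 puts the full envelope swing on the theta cycle, and
the cosine shape gives closed-form phase-bin masses for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import CONDITIONS, Recording
from .montage import CHANNELS_64, DEFAULT_REGIONS

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_pac_signal",
    "generate_recording",
    "generate_behavior",
    "pink_noise",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Rates and the lognormal RT parameters may be scalars (applied to both
    conditions) or per-condition dicts keyed "2T"/"4T". Amplitudes are in
    microvolts; ``rt_lognormal_mu``/``sigma`` are on the log-millisecond
    scale.
    """

    sampling_rate: float = 1000.0
    channel_names: tuple[str, ...] = CHANNELS_64
    n_trials_per_condition: int = 100
    theta_freq: float = 6.0
    gamma_freq: float = 40.0
    modulation_depth: float = 0.6
    theta_amp: float = 10.0
    gamma_amp: float = 5.0
    noise_sd: float = 1.0  # white measurement noise, uV
    pink_sd: float = 2.0  # 1/f background, uV
    artifact_rate: float = 0.0  # probability per 2-s segment
    artifact_gain: float = 10.0  # must exceed the 5x rejection factor
    hit_rate: float | dict = field(default_factory=lambda: {"2T": 0.90, "4T": 0.75})
    fa_rate: float | dict = field(default_factory=lambda: {"2T": 0.10, "4T": 0.20})
    rt_lognormal_mu: float = 6.6  # exp(6.6) ~ 735 ms
    rt_lognormal_sigma: float = 0.25
    trial_spacing_s: tuple[float, float] = (3.5, 4.5)
    seed: int = 0

    def rate(self, which: str, condition: str) -> float:
        v = getattr(self, which)
        return float(v[condition]) if isinstance(v, dict) else float(v)

    def validate(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        if self.gamma_freq <= self.theta_freq:
            raise ValueError("gamma_freq must exceed theta_freq")
        if not 4.0 <= self.theta_freq <= 8.0:
            raise ValueError("theta_freq must lie in the 4-8 Hz band")
        if not 30.0 <= self.gamma_freq <= 80.0:
            raise ValueError("gamma_freq must lie in the 30-80 Hz band")
        if self.sampling_rate < 2 * 95.0:
            raise ValueError("sampling_rate must be >= 190 Hz (2 x 95 Hz filter edge)")
        if self.sampling_rate < 2 * self.gamma_freq:
            raise ValueError("sampling_rate below Nyquist for gamma_freq")
        for cond in CONDITIONS:
            for which in ("hit_rate", "fa_rate"):
                r = self.rate(which, cond)
                if not (np.isfinite(r) and 0.0 <= r <= 1.0):
                    raise ValueError(f"{which}[{cond}] must be a probability")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        lo, hi = self.trial_spacing_s
        if lo < 3.5 or hi < lo:
            raise ValueError("trial spacing must be >= 3.5 s so epochs never overlap")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What was injected, for parameter-recovery tests."""

    channel_depth: dict[str, float]
    artifact_segments: list[int]  # 2-s segment indices scaled by artifact_gain
    segment_len: int  # samples per artifact segment
    trial_truth: dict[str, list[str]]  # condition -> per-trial "match"/"mismatch"


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    # shape white Gaussian noise by 1/sqrt(f) in amplitude => 1/f power
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pac_waveform(
    t: np.ndarray,
    depth: float,
    theta_freq: float,
    gamma_freq: float,
    theta_amp: float,
    gamma_amp: float,
) -> np.ndarray:
    theta_phase = 2 * np.pi * theta_freq * t
    envelope = (1.0 - depth) + depth * (1.0 + np.cos(theta_phase)) / 2.0
    return theta_amp * np.sin(theta_phase) + gamma_amp * envelope * np.sin(
        2 * np.pi * gamma_freq * t
    )


def generate_pac_signal(
    config: SynthConfig,
    channel_depth: float,
    duration_s: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-channel phase-amplitude-coupled series, in microvolts.

    ``channel_depth`` overrides ``config.modulation_depth`` for this
    channel. With depth 0 and zero noise the gamma envelope is constant;
    with depth 1 the envelope follows (1 + cos phase)/2 exactly, so the
    phase-binned amplitude distribution is known in closed form.
    """
    config.validate()
    if not 0.0 <= channel_depth <= 1.0:
        raise ValueError("channel_depth must be in [0, 1]")
    fs = config.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = _pac_waveform(
        t, channel_depth, config.theta_freq, config.gamma_freq,
        config.theta_amp, config.gamma_amp,
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.pink_sd > 0:
        x = x + config.pink_sd * pink_noise(n, rng)
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal(n)
    return x


def default_channel_depths(config: SynthConfig) -> dict[str, float]:
    """Coupling depth per channel: occipital electrodes carry the
    modulated gamma, all others are uncoupled."""
    occipital = set(DEFAULT_REGIONS["left_occipital"]) | set(
        DEFAULT_REGIONS["right_occipital"]
    )
    return {
        ch: (config.modulation_depth if ch in occipital else 0.0)
        for ch in config.channel_names
    }


def generate_recording(
    config: SynthConfig,
    channel_depths: dict[str, float] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Continuous recording for one session: both conditions interleaved.

    One marker per trial at the cue-arrow onset, with codes arrow_2T /
    arrow_4T; trial spacing is jittered uniformly within
    ``config.trial_spacing_s`` (>= 3.5 s, so -1...+2 s epochs never
    overlap). A shared theta oscillator drives frontal channels and
    modulates occipital gamma amplitude, giving true frontal-theta to
    occipital-gamma coupling at the configured depth.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    fs = config.sampling_rate
    if channel_depths is None:
        channel_depths = default_channel_depths(config)
    for ch in channel_depths:
        if ch not in config.channel_names:
            raise ValueError(f"depth map channel {ch!r} not in montage")

    # --- trial timeline ------------------------------------------------
    n_trials = 2 * config.n_trials_per_condition
    codes = np.array(
        ["arrow_2T"] * config.n_trials_per_condition
        + ["arrow_4T"] * config.n_trials_per_condition
    )
    rng.shuffle(codes)
    lo, hi = config.trial_spacing_s
    gaps = rng.uniform(lo, hi, size=n_trials)
    onsets_s = 1.5 + np.cumsum(gaps) - gaps[0]  # first arrow at 1.5 s
    events = [(int(round(o * fs)), c) for o, c in zip(onsets_s, codes)]
    duration_s = onsets_s[-1] + 2.5  # room for the last epoch
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # --- signal ---------------------------------------------------------
    theta_phase = 2 * np.pi * config.theta_freq * t
    theta_wave = np.sin(theta_phase)
    gamma_carrier = np.sin(2 * np.pi * config.gamma_freq * t)
    frontal = set(DEFAULT_REGIONS["left_frontal"]) | set(DEFAULT_REGIONS["right_frontal"])

    data = np.empty((len(config.channel_names), n))
    for i, ch in enumerate(config.channel_names):
        d = channel_depths.get(ch, 0.0)
        x = np.zeros(n)
        if ch in frontal:
            x += config.theta_amp * theta_wave
        if d > 0:
            envelope = (1.0 - d) + d * (1.0 + np.cos(theta_phase)) / 2.0
            x = x + config.gamma_amp * envelope * gamma_carrier
            # weak local theta so occipital phase is also defined
            x += 0.3 * config.theta_amp * theta_wave
        if config.pink_sd > 0:
            x = x + config.pink_sd * pink_noise(n, rng)
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(n)
        data[i] = x

    # --- artifact injection ----------------------------------------------
    seg_len = int(round(2.0 * fs))
    n_segments = n // seg_len
    artifact_segments: list[int] = []
    if config.artifact_rate > 0:
        flags = rng.random(n_segments) < config.artifact_rate
        for s in np.flatnonzero(flags):
            sl = slice(s * seg_len, (s + 1) * seg_len)
            data[:, sl] *= config.artifact_gain
            artifact_segments.append(int(s))

    truth = GroundTruth(
        channel_depth=dict(channel_depths),
        artifact_segments=artifact_segments,
        segment_len=seg_len,
        trial_truth={},  # filled by generate_behavior when run jointly
    )
    rec = Recording(
        data=data, sfreq=fs, ch_names=list(config.channel_names), events=events
    )
    return rec, truth


def generate_behavior(
    config: SynthConfig,
    subject: str = "S01",
    session: str = "pre",
):
    """Per-trial behavioral log as a tidy DataFrame.

    Columns: subject, session, condition, trial, truth, response, rt_ms.
    Truth is match/mismatch with equal probability; the response is
    "match" with probability hit_rate on match trials and fa_rate on
    mismatch trials; RTs are lognormal in milliseconds.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for cond in CONDITIONS:
        hit = config.rate("hit_rate", cond)
        fa = config.rate("fa_rate", cond)
        # balanced design: half match, half mismatch, shuffled order
        n = config.n_trials_per_condition
        truths = np.array(["match"] * (n - n // 2) + ["mismatch"] * (n // 2))
        rng.shuffle(truths)
        for trial in range(n):
            truth = str(truths[trial])
            p_match = hit if truth == "match" else fa
            response = "match" if rng.random() < p_match else "mismatch"
            rt = float(
                np.exp(rng.normal(config.rt_lognormal_mu, config.rt_lognormal_sigma))
            )
            rows.append(
                dict(
                    subject=subject,
                    session=session,
                    condition=cond,
                    trial=trial,
                    truth=truth,
                    response=response,
                    rt_ms=rt,
                )
            )
    return pd.DataFrame(rows)
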