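"""Phase-amplitude (modulation index) and phase-phase coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgcwm.coupling import (
    N_BINS,
    analytic,
    couple_regions,
    mi_from_distribution,
    modulation_index,
    phase_amplitude_distribution,
    phase_bin_edges,
    phase_phase_coupling,
)

FS = 500.0


def mi_oracle(p):
    """Independent direct evaluation of the MI formula on bin masses."""
    n = len(p)
    total = 0.0
    for pi in p:
        if pi > 0:
            total += pi * np.log(pi / (1.0 / n))
    return total / np.log(n)


def cosine_bin_masses(n_bins=N_BINS, depth=1.0):
    """Closed-form P_i for an envelope (1-d) + d(1+cos phi)/2 over
    equal-width bins: the bin mass is the integral of the envelope."""
    edges = phase_bin_edges(n_bins)
    masses = []
    for a, b in zip(edges[:-1], edges[1:]):
        masses.append((1 - depth) * (b - a) + depth * ((b - a) + np.sin(b) - np.sin(a)) / 2)
    masses = np.array(masses)
    return masses / masses.sum()


def brute_force_mi(phase, amplitude, n_bins=N_BINS):
    """Sample-by-sample loop implementation, independent of bincount."""
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    width = 2 * np.pi / n_bins
    for ph, am in zip(phase, amplitude):
        i = int((ph + np.pi) // width)
        i = min(max(i, 0), n_bins - 1)
        sums[i] += am
        counts[i] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    p = means / means.sum()
    return mi_oracle(p)


class TestAnalytic:
    def test_phase_advances_at_carrier_rate(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        sig = analytic(x, (4, 8), FS)
        sl = slice(int(FS), -int(FS))
        slope = np.diff(np.unwrap(sig.phase[sl])).mean() * FS / (2 * np.pi)
        assert slope == pytest.approx(6.0, rel=0.01)

    def test_constant_amplitude_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 40.0 * t)
        sig = analytic(x, (30, 60), FS)
        env = sig.amplitude[int(FS):-int(FS)]
        assert np.abs(env - 3.0).max() < 0.06  # within 2%

    def test_known_envelope_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        x = env * np.sin(2 * np.pi * 40.0 * t)
        sig = analytic(x, (30, 60), FS)
        sl = slice(int(FS), -int(FS))
        assert np.corrcoef(sig.amplitude[sl], env[sl])[0, 1] > 0.99

    def test_window_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="3 cycles"):
            analytic(np.zeros(100), (4, 8), FS)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        mi = modulation_index(phase, np.ones_like(phase))
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_mass_gives_one(self, rng):
        phase = 0.1 + rng.uniform(0, 0.05, 5_000)  # all in one 20-degree bin
        amp = rng.uniform(0.5, 1.5, 5_000)
        assert modulation_index(phase, amp) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_cosine_masses_match_oracle(self):
        for depth in (0.25, 0.5, 1.0):
            p = cosine_bin_masses(depth=depth)
            assert mi_from_distribution(p) == pytest.approx(
                mi_oracle(p), abs=1e-10
            )

    def test_sampled_cosine_envelope_approaches_closed_form(self):
        # regular phase sampling over whole cycles, envelope (1+cos)/2
        phase = np.angle(np.exp(1j * np.linspace(0, 400 * np.pi, 360_000,
                                                 endpoint=False)))
        amp = (1 + np.cos(phase)) / 2
        assert modulation_index(phase, amp) == pytest.approx(
            mi_from_distribution(cosine_bin_masses(depth=1.0)), abs=1e-4
        )

    def test_matches_brute_force_loop(self, rng):
        for _ in range(5):
            phase = rng.uniform(-np.pi, np.pi, 2_000)
            amp = rng.gamma(2.0, 1.0, 2_000)
            assert modulation_index(phase, amp) == pytest.approx(
                brute_force_mi(phase, amp), abs=1e-12
            )

    def test_all_zero_amplitude_is_an_error(self, rng):
        with pytest.raises(ValueError, match="all-zero"):
            modulation_index(rng.uniform(-np.pi, np.pi, 100), np.zeros(100))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(30, 500))
    def test_bounds_and_scale_invariance(self, seed, n):
        r = np.random.default_rng(seed)
        phase = r.uniform(-np.pi, np.pi, n)
        amp = r.exponential(1.0, n) + 1e-9
        mi = modulation_index(phase, amp)
        assert 0.0 <= mi <= 1.0
        assert modulation_index(phase, 7.3 * amp) == pytest.approx(mi, abs=1e-12)

    def test_null_bias_decreases_with_window_length(self, rng):
        """On pure noise, MI bias shrinks as the window grows: the 1-s
        retention window has a lower null MI than a 0.5-s window."""
        short, long_ = [], []
        for _ in range(200):
            for n, acc in ((125, short), (250, long_)):
                phase = rng.uniform(-np.pi, np.pi, n)
                amp = rng.rayleigh(1.0, n)
                acc.append(modulation_index(phase, amp))
        assert np.mean(short) > np.mean(long_)


class TestPhasePhaseCoupling:
    def test_perfect_locking(self):
        slow = np.linspace(-np.pi, np.pi, 1_000)
        fast = 6.0 * slow  # m/n ratio with n=1, m=6
        assert phase_phase_coupling(slow, fast, n=1, m=6) == pytest.approx(1.0)

    def test_constant_offset_invariance(self, rng):
        slow = rng.uniform(-np.pi, np.pi, 2_000)
        fast = rng.uniform(-np.pi, np.pi, 2_000)
        a = phase_phase_coupling(slow, fast)
        b = phase_phase_coupling(slow, fast + 1.234)
        assert a == pytest.approx(b, abs=1e-12)

    def test_rayleigh_null_level(self):
        """Independent phases at T=10,000: PPC below 0.05 in >=95% of
        100 seeds (null mean ~ sqrt(pi)/(2 sqrt(T)) ~ 0.009)."""
        below = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            ppc = phase_phase_coupling(
                r.uniform(-np.pi, np.pi, 10_000),
                r.uniform(-np.pi, np.pi, 10_000),
            )
            below += ppc < 0.05
        assert below >= 95

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            phase_phase_coupling(np.empty(0), np.empty(0))


class TestCoupleRegions:
    @staticmethod
    def _epochs(depth, seed, n_trials=2):
        from tgcwm.core import EpochSet
        from tgcwm.synth import SynthConfig, generate_recording
        from tgcwm.preprocess import make_epochs

        cfg = SynthConfig(
            sampling_rate=250.0, channel_names=("F3", "O1"),
            n_trials_per_condition=n_trials, modulation_depth=depth,
            pink_sd=0.5, noise_sd=0.5, seed=seed,
        )
        depths = {"F3": 0.0, "O1": depth}
        rec, _ = generate_recording(cfg, channel_depths=depths)
        return make_epochs(rec, reject_uv=np.inf)

    def test_grid_shape_per_pair(self, two_region_map):
        epochs = self._epochs(0.5, seed=1)
        table = couple_regions(
            epochs, two_region_map, [("left_frontal", "left_occipital")]
        )
        per_cond = table.groupby("condition").size()
        # 3 windows x 2 gamma sub-bands x 2 measures
        assert (per_cond == 12).all()
        assert set(table["measure"]) == {"PAC_MI", "PPC"}
        assert table["value"].between(0, 1).all()

    def test_amplitude_scale_invariance(self, two_region_map):
        epochs = self._epochs(0.5, seed=2)
        a = couple_regions(epochs, two_region_map,
                           [("left_frontal", "left_occipital")])
        epochs.data[:, 1, :] *= 10.0  # amplitude-region channel
        b = couple_regions(epochs, two_region_map,
                           [("left_frontal", "left_occipital")])
        assert np.allclose(a["value"], b["value"], atol=1e-9)

    def test_injected_coupling_detected_paired_over_seeds(self, two_region_map):
        """MI(depth 0.8) > MI(depth 0) in a paired comparison, 20 seeds."""
        wins = 0
        for seed in range(20):
            vals = {}
            for d in (0.0, 0.8):
                table = couple_regions(
                    self._epochs(d, seed=seed), two_region_map,
                    [("left_frontal", "left_occipital")],
                )
                vals[d] = table.query(
                    "measure == 'PAC_MI' and gamma_band == 'low_gamma'"
                )["value"].mean()
            wins += vals[0.8] > vals[0.0]
        assert wins >= 16  # >=80% of seeds

    def test_short_windows_flagged_low_confidence(self, two_region_map):
        epochs = self._epochs(0.5, seed=3)
        table = couple_regions(epochs, two_region_map,
                               [("left_frontal", "left_occipital")])
        # the 500-ms attention/encoding windows are exactly at the
        # 2-cycle minimum, so nothing is flagged on the standard grid
        assert not table["low_confidence"].any()
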