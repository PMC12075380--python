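"""Segment rejection, filtering, ICA stage and epoching."""

import numpy as np
import pytest

from tgcwm.core import Recording
from tgcwm.preprocess import (
    PreprocessConfig,
    filter_chain,
    make_epochs,
    preprocess,
    reject_segments,
    remove_artifact_components,
)

FS = 250.0


def _segmented_recording(seg_values, fs=FS, seg_s=2.0, events=()):
    """One-channel recording made of constant-amplitude 2-s segments."""
    seg_len = int(seg_s * fs)
    data = np.concatenate([np.full(seg_len, v) for v in seg_values])[None, :]
    return Recording(data=data, sfreq=fs, ch_names=["Cz"], events=list(events))


class TestRejectSegments:
    def test_constant_recording_removes_nothing(self):
        rec = _segmented_recording([1.0] * 20)
        out, log = reject_segments(rec)
        assert not log["removed"].any()
        assert out.n_samples == rec.n_samples

    def test_single_outlier_removed_exactly(self):
        values = [1.0] * 99 + [10.0]
        rec = _segmented_recording(values)
        out, log = reject_segments(rec)
        assert list(log.loc[log["removed"], "segment_index"]) == [99]
        assert out.n_samples == rec.n_samples - int(2 * FS)

    def test_exact_five_times_boundary_retained(self):
        # r = 5 * mean([1]*99 + [r]) / 100  =>  r = 495/95
        r = 495.0 / 95.0
        rec = _segmented_recording([1.0] * 99 + [r])
        _, log = reject_segments(rec)
        assert not log["removed"].any()

    def test_idempotent_second_pass_removes_nothing(self):
        rec = _segmented_recording([1.0] * 50 + [10.0])
        once, _ = reject_segments(rec)
        _, log2 = reject_segments(once)
        assert log2["removed"].sum() == 0

    def test_events_dropped_and_reindexed(self):
        seg_len = int(2 * FS)
        events = [(seg_len // 2, "arrow_2T"),       # inside removed segment 0
                  (3 * seg_len + 10, "arrow_4T")]   # after removed segment
        rec = _segmented_recording([10.0] + [1.0] * 49, events=events)
        out, log = reject_segments(rec)
        assert list(log.loc[log["removed"], "segment_index"]) == [0]
        assert out.events == [(3 * seg_len + 10 - seg_len, "arrow_4T")]

    def test_all_removed_is_an_error(self):
        # impossible with a finite factor on homogeneous data; force via factor<1
        rec = _segmented_recording([1.0] * 10)
        with pytest.raises(ValueError, match="all segments"):
            reject_segments(rec, factor=0.5)

    def test_too_short_recording(self):
        rec = Recording(np.zeros((1, 10)), FS, ["Cz"])
        with pytest.raises(ValueError, match="shorter"):
            reject_segments(rec)


class TestFilterChain:
    @staticmethod
    def _tone(freq, fs=500.0, dur=10.0):
        t = np.arange(int(dur * fs)) / fs
        return Recording(np.sin(2 * np.pi * freq * t)[None, :], fs, ["Cz"])

    def test_power_line_attenuated(self):
        rec = self._tone(50.0)
        out = filter_chain(rec)
        sl = slice(1000, -1000)
        assert np.sqrt(np.mean(out.data[0, sl] ** 2)) < 0.1 * np.sqrt(
            np.mean(rec.data[0, sl] ** 2)
        )

    @pytest.mark.parametrize("freq", [6.0, 10.0, 40.0])
    def test_passband_preserved(self, freq):
        rec = self._tone(freq)
        out = filter_chain(rec)
        sl = slice(1000, -1000)
        ratio = np.sqrt(np.mean(out.data[0, sl] ** 2)) / np.sqrt(
            np.mean(rec.data[0, sl] ** 2)
        )
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_offset_removed(self):
        fs = 500.0
        rec = Recording(np.full((1, int(10 * fs)), 7.0), fs, ["Cz"])
        out = filter_chain(rec)
        assert np.abs(out.data[0, 1000:-1000]).max() < 0.1

    def test_sampling_rate_too_low_for_upper_edge(self):
        rec = self._tone(10.0, fs=180.0)
        with pytest.raises(ValueError, match="band-pass upper edge"):
            filter_chain(rec)


class TestIcaStage:
    def test_requires_twenty_channels(self):
        rec = Recording(np.random.default_rng(0).standard_normal((4, 1000)),
                        FS, ["Fp1", "Fp2", "Cz", "Oz"])
        with pytest.raises(ValueError, match="20 channels"):
            remove_artifact_components(rec)

    def test_blink_component_suppressed(self, rng):
        """Frontal low-frequency transients shrink frontal variance."""
        from tgcwm.synth import pink_noise

        fs, dur = 250.0, 40.0
        n = int(fs * dur)
        names = [f"C{i}" for i in range(20)] + ["Fp1", "Fp2", "AF3", "AF4"]
        # 1/f background: broadband white noise would itself (correctly)
        # trip the muscle criterion
        data = np.stack([pink_noise(n, rng) for _ in range(24)])
        t = np.arange(n) / fs
        blink = np.zeros(n)
        for onset in np.arange(2.0, dur - 2.0, 3.0):
            m = (t > onset) & (t < onset + 0.4)
            blink[m] += np.hanning(m.sum()) * 40.0
        for idx in (20, 21, 22, 23):
            data[idx] += blink
        rec = Recording(data, fs, names)
        out = remove_artifact_components(rec, n_components=23, random_state=0)
        assert out.data[20].var() < 0.7 * rec.data[20].var()
        # non-frontal channels largely preserved
        r = np.corrcoef(out.data[0], rec.data[0])[0, 1]
        assert r > 0.8


class TestMakeEpochs:
    @staticmethod
    def _recording_with_trials(amplitudes, fs=FS):
        """Trials spaced 4 s; each epoch has the given peak amplitude."""
        n_trials = len(amplitudes)
        n = int((4 * n_trials + 4) * fs)
        data = np.zeros((1, n))
        events = []
        for k, amp in enumerate(amplitudes):
            s = int((2 + 4 * k) * fs)
            data[0, s + 10] = amp
            events.append((s, "arrow_2T" if k % 2 == 0 else "arrow_4T"))
        return Recording(data, fs, ["Cz"], events)

    def test_amplitude_threshold_boundary(self):
        rec = self._recording_with_trials([99.0, 50.0, 101.0, 50.0])
        epochs = make_epochs(rec)
        assert epochs.n_trials == 4
        assert list(epochs.kept) == [True, True, False, True]

    def test_condition_counts(self):
        rec = self._recording_with_trials([1.0] * 10)
        epochs = make_epochs(rec)
        assert (epochs.condition == "2T").sum() == 5
        assert (epochs.condition == "4T").sum() == 5

    def test_boundary_trial_dropped(self):
        fs = FS
        data = np.zeros((1, int(10 * fs)))
        events = [(int(0.5 * fs), "arrow_2T"),  # needs 1 s of pre-samples
                  (int(5 * fs), "arrow_2T")]
        rec = Recording(data, fs, ["Cz"], events)
        epochs = make_epochs(rec)
        assert epochs.n_trials == 1

    def test_no_events_is_an_error(self):
        rec = Recording(np.zeros((1, 1000)), FS, ["Cz"])
        with pytest.raises(ValueError, match="no event markers"):
            make_epochs(rec)

    def test_all_rejected_condition_is_an_error(self):
        rec = self._recording_with_trials([500.0, 1.0, 500.0, 1.0])
        with pytest.raises(ValueError, match="zero kept epochs.*2T"):
            make_epochs(rec)

    def test_phase_windows_disjoint_and_ordered(self):
        rec = self._recording_with_trials([1.0, 1.0])
        windows = make_epochs(rec).phase_window_samples()
        spans = [windows[k] for k in ("attention", "encoding", "retention")]
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            assert b0 == a1  # contiguous, non-overlapping
        assert spans[0][0] == int(1.0 * FS)  # arrow onset at +1 s into epoch


def test_full_chain_provenance_order(small_config):
    from tgcwm.synth import generate_recording

    rec, _ = generate_recording(small_config)
    epochs, prov = preprocess(rec, PreprocessConfig())
    assert prov["stages"] == ["reject_segments", "filter_chain", "make_epochs"]
    assert prov["n_epochs"] == 2 * small_config.n_trials_per_condition
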