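"""Conditioning filters, epoching, baseline correction, CAR + decimation."""

import numpy as np
import pytest

from reachdecode.containers import TARGETS, EpochsSet
from reachdecode.preprocess import (
    ContinuousEEG,
    EpochError,
    baseline_correct,
    baseline_means,
    car_downsample,
    condition,
    make_epochs,
)


@pytest.fixture()
def continuous(montage):
    """Synthetic continuous record: 6 trials, known events, mixed content."""
    rng = np.random.default_rng(11)
    sf = 512.0
    n_trials = 6
    go_f = 5.0 + 10.0 * np.arange(n_trials)
    events = np.column_stack([go_f - 2.0, go_f, go_f + 4.0])
    n_samp = int((go_f[-1] + 5.0) * sf)
    data = rng.standard_normal((60, n_samp)).astype(np.float32)
    return ContinuousEEG(
        data=data, sfreq=sf, events=events,
        labels=rng.integers(0, 5, n_trials), montage=montage,
    )


class TestCondition:
    def test_notch_removes_line_frequency(self, continuous):
        sf = continuous.sfreq
        t = np.arange(continuous.data.shape[1]) / sf
        line = 20.0 * np.sin(2 * np.pi * 50.0 * t)
        raw = ContinuousEEG(
            data=np.tile(line, (60, 1)).astype(np.float32), sfreq=sf,
            events=continuous.events, labels=continuous.labels,
            montage=continuous.montage,
        )
        out = condition(raw)
        mid = slice(1000, -1000)
        assert (np.sqrt((out.data[0, mid] ** 2).mean())
                < 0.05 * np.sqrt((line[mid] ** 2).mean()))

    def test_linear_ramp_and_dc_removed(self, continuous):
        n = continuous.data.shape[1]
        ramp = 100.0 + 0.5 * np.arange(n) / continuous.sfreq
        raw = ContinuousEEG(
            data=np.tile(ramp, (60, 1)).astype(np.float32),
            sfreq=continuous.sfreq, events=continuous.events,
            labels=continuous.labels, montage=continuous.montage,
        )
        out = condition(raw)
        assert np.abs(out.data).max() < 1.0  # drift and offset gone

    def test_band_above_nyquist_rejected(self, continuous):
        with pytest.raises(ValueError, match="sfreq"):
            condition(ContinuousEEG(
                data=continuous.data[:, ::8], sfreq=64.0,
                events=continuous.events, labels=continuous.labels,
                montage=continuous.montage,
            ))

    def test_in_band_signal_preserved(self, continuous):
        t = np.arange(continuous.data.shape[1]) / continuous.sfreq
        tone = 10.0 * np.sin(2 * np.pi * 10.0 * t)
        raw = ContinuousEEG(
            data=np.tile(tone, (60, 1)).astype(np.float32),
            sfreq=continuous.sfreq, events=continuous.events,
            labels=continuous.labels, montage=continuous.montage,
        )
        out = condition(raw)
        mid = slice(2000, -2000)
        ratio = (out.data[0, mid] ** 2).mean() / (tone[mid] ** 2).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestMakeEpochs:
    def test_forward_epoch_count_and_span(self, continuous):
        e = make_epochs(continuous, "forward")
        assert e.data.shape == (6, 60, int(5 * continuous.sfreq))
        assert e.times[0] == pytest.approx(-3.0)
        assert e.times[-1] == pytest.approx(2.0 - 1 / continuous.sfreq)
        assert np.array_equal(e.labels, continuous.labels)

    def test_backward_epoch_span(self, continuous):
        e = make_epochs(continuous, "backward_prep")
        assert e.data.shape == (6, 60, int(2 * continuous.sfreq))
        assert e.times[0] == pytest.approx(-2.0)

    def test_epoch_values_match_source_slices(self, continuous):
        e = make_epochs(continuous, "forward")
        sf = continuous.sfreq
        s0 = int(round((continuous.events[2, 1] - 3.0) * sf))
        assert np.array_equal(e.data[2], continuous.data[:, s0:s0 + int(5 * sf)])

    def test_truncated_recording_raises_with_trial_index(self, continuous):
        short = ContinuousEEG(
            data=continuous.data[:, :int(30 * continuous.sfreq)],
            sfreq=continuous.sfreq, events=continuous.events,
            labels=continuous.labels, montage=continuous.montage,
        )
        with pytest.raises(EpochError, match=r"\[3, 4, 5\]"):
            make_epochs(short, "forward")

    def test_label_order_follows_trial_sequence(self, continuous):
        # scramble the label sequence; epochs must carry the same order
        labels = continuous.labels[::-1].copy()
        c2 = ContinuousEEG(
            data=continuous.data, sfreq=continuous.sfreq,
            events=continuous.events, labels=labels,
            montage=continuous.montage,
        )
        assert np.array_equal(make_epochs(c2, "forward").labels, labels)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self, montage):
        e = EpochsSet(
            data=np.full((3, 60, 640), 5.0, np.float32), sfreq=128.0,
            times=-3 + np.arange(640) / 128.0,
            labels=np.zeros(3, int), label_names=TARGETS, montage=montage,
        )
        out = baseline_correct(e)
        assert np.abs(out.data).max() == 0

    def test_baseline_interval_mean_is_zero(self, small_subject):
        fw, _, _ = small_subject
        m = baseline_means(fw)  # fw was baseline-corrected pre-decimation
        assert np.abs(m).max() < 0.5  # decimation filter leaves tiny residue

    def test_external_baseline_applies_forward_offsets(self, montage):
        rng = np.random.default_rng(12)
        bw = EpochsSet(
            data=rng.standard_normal((4, 60, 256)).astype(np.float32),
            sfreq=128.0, times=-2 + np.arange(256) / 128.0,
            labels=np.zeros(4, int), label_names=TARGETS, montage=montage,
            phase="backward_prep",
        )
        offsets = rng.standard_normal((4, 60)).astype(np.float32)
        out = baseline_correct(bw, external_baseline=offsets)
        assert np.allclose(out.data, bw.data - offsets[:, :, None], atol=1e-6)

    def test_baseline_outside_span_without_external_raises(self, montage):
        bw = EpochsSet(
            data=np.zeros((2, 60, 256), np.float32), sfreq=128.0,
            times=-2 + np.arange(256) / 128.0, labels=np.zeros(2, int),
            label_names=TARGETS, montage=montage, phase="backward_prep",
        )
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(bw)


class TestCarDownsample:
    def _epochs(self, montage, sfreq=512.0, dur=5.0):
        rng = np.random.default_rng(13)
        n = int(dur * sfreq)
        return EpochsSet(
            data=rng.standard_normal((4, 60, n)).astype(np.float32),
            sfreq=sfreq, times=-3 + np.arange(n) / sfreq,
            labels=np.zeros(4, int), label_names=TARGETS, montage=montage,
        )

    def test_forward_512_to_128_gives_640_samples(self, montage):
        out = car_downsample(self._epochs(montage))
        assert out.data.shape[-1] == 640
        assert out.sfreq == 128.0

    def test_backward_gives_256_samples(self, montage):
        out = car_downsample(self._epochs(montage, dur=2.0))
        assert out.data.shape[-1] == 256

    def test_channel_mean_is_zero_after_car(self, montage):
        out = car_downsample(self._epochs(montage))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-4

    def test_car_idempotent(self, montage):
        e = self._epochs(montage, sfreq=128.0, dur=5.0)
        once = car_downsample(e, 128.0)
        twice = car_downsample(once, 128.0)
        assert np.allclose(once.data, twice.data, atol=1e-5)

    def test_non_integer_factor_rejected(self, montage):
        with pytest.raises(ValueError, match="integer"):
            car_downsample(self._epochs(montage), target_sfreq=100.0)
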