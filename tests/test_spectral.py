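"""CWT power, ERSP normalization, band/window maps, position tests."""

import numpy as np
import pytest

from reachdecode.containers import TARGETS, EpochsSet
from reachdecode.spectral import (
    band_window_maps,
    cwt_power,
    ersp,
    ersp_from_epochs,
    pairwise_position_tests,
)


def tone_epochs(montage, freq=10.0, amp=1.0, n_trials=5, sfreq=128.0,
                n_samples=640, gain=None, gain_window=None):
    """Sinusoidal epochs, optionally amplitude-scaled inside one window."""
    times = -3.0 + np.arange(n_samples) / sfreq
    x = amp * np.cos(2 * np.pi * freq * times)
    data = np.tile(x, (n_trials, 60, 1)).astype(np.float32)
    if gain is not None:
        mask = (times >= gain_window[0]) & (times < gain_window[1])
        data[:, :, mask] *= gain
    return EpochsSet(
        data=data, sfreq=sfreq, times=times,
        labels=np.arange(n_trials) % 5, label_names=TARGETS, montage=montage,
    )


class TestCwtPower:
    def test_pure_tone_peaks_at_its_frequency(self, montage):
        e = tone_epochs(montage, n_trials=1)
        tf = cwt_power(e)
        central = (e.times > -2.5) & (e.times < 1.5)
        prof = tf.power[0, 0][:, central].mean(axis=1)
        assert tf.freqs[prof.argmax()] == 10.0
        # constant power over the central samples
        p10 = tf.power[0, 0, list(tf.freqs).index(10.0), central]
        assert p10.std() / p10.mean() < 0.01

    def test_quadratic_amplitude_to_power(self, montage):
        tf1 = cwt_power(tone_epochs(montage, amp=1.0, n_trials=1))
        tf2 = cwt_power(tone_epochs(montage, amp=2.0, n_trials=1))
        central = slice(64, -64)  # skip the outer 0.5 s
        i10 = list(tf1.freqs).index(10.0)
        ratio = tf2.power[0, 0, i10, central] / tf1.power[0, 0, i10, central]
        assert np.allclose(ratio, 4.0, rtol=0.02)

    def test_zero_input_zero_power(self, montage):
        e = tone_epochs(montage, amp=0.0, n_trials=1)
        assert np.abs(cwt_power(e).power).max() == 0

    def test_frequency_above_nyquist_rejected(self, montage):
        e = tone_epochs(montage, n_trials=1)
        with pytest.raises(ValueError, match="Nyquist|frequencies"):
            cwt_power(e, freqs=np.array([10.0, 70.0]))


class TestErsp:
    def test_power_equal_to_baseline_gives_zero(self, montage):
        e = tone_epochs(montage, n_trials=5)
        maps = ersp(cwt_power(e), e.labels, TARGETS)
        central = (e.times > -2.5) & (e.times < 1.5)
        i10 = list(maps.freqs).index(10.0)
        assert np.abs(maps.ersp[:, :, i10, central]).max() < 0.02

    def test_doubled_power_gives_plus_one(self, montage):
        e = tone_epochs(montage, n_trials=5, gain=np.sqrt(2.0),
                        gain_window=(-1.4, -0.1))
        maps = ersp(cwt_power(e), e.labels, TARGETS)
        mid = (e.times > -1.0) & (e.times < -0.5)  # away from edges
        i10 = list(maps.freqs).index(10.0)
        val = maps.ersp[:, :, i10, mid].mean()
        assert val == pytest.approx(1.0, abs=0.1)

    def test_injected_gain_recovered_via_band_window_maps(self, montage):
        """Amplitude gain g inside a window shows up as g^2 - 1 band ERSP."""
        g = 0.7
        e = tone_epochs(montage, n_trials=5, gain=g, gain_window=(-1.5, -1.0))
        bw = band_window_maps(ersp(cwt_power(e), e.labels, TARGETS), "alpha")
        assert bw.ersp.shape == (5, 60, 10)
        val = bw.ersp[:, :, 3].mean()  # window [-1.5, -1.0)
        assert val == pytest.approx(g ** 2 - 1, abs=0.08)
        # baseline window stays near zero
        assert abs(bw.ersp[:, :, 0].mean()) < 0.05

    def test_ersp_lower_bound(self, montage):
        e = tone_epochs(montage, n_trials=5, gain=0.01,
                        gain_window=(-1.5, -1.0))
        maps = ersp(cwt_power(e), e.labels, TARGETS)
        assert maps.ersp.min() >= -1.0 - 1e-6

    def test_chunked_path_matches_direct(self, montage):
        rng = np.random.default_rng(20)
        e = tone_epochs(montage, n_trials=5)
        e.data += rng.standard_normal(e.data.shape).astype(np.float32)
        direct = ersp(cwt_power(e), e.labels, TARGETS)
        chunked = ersp_from_epochs(e, chunk=2)
        assert np.allclose(direct.ersp, chunked.ersp, atol=1e-4)

    def test_zero_baseline_power_reported(self, montage):
        e = tone_epochs(montage, amp=0.0, n_trials=5)
        with pytest.raises(FloatingPointError, match="baseline"):
            ersp(cwt_power(e), e.labels, TARGETS)


class TestBandWindows:
    def test_alpha_band_frequency_selection(self, montage):
        e = tone_epochs(montage, n_trials=5)
        bw = band_window_maps(ersp(cwt_power(e), e.labels, TARGETS), "alpha")
        assert bw.freqs.min() >= 8.0 and bw.freqs.max() <= 13.0

    def test_ten_windows_over_forward_epoch(self, montage):
        e = tone_epochs(montage, n_trials=5)
        bw = band_window_maps(ersp(cwt_power(e), e.labels, TARGETS), "beta")
        assert bw.ersp.shape[-1] == 10
        assert len(bw.window_edges) == 11

    def test_constant_ersp_propagates_to_every_cell(self, montage):
        e = tone_epochs(montage, n_trials=5)
        maps = ersp(cwt_power(e), e.labels, TARGETS)
        maps.ersp[:] = 0.25
        bw = band_window_maps(maps, "alpha")
        assert np.allclose(bw.ersp, 0.25)

    def test_unknown_band_rejected(self, montage):
        e = tone_epochs(montage, n_trials=5)
        maps = ersp(cwt_power(e), e.labels, TARGETS)
        with pytest.raises(ValueError, match="band"):
            band_window_maps(maps, "gamma")


class TestPositionTests:
    def test_identical_positions_give_p_one(self):
        rng = np.random.default_rng(21)
        base = rng.standard_normal((6, 1, 60, 10))
        sm = np.repeat(base, 5, axis=1)  # all positions identical
        res = pairwise_position_tests(sm, window=3)
        assert np.all(res.p_raw == 1.0)
        assert not res.reject.any()

    def test_strong_posterior_difference_detected(self, montage):
        rng = np.random.default_rng(22)
        post = montage.region_channels("parietal_occipital")
        sm = rng.standard_normal((8, 5, 60, 10)) * 0.1
        sm[:, 0, post, 3] += 2.0  # position 0 deviates posteriorly
        res = pairwise_position_tests(sm, window=3)
        pairs_with_0 = [k for k, (i, j) in enumerate(res.pairs) if 0 in (i, j)]
        sig_channels = set(np.where(res.reject[pairs_with_0].any(axis=0))[0])
        assert set(post) <= sig_channels
        other_pairs = [k for k in range(len(res.pairs))
                       if k not in pairs_with_0]
        assert res.reject[other_pairs].mean() < 0.2

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            pairwise_position_tests(np.zeros((1, 5, 60, 10)), window=0)
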