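"""Generator structure, determinism, and amplitude-gain fidelity."""

import numpy as np
import pytest

from reachdecode.containers import TARGETS
from reachdecode.montage import standard_60_montage
from reachdecode.simulate import (
    SimulationConfig,
    class_prep_gain_map,
    simulate_cohort,
    simulate_subject,
    subject_rng,
)
from reachdecode.spectral import band_window_maps, cwt_power, ersp


class TestStructure:
    def test_small_subject_counts_and_spans(self):
        cfg = SimulationConfig(trials_per_target=3, seed=0)
        fw, bw, truth = simulate_subject(cfg)
        assert fw.data.shape == (15, 60, int(5 * cfg.sfreq_raw))
        assert bw.data.shape == (15, 60, int(2 * cfg.sfreq_raw))
        assert np.bincount(fw.labels, minlength=5).tolist() == [3] * 5
        assert np.array_equal(fw.labels, bw.labels)
        assert fw.phase == "forward" and bw.phase == "backward_prep"

    def test_default_config_emulates_study_protocol(self):
        cfg = SimulationConfig(seed=0)
        assert cfg.n_subjects == 20
        assert cfg.trials_per_target == 60
        assert cfg.sfreq_raw == 512.0
        fw, _, _ = simulate_subject(cfg)
        assert fw.n_trials == 300
        assert np.bincount(fw.labels).tolist() == [60] * 5

    def test_trials_per_target_below_two_rejected(self):
        with pytest.raises(ValueError, match="trials_per_target"):
            SimulationConfig(trials_per_target=1)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(trials_per_target=2, seed=5)
        a = simulate_subject(cfg)
        b = simulate_subject(cfg)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert np.array_equal(a[0].labels, b[0].labels)

    def test_cohort_derives_distinct_subjects_deterministically(self):
        cfg = SimulationConfig(trials_per_target=2, seed=3, n_subjects=2)
        c1 = simulate_cohort(cfg)
        c2 = simulate_cohort(cfg)
        assert len(c1) == 2
        assert np.array_equal(c1[0][0].data, c2[0][0].data)
        assert not np.array_equal(c1[0][0].data, c1[1][0].data)
        solo = simulate_subject(cfg, "S00", rng=subject_rng(cfg, 0))
        assert np.array_equal(solo[0].data, c1[0][0].data)


class TestDirectionCoding:
    def test_gain_map_lateralization_follows_target_side(self):
        cfg = SimulationConfig(direction_effect=0.6, seed=0)
        m = standard_60_montage()
        gains = class_prep_gain_map(cfg, m)
        assert gains.shape == (5, 60)
        right_post = m.index("PO8")
        left_post = m.index("PO7")
        # left target (class 0): deeper ERD (smaller gain) on the right
        assert gains[0, right_post] < gains[0, left_post]
        # right target (class 4): mirrored
        assert gains[4, left_post] < gains[4, right_post]
        # middle target: symmetric
        assert gains[2, left_post] == pytest.approx(gains[2, right_post],
                                                    abs=0.05)

    def test_zero_effect_collapses_classes(self):
        cfg = SimulationConfig(direction_effect=0.0, seed=0)
        gains = class_prep_gain_map(cfg, standard_60_montage())
        assert np.allclose(gains, gains[0][None, :])

    def test_truth_records_match_generated_map(self):
        cfg = SimulationConfig(trials_per_target=2, direction_effect=0.4,
                               seed=1)
        _, _, truth = simulate_subject(cfg)
        expected = class_prep_gain_map(cfg, standard_60_montage())
        assert np.allclose(truth.class_prep_gain, expected)
        assert truth.informative_interval == (-1.5, 0.0)


class TestGainFidelity:
    def test_injected_prep_gain_recovered_from_noise_free_rhythms(self):
        """Band power in the ERD window drops by the squared gain.

        Measured before common-average re-referencing: CAR mixes channels
        spatially, which redistributes the coherent rhythm's amplitude and
        is not part of the per-channel spectral contract.
        """
        cfg = SimulationConfig(
            trials_per_target=2, seed=2, noise_amp=0.0,
            direction_effect=0.0, cue_ers_gain=1.0, exec_erd_gain=1.0,
            prep_erd_gain=0.6,
        )
        fw, _, truth = simulate_subject(cfg)
        from reachdecode.preprocess import baseline_correct

        fw = baseline_correct(fw)  # still 512 Hz, no CAR
        maps = ersp(cwt_power(fw), fw.labels, TARGETS)
        bw = band_window_maps(maps, "alpha")
        m = fw.montage
        # strongest-modulation posterior channel: predicted gain per channel
        post = m.region_channels("parietal_occipital")
        ch = post[np.argmax(1 - truth.class_prep_gain[0, post])]
        g = truth.class_prep_gain[0, ch]
        # windows 4..5 cover [-1.0, 0.0) s, inside the ERD plateau
        measured = bw.ersp[:, ch, 4:6].mean()
        assert measured == pytest.approx(g ** 2 - 1, abs=0.1 * abs(g ** 2 - 1) + 0.03)

    def test_direction_contrast_confined_to_prep_interval(self):
        """The left-right posterior ERD asymmetry tracks the target side in
        the preparation windows and is absent in the execution windows."""
        cfg = SimulationConfig(trials_per_target=8, seed=3,
                               direction_effect=0.8, noise_amp=1.0)
        fw, _, truth = simulate_subject(cfg)
        from reachdecode.preprocess import preprocess_epochs

        fw, _ = preprocess_epochs(fw)
        bwm = band_window_maps(
            ersp(cwt_power(fw), fw.labels, TARGETS), "alpha"
        )
        m = fw.montage
        lat = m.lateralization()
        post = m.region_channels("parietal_occipital")
        right = [i for i in post if lat[i] > 0.2]
        left = [i for i in post if lat[i] < -0.2]
        # hemispheric ERSP contrast per class: right minus left posterior
        def contrast(wins):
            per_class = bwm.ersp[:, right][:, :, wins].mean(axis=(1, 2)) - \
                bwm.ersp[:, left][:, :, wins].mean(axis=(1, 2))
            return per_class

        c_prep = contrast(slice(4, 6))    # [-1.0, 0.0) s
        c_exec = contrast(slice(7, 9))    # [0.5, 1.5) s
        # left targets (class 0) -> deeper right ERD -> negative contrast
        assert c_prep[0] < c_prep[2] < c_prep[4]
        assert np.ptp(c_prep) > 3 * np.ptp(c_exec)
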