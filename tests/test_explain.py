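"""DeepLIFT properties, relevance aggregation, occlusion mechanics."""

import numpy as np
import pytest

from reachdecode.containers import TARGETS, EpochsSet
from reachdecode.explain import (
    RelevanceMap,
    occlude,
    relevance_baseline_test,
    subject_relevance,
)
from reachdecode.net import Dense, Flatten, NetSpec, build_net
from tests.test_net import tiny_float64_net


class TestDeepLift:
    def test_zero_input_zero_attribution(self):
        net = tiny_float64_net()
        x = np.zeros((5, 32))
        attr = net.deeplift(x, 0)
        assert np.abs(attr).max() == 0

    def test_summation_to_delta(self):
        net = tiny_float64_net(seed=5)
        rng = np.random.default_rng(6)
        net.logits(rng.standard_normal((8, 5, 32)), training=True)
        for trial in range(5):
            x = rng.standard_normal((5, 32))
            for cls in range(3):
                attr = net.deeplift(x, cls)
                lx = net.logits(x[None])[0, cls]
                l0 = net.logits(np.zeros((1, 5, 32)))[0, cls]
                assert abs(attr.sum() - (lx - l0)) < 1e-3 * max(1e-9, abs(lx - l0))

    def test_linear_model_closed_form(self):
        """For a purely linear map, attribution is input x weight."""
        net = build_net(NetSpec(n_channels=2, n_samples=16, n_classes=2),
                        seed=0)
        rng = np.random.default_rng(7)
        w = rng.standard_normal((32, 2))
        dense = Dense(32, 2, rng)
        dense.w = w.copy()
        dense.b = np.array([0.3, -0.2])
        net.layers = [Flatten(), dense]
        x = rng.standard_normal((2, 16))
        attr = net.deeplift(x, 1)
        assert np.allclose(attr, x * w[:, 1].reshape(2, 16))

    def test_target_class_out_of_range(self):
        net = tiny_float64_net()
        with pytest.raises(ValueError, match="target_class"):
            net.deeplift(np.zeros((5, 32)), 7)


def _relevance_map(montage, values, sfreq=128.0):
    n_samples = values.shape[1]
    return RelevanceMap(
        values=values, times=-3 + np.arange(n_samples) / sfreq,
        montage=montage, subject_id="S0", n_folds=2, n_trials=10,
    )


class TestRelevanceMap:
    def test_marginal_views_are_exact_means(self, montage):
        rng = np.random.default_rng(8)
        v = np.abs(rng.standard_normal((60, 640)))
        m = _relevance_map(montage, v)
        assert np.allclose(m.temporal(), v.mean(axis=0))
        assert np.allclose(m.spatial((-2.0, -1.0)),
                           v[:, 128:256].mean(axis=1))

    def test_negative_values_rejected(self, montage):
        with pytest.raises(ValueError, match="non-negative"):
            _relevance_map(montage, np.full((60, 640), -1.0))

    def test_subject_relevance_identical_folds_average_to_same(self, montage):
        net = build_net(NetSpec(n_channels=60, n_samples=64, n_classes=2),
                        seed=0)
        rng = np.random.default_rng(9)
        e = EpochsSet(
            data=rng.standard_normal((6, 60, 64)).astype(np.float32),
            sfreq=128.0, times=-3 + np.arange(64) / 128.0,
            labels=np.array([0, 1] * 3), label_names=("proximal", "distal"),
            montage=montage,
        )
        idx = np.arange(6)
        single = subject_relevance([net], e, [idx])
        double = subject_relevance([net, net], e, [idx, idx])
        assert np.allclose(single.values, double.values)
        assert single.values.min() >= 0

    def test_empty_test_set_rejected(self, montage):
        net = build_net(NetSpec(n_channels=60, n_samples=64, n_classes=2))
        e = EpochsSet(
            data=np.zeros((2, 60, 64), np.float32), sfreq=128.0,
            times=-3 + np.arange(64) / 128.0, labels=np.array([0, 1]),
            label_names=("a", "b"), montage=montage,
        )
        with pytest.raises(ValueError, match="empty"):
            subject_relevance([net], e, [np.array([], int)])


class TestRelevanceBaselineTest:
    def test_flat_relevance_yields_no_significance(self, montage):
        rng = np.random.default_rng(10)
        maps = [
            _relevance_map(montage,
                           np.abs(1 + 0.01 * rng.standard_normal((60, 640))))
            for _ in range(6)
        ]
        _, _, _, p_fdr, rej = relevance_baseline_test(maps, n_perm=2000,
                                                      seed=0)
        assert rej.mean() < 0.05

    def test_elevated_interval_detected(self, montage):
        rng = np.random.default_rng(11)
        maps = []
        for _ in range(8):
            v = np.abs(1 + 0.05 * rng.standard_normal((60, 640)))
            v[:, 128:256] *= 2.0  # [-2, -1) s doubled for every subject
            maps.append(_relevance_map(montage, v))
        times, _, _, _, rej = relevance_baseline_test(maps, seed=0)
        win = (times >= -2.0) & (times < -1.0)
        assert rej[win].mean() > 0.9
        assert rej[times >= 0.5].mean() < 0.1

    def test_needs_two_subjects(self, montage):
        m = _relevance_map(montage, np.ones((60, 640)))
        with pytest.raises(ValueError, match="subjects"):
            relevance_baseline_test([m])


class TestOcclude:
    def _epochs(self, montage):
        rng = np.random.default_rng(12)
        return EpochsSet(
            data=rng.standard_normal((3, 60, 640)).astype(np.float32),
            sfreq=128.0, times=-3 + np.arange(640) / 128.0,
            labels=np.zeros(3, int), label_names=TARGETS, montage=montage,
        )

    def test_empty_interval_is_identity(self, montage):
        e = self._epochs(montage)
        out = occlude(e, (-1.0, -1.0))
        assert np.array_equal(out.data, e.data)

    def test_full_span_zeroes_everything(self, montage):
        e = self._epochs(montage)
        assert np.abs(occlude(e, (-3.0, 2.0)).data).max() == 0

    def test_prep_interval_zeroes_256_samples(self, montage):
        e = self._epochs(montage)
        out = occlude(e, (-2.0, 0.0))
        zeroed = np.all(out.data == 0, axis=(0, 1))
        assert zeroed.sum() == 256
        untouched = ~zeroed
        assert np.array_equal(out.data[:, :, untouched],
                              e.data[:, :, untouched])

    def test_idempotent_and_commutes_on_disjoint_intervals(self, montage):
        e = self._epochs(montage)
        once = occlude(e, (-2.0, 0.0))
        twice = occlude(once, (-2.0, 0.0))
        assert np.array_equal(once.data, twice.data)
        ab = occlude(occlude(e, (-2.0, 0.0)), (1.0, 2.0))
        ba = occlude(occlude(e, (1.0, 2.0)), (-2.0, 0.0))
        assert np.array_equal(ab.data, ba.data)

    def test_interval_outside_span_rejected(self, montage):
        with pytest.raises(ValueError, match="outside"):
            occlude(self._epochs(montage), (-5.0, -4.0))
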