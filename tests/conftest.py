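"""Shared fixtures: small synthetic cohorts and trained decoders.

Expensive fixtures are session-scoped so the decoding-dependent tests
(recovery, occlusion, relevance) share one set of trained models.
"""

from __future__ import annotations

import pytest

from reachdecode.montage import standard_60_montage
from reachdecode.preprocess import preprocess_epochs
from reachdecode.simulate import SimulationConfig, simulate_subject
from reachdecode.train import TrainConfig, build_problem, crossval_train

#: reduced problem size used by training-dependent tests: small cohorts keep
#: the suite fast while leaving the decoding task learnable
SMALL_TPT = 24            # trials per target (full study: 60)
STRONG = dict(direction_effect=1.5, noise_amp=0.5)  # positive-control effect
TRAIN_KW = dict(folds=3, lr=1e-3, max_epochs=40, batch_size=8)


@pytest.fixture(scope="session")
def montage():
    return standard_60_montage()


def make_subject(seed: int, tpt: int = SMALL_TPT, **cfg_kw):
    """Simulate + preprocess one subject; returns (forward, backward, truth)."""
    cfg = SimulationConfig(trials_per_target=tpt, seed=seed, **cfg_kw)
    fw, bw, truth = simulate_subject(cfg, f"S{seed:02d}")
    fw, bw = preprocess_epochs(fw, bw)
    return fw, bw, truth


def train_subject(seed: int, problem: str = "coarse", **cfg_kw):
    """One strong-effect subject with a cross-validated trained decoder."""
    fw, bw, truth = make_subject(seed, **({**STRONG, **cfg_kw}))
    sub = build_problem(fw, problem)
    report, models, tsets = crossval_train(
        sub, TrainConfig(seed=seed, **TRAIN_KW)
    )
    return {
        "forward": fw, "backward": bw, "truth": truth, "epochs": sub,
        "report": report, "models": models, "test_sets": tsets,
    }


@pytest.fixture(scope="session")
def small_subject():
    """One preprocessed strong-effect subject at reduced scale."""
    return make_subject(seed=7, **STRONG)


@pytest.fixture(scope="session")
def trained_cohort():
    """Three strong-effect subjects with trained coarse-problem decoders.

    Shared by the decoding-recovery, occlusion and relevance tests.
    """
    return [train_subject(seed) for seed in (0, 1, 2)]
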