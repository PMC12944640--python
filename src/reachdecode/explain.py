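"""DeepLIFT relevance maps and interval-occlusion analysis.

Relevance: for every trained fold model, DeepLIFT attributions (Rescale
rule, zero reference) are taken for the output neuron of the trial's
*correct* class, with respect to the pre-softmax score (softmax saturation
makes post-softmax attributions degenerate).  Absolute values are averaged
over the fold's test trials and then over folds, giving one channels ×
samples map per subject.  Marginal views: the temporal profile is the mean
over channels; spatial profiles are means over samples within 1 s windows.

Occlusion: test trials are re-fed to the trained models with all channels
zeroed inside one interval (preparation [-2, 0) s or execution [0, +2) s);
confusion-matrix and accuracy differences against the intact inputs
quantify each interval's contribution.  Models are never retrained on
occluded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochsSet
from .montage import REGIONS, Montage
from .net import EEGDecoder
from .stats import fdr_bh, paired_permutation_t, paired_t
from .train import evaluate

PREP_INTERVAL = (-2.0, 0.0)
EXEC_INTERVAL = (0.0, 2.0)


@dataclass
class RelevanceMap:
    """Subject-level absolute DeepLIFT relevance with marginal views."""

    values: np.ndarray                 # (channels, samples), >= 0
    times: np.ndarray
    montage: Montage
    subject_id: str
    n_folds: int
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("relevance values must be non-negative")

    def temporal(self) -> np.ndarray:
        """Mean relevance over channels, one value per sample."""
        return self.values.mean(axis=0)

    def spatial(self, window: tuple[float, float]) -> np.ndarray:
        """Mean relevance over samples of a time window, per channel."""
        mask = (self.times >= window[0] - 1e-9) & (self.times < window[1] - 1e-9)
        if not mask.any():
            raise ValueError(f"window {window} outside epoch span")
        return self.values[:, mask].mean(axis=1)

    def region_means(self, window: tuple[float, float]) -> dict[str, float]:
        sp = self.spatial(window)
        return {
            r: float(sp[self.montage.region_channels(r)].mean())
            for r in REGIONS
        }


def deeplift_attribution(
    model: EEGDecoder, x: np.ndarray, target_class: int
) -> np.ndarray:
    """Signed channels × samples attribution for one input trial."""
    return model.deeplift(x, target_class)


def subject_relevance(
    models: list[EEGDecoder],
    e: EpochsSet,
    test_sets: list[np.ndarray],
) -> RelevanceMap:
    """Fold-and-trial-averaged absolute relevance for one subject.

    For each fold model, attributions are computed on that fold's test
    trials toward each trial's correct class, |.| taken, averaged across
    trials, then across folds.
    """
    if len(models) != len(test_sets):
        raise ValueError("need one test set per fold model")
    fold_maps = []
    n_trials = 0
    for model, idx in zip(models, test_sets):
        if len(idx) == 0:
            raise ValueError("empty test set")
        maps = [
            np.abs(model.deeplift(e.data[i].astype(np.float64),
                                  int(e.labels[i])))
            for i in idx
        ]
        fold_maps.append(np.mean(maps, axis=0))
        n_trials += len(idx)
    return RelevanceMap(
        values=np.mean(fold_maps, axis=0), times=e.times,
        montage=e.montage, subject_id=e.subject_id,
        n_folds=len(models), n_trials=n_trials,
    )


def relevance_baseline_test(
    cohort_maps: list[RelevanceMap],
    test_span: tuple[float, float] = (-2.0, 2.0),
    baseline: tuple[float, float] = (-3.0, -2.0),
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Per-sample deviation of temporal relevance from its baseline level.

    For every sample in ``test_span``, each subject contributes the pair
    (relevance at that sample, that subject's mean baseline relevance); a
    sign-flip permutation t-test across subjects is BH-corrected over all
    tested samples.  Returns (times, t, p_raw, p_fdr, reject).
    """
    if len(cohort_maps) < 2:
        raise ValueError("need at least 2 subjects")
    times = cohort_maps[0].times
    tmask = (times >= test_span[0] - 1e-9) & (times < test_span[1] - 1e-9)
    bmask = (times >= baseline[0] - 1e-9) & (times < baseline[1] - 1e-9)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} outside epoch span")
    temp = np.stack([m.temporal() for m in cohort_maps])   # (subj, samples)
    base = temp[:, bmask].mean(axis=1, keepdims=True)
    res = paired_permutation_t(
        temp[:, tmask], np.broadcast_to(base, temp[:, tmask].shape),
        n_perm=n_perm, seed=seed,
    )
    reject, p_fdr = fdr_bh(res.p_raw, alpha=alpha)
    return times[tmask], res.statistic, res.p_raw, p_fdr, reject


def occlude(e: EpochsSet, interval: tuple[float, float]) -> EpochsSet:
    """Zero all channels inside the half-open time interval."""
    t0, t1 = interval
    if t1 < t0:
        raise ValueError(f"invalid interval {interval}")
    if t0 < e.times[0] - 1e-9 or t1 > e.times[-1] + 1 / e.sfreq + 1e-9:
        raise ValueError(
            f"interval {interval} outside epoch span "
            f"[{e.times[0]}, {e.times[-1] + 1 / e.sfreq})"
        )
    data = e.data.copy()
    data[:, :, e.time_mask(interval)] = 0
    return e.copy(data=data)


@dataclass
class OcclusionResult:
    """Occluded-minus-intact performance differences for one interval."""

    interval: tuple[float, float]
    confusion_diff: np.ndarray        # (subjects, classes, classes)
    accuracy_diff: np.ndarray         # (subjects,)
    accuracy_intact: np.ndarray
    accuracy_occluded: np.ndarray
    t_cells: np.ndarray | None = None
    p_raw_cells: np.ndarray | None = None
    p_fdr_cells: np.ndarray | None = None
    reject_cells: np.ndarray | None = None


def _subject_metrics(models, e, test_sets) -> tuple[np.ndarray, float]:
    cms, accs, ns = [], [], []
    for model, idx in zip(models, test_sets):
        m = evaluate(model, e.data[idx].astype(np.float32), e.labels[idx])
        cms.append(m["confusion"])
        accs.append(m["accuracy"])
        ns.append(len(idx))
    return np.mean(cms, axis=0), float(np.average(accs, weights=ns))


def occlusion_analysis(
    subject_models: list[list[EEGDecoder]],
    subject_epochs: list[EpochsSet],
    subject_test_sets: list[list[np.ndarray]],
    intervals: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
) -> dict[str, OcclusionResult]:
    """Interval-occlusion contrast across a cohort.

    For every subject, fold models are evaluated on intact and occluded
    test inputs; per-interval differences (occluded − intact) in the
    row-normalized confusion matrix and in accuracy are aggregated across
    subjects, with per-cell paired t-tests BH-corrected per interval.
    """
    if intervals is None:
        intervals = {"prep": PREP_INTERVAL, "exec": EXEC_INTERVAL}
    n_sub = len(subject_epochs)
    if not (len(subject_models) == len(subject_test_sets) == n_sub):
        raise RuntimeError("per-subject models/epochs/test sets mismatch")
    intact = [
        _subject_metrics(m, e, ts)
        for m, e, ts in zip(subject_models, subject_epochs, subject_test_sets)
    ]
    out: dict[str, OcclusionResult] = {}
    for name, iv in intervals.items():
        diffs, acc_d, acc_i, acc_o = [], [], [], []
        for s in range(n_sub):
            occluded = occlude(subject_epochs[s], iv)
            cm_o, a_o = _subject_metrics(
                subject_models[s], occluded, subject_test_sets[s]
            )
            cm_i, a_i = intact[s]
            diffs.append(cm_o - cm_i)
            acc_d.append(a_o - a_i)
            acc_i.append(a_i)
            acc_o.append(a_o)
        diffs = np.stack(diffs)
        res = OcclusionResult(
            interval=iv, confusion_diff=diffs,
            accuracy_diff=np.array(acc_d),
            accuracy_intact=np.array(acc_i),
            accuracy_occluded=np.array(acc_o),
        )
        if n_sub >= 2 and np.any(diffs.std(axis=0) > 0):
            t = paired_t(diffs, np.zeros_like(diffs))
            reject, p_fdr = fdr_bh(np.nan_to_num(t.p_raw, nan=1.0), alpha=alpha)
            res.t_cells = t.statistic
            res.p_raw_cells = t.p_raw
            res.p_fdr_cells = p_fdr
            res.reject_cells = reject
        out[name] = res
    return out
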