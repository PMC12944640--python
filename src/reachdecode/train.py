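"""Label construction, within-subject cross-validated training, metrics.

Three classification problems are built from the five target positions:

* ``fine`` — all five positions as separate classes (chance 0.2);
* ``coarse`` — left / middle / right, discarding the two intermediate
  positions (chance 0.33);
* ``proximity`` — (left + right) vs (middle-left + middle-right), the
  middle target excluded to keep classes balanced (chance 0.5).

Training follows a within-subject stratified 5-fold cross-validation; in
each fold a stratified 20% of the training trials is held out as a
validation set, and the parameters from the epoch with the highest
validation accuracy are restored (earliest epoch on ties).  Optimization
is Adam on categorical cross-entropy.  Metrics — row-normalized confusion
matrix, accuracy, macro F1 and macro one-vs-rest AUC — are computed on the
held-out test fold only and averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import TARGETS, EpochsSet
from .net import EEGDecoder, NetSpec, build_net

PROBLEMS = ("fine", "coarse", "proximity")

CHANCE = {"fine": 0.2, "coarse": 1 / 3, "proximity": 0.5}

# target-code -> (new label code, class name) per problem; None drops the trial
_PROBLEM_MAPS: dict[str, tuple[tuple[str, ...], dict[int, int]]] = {
    "fine": (TARGETS, {i: i for i in range(5)}),
    "coarse": (("left", "middle", "right"), {0: 0, 2: 1, 4: 2}),
    "proximity": (("proximal", "distal"), {0: 0, 4: 0, 1: 1, 3: 1}),
}


def build_problem(e: EpochsSet, problem: str) -> EpochsSet:
    """Subset/relabel an EpochsSet for one of the three problems."""
    if problem not in _PROBLEM_MAPS:
        raise ValueError(f"problem must be one of {PROBLEMS}, got {problem!r}")
    if tuple(e.label_names) != TARGETS:
        raise ValueError("build_problem expects five-target position labels")
    names, mapping = _PROBLEM_MAPS[problem]
    keep = np.array([lbl in mapping for lbl in e.labels])
    new_labels = np.array([mapping[lbl] for lbl in e.labels[keep]])
    return EpochsSet(
        data=e.data[keep], sfreq=e.sfreq, times=e.times, labels=new_labels,
        label_names=names, montage=e.montage, subject_id=e.subject_id,
        phase=e.phase,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the full-scale study values."""

    folds: int = 5
    val_fraction: float = 0.2
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class FoldResult:
    confusion: np.ndarray          # row-normalized over true class
    accuracy: float
    f1: float
    auc: float
    test_indices: np.ndarray
    best_epoch: int


@dataclass
class EvalReport:
    """Per-subject, per-problem cross-validation outcome."""

    problem: str
    subject_id: str
    folds: list[FoldResult]

    @property
    def accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def f1(self) -> float:
        return float(np.mean([f.f1 for f in self.folds]))

    @property
    def auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def confusion(self) -> np.ndarray:
        return np.mean([f.confusion for f in self.folds], axis=0)

    def summary(self) -> dict:
        return {
            "problem": self.problem,
            "subject_id": self.subject_id,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "fold_accuracy": [f.accuracy for f in self.folds],
        }


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g.astype(np.float64) ** 2 - v)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                p.dtype)


def _fit_one(
    model: EEGDecoder,
    x_tr: np.ndarray, y_tr: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> int:
    """Train with early stopping on validation accuracy; returns best epoch."""
    opt = _Adam(model.params(), lr=cfg.lr)
    best_key, best_epoch, best_state = None, 0, model.get_state()
    n = len(y_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for s0 in range(0, n, cfg.batch_size):
            idx = order[s0:s0 + cfg.batch_size]
            model.loss_and_grad(x_tr[idx], y_tr[idx])
            opt.step(model.grads())
            model.constrain()
        proba = model.predict_proba(x_val)
        acc = float((proba.argmax(axis=1) == y_val).mean())
        # accuracy ties are common when the validation set is small; the
        # latest tying epoch is kept so training is not arrested by an
        # early lucky plateau
        if best_key is None or acc >= best_key:
            best_key, best_epoch = acc, epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return best_epoch


def evaluate(model: EEGDecoder, x: np.ndarray, y: np.ndarray) -> dict:
    """Test-set metrics for a trained model.

    Raises
    ------
    ValueError
        If the test set contains a single class (AUC undefined).
    """
    n_classes = model.spec.n_classes
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined on a single-class test set")
    proba = model.predict_proba(x)
    pred = proba.argmax(axis=1)
    cm = confusion_matrix(y, pred, labels=np.arange(n_classes)).astype(float)
    rowsum = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, rowsum, out=np.zeros_like(cm), where=rowsum > 0)
    if n_classes == 2:
        auc = roc_auc_score(y, proba[:, 1])
    else:
        auc = roc_auc_score(y, proba, multi_class="ovr", average="macro",
                            labels=np.arange(n_classes))
    return {
        "confusion": cm_norm,
        "accuracy": float(accuracy_score(y, pred)),
        "f1": float(f1_score(y, pred, average="macro",
                             labels=np.arange(n_classes), zero_division=0)),
        "auc": float(auc),
    }


def crossval_train(
    e: EpochsSet,
    cfg: TrainConfig = TrainConfig(),
    spec: NetSpec | None = None,
) -> tuple[EvalReport, list[EEGDecoder], list[np.ndarray]]:
    """Stratified k-fold cross-validated training on one subject's epochs.

    Returns the evaluation report, the per-fold trained models, and the
    per-fold test index arrays (a partition of all trials).
    """
    x = e.data.astype(np.float32)
    y = e.labels.astype(int)
    counts = np.bincount(y, minlength=len(e.label_names))
    if counts.min() < cfg.folds:
        raise ValueError(
            f"every class needs >= {cfg.folds} trials for stratified "
            f"{cfg.folds}-fold CV; class counts are {counts.tolist()}"
        )
    if spec is None:
        spec = NetSpec(
            n_channels=e.n_channels, n_samples=e.n_samples,
            n_classes=len(e.label_names),
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=cfg.seed)
    folds: list[FoldResult] = []
    models: list[EEGDecoder] = []
    test_sets: list[np.ndarray] = []
    n_classes = len(e.label_names)
    for k, (train_idx, test_idx) in enumerate(skf.split(x, y)):
        n_val = max(int(round(cfg.val_fraction * len(train_idx))), n_classes)
        stratify = y[train_idx] if n_val >= n_classes else None
        tr_idx, val_idx = train_test_split(
            train_idx, test_size=n_val,
            stratify=stratify, random_state=cfg.seed + 1000 + k,
        )
        model = build_net(spec, seed=cfg.seed + 10_000 + k)
        rng = np.random.default_rng(cfg.seed + 20_000 + k)
        best_epoch = _fit_one(
            model, x[tr_idx], y[tr_idx], x[val_idx], y[val_idx], cfg, rng
        )
        metrics = evaluate(model, x[test_idx], y[test_idx])
        folds.append(FoldResult(
            confusion=metrics["confusion"], accuracy=metrics["accuracy"],
            f1=metrics["f1"], auc=metrics["auc"],
            test_indices=test_idx, best_epoch=best_epoch,
        ))
        models.append(model)
        test_sets.append(test_idx)
    return EvalReport(problem="", subject_id=e.subject_id, folds=folds), \
        models, test_sets
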