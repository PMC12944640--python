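"""Epoched-EEG containers, protocol constants, and HDF5 persistence.

The on-disk container is self-describing HDF5::

    /data              float32, (trials, channels, samples), microvolt
    /labels            int8, per-trial class codes; attribute ``label_names``
    /times             float64, per-sample epoch time in seconds
    /montage/names     channel labels
    /montage/pos       (channels, 2) projected positions
    /montage/regions   per-channel region labels
    attrs: sfreq, subject_id, phase

Datasets are written with ``track_times=False`` so identical content yields
bit-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .montage import Montage

PHASES = ("forward", "backward_prep")

#: Canonical target-position labels, left to right.
TARGETS = ("left", "middle_left", "middle", "middle_right", "right")


class FormatError(RuntimeError):
    """A container file is missing a dataset or has inconsistent shapes."""


@dataclass(frozen=True)
class ProtocolConstants:
    """Quantitative structure of the delayed center-out reaching protocol.

    Five LED targets on a 40 cm semicircular arc, 45° apart; the cue lights
    the target 2 s before the go signal.  Epoch intervals are half-open,
    in seconds relative to the (forward) go signal.
    """

    n_targets: int = 5
    trials_per_target: int = 60
    cue_time: float = -2.0
    go_time: float = 0.0
    baseline_interval: tuple[float, float] = (-3.0, -2.0)
    prep_interval: tuple[float, float] = (-2.0, 0.0)
    exec_interval: tuple[float, float] = (0.0, 2.0)
    target_radius_cm: float = 40.0
    target_spacing_deg: float = 45.0

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.trials_per_target

    def __post_init__(self) -> None:
        ivs = [self.baseline_interval, self.prep_interval, self.exec_interval]
        for (a, b) in ivs:
            if not a < b:
                raise ValueError(f"degenerate interval {(a, b)}")
        for (_, b), (a2, _) in zip(ivs[:-1], ivs[1:]):
            if b != a2:
                raise ValueError("protocol intervals must be contiguous")


@dataclass
class EpochsSet:
    """Trials × channels × samples epoched EEG with labels and montage.

    ``data`` is in microvolt; ``times`` holds the epoch time axis in seconds
    relative to the go signal (half-open span, 0-based samples).  ``labels``
    are integer codes into ``label_names``.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    labels: np.ndarray
    label_names: tuple[str, ...]
    montage: Montage
    subject_id: str = "S00"
    phase: str = "forward"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n_tr, n_ch, n_sa = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError(
                f"data has {n_ch} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if len(self.times) != n_sa:
            raise ValueError("times length must equal the sample axis")
        if len(self.labels) != n_tr:
            raise ValueError("labels length must equal the trial axis")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.label_names)
        ):
            raise ValueError("label codes outside label_names range")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def label_strings(self) -> np.ndarray:
        return np.asarray(self.label_names)[self.labels]

    def time_mask(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for the half-open time interval [t0, t1)."""
        t0, t1 = interval
        return (self.times >= t0 - 1e-9) & (self.times < t1 - 1e-9)

    def copy(self, **changes) -> "EpochsSet":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


def save_epochs(e: EpochsSet, path: str | Path) -> None:
    """Write an :class:`EpochsSet` to the self-describing HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=e.data.astype(np.float32),
                         track_times=False)
        dl = f.create_dataset("labels", data=e.labels.astype(np.int8),
                              track_times=False)
        dl.attrs["label_names"] = list(e.label_names)
        f.create_dataset("times", data=e.times.astype(np.float64),
                         track_times=False)
        f.attrs["sfreq"] = float(e.sfreq)
        f.attrs["subject_id"] = e.subject_id
        f.attrs["phase"] = e.phase
        g = f.create_group("montage")
        g.create_dataset("names", data=list(e.montage.channel_names),
                         track_times=False)
        g.create_dataset("pos", data=e.montage.positions, track_times=False)
        g.create_dataset("regions", data=list(e.montage.regions),
                         track_times=False)


def load_epochs(path: str | Path) -> EpochsSet:
    """Read a container written by :func:`save_epochs`.

    Raises
    ------
    FormatError
        Naming the missing dataset/attribute or the shape inconsistency.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "times"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '/{name}'")
        if "montage" not in f:
            raise FormatError(f"{path}: missing group '/montage'")
        for name in ("names", "pos", "regions"):
            if name not in f["montage"]:
                raise FormatError(f"{path}: missing dataset '/montage/{name}'")
        for attr in ("sfreq", "subject_id", "phase"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
        if "label_names" not in f["labels"].attrs:
            raise FormatError(
                f"{path}: missing attribute 'label_names' on /labels"
            )
        data = f["data"][()]
        labels = f["labels"][()]
        times = f["times"][()]
        label_names = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f["labels"].attrs["label_names"]
        )
        names = tuple(s.decode() for s in f["montage/names"][()])
        pos = f["montage/pos"][()]
        regions = tuple(s.decode() for s in f["montage/regions"][()])
        montage = Montage(names, pos, regions)
        try:
            return EpochsSet(
                data=data, sfreq=float(f.attrs["sfreq"]), times=times,
                labels=labels, label_names=label_names, montage=montage,
                subject_id=str(f.attrs["subject_id"]),
                phase=str(f.attrs["phase"]),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
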