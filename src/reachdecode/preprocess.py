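"""Continuous-signal conditioning and epoch construction.

The conditioning chain is linear detrend → zero-phase 4th-order Butterworth
band-pass (1–60 Hz) → zero-phase notch (50 Hz, Q = 30).  Zero-phase
(forward–backward) filtering is used so no latency shift corrupts the
interval-aligned relevance analysis downstream.  Epochs are cut around the
go events, baseline-corrected against the 1 s pre-cue interval, re-referenced
to the common average, and decimated to 128 Hz behind an order-8 anti-alias
low-pass.

Bad-channel detection, ICA artifact removal and channel interpolation that a
real-data pipeline would run between conditioning and epoching are out of
scope here (the synthetic data are artifact-free); ``condition`` accepts an
optional ``hook`` callable marking where they would sit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import signal

from .containers import TARGETS, EpochsSet
from .montage import Montage


class EpochError(RuntimeError):
    """An epoch window falls outside the recording."""


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording with per-trial event times.

    ``events`` is a ``(n_trials, 3)`` float array of times in seconds:
    columns are (cue, go_forward, go_backward).  The cue precedes the
    forward go by exactly 2 s.
    """

    data: np.ndarray          # (channels, samples), microvolt
    sfreq: float
    events: np.ndarray        # (trials, 3): cue, go_forward, go_backward
    labels: np.ndarray        # (trials,) int codes into label_names
    montage: Montage
    label_names: tuple[str, ...] = TARGETS
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.events.ndim != 2 or self.events.shape[1] != 3:
            raise ValueError("events must be (trials, 3)")
        if len(self.labels) != len(self.events):
            raise ValueError("labels length must equal trial count")
        cue, go_f, go_b = self.events.T
        if not np.all(np.diff(self.events, axis=1) > 0):
            raise ValueError("events must increase within each trial")
        if not np.allclose(go_f - cue, 2.0, atol=1e-6):
            raise ValueError("cue must precede the forward go by exactly 2 s")

    @property
    def n_trials(self) -> int:
        return len(self.events)


def condition(
    raw: ContinuousEEG,
    band: tuple[float, float] = (1.0, 60.0),
    notch: float = 50.0,
    notch_q: float = 30.0,
    hook: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ContinuousEEG:
    """Detrend, band-pass and notch-filter a continuous recording.

    ``hook``, if given, is applied to the conditioned (channels × samples)
    array before returning — the slot where artifact handling for real
    recordings would go.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if raw.sfreq <= 2 * hi:
        raise ValueError(
            f"band upper edge {hi} Hz requires sfreq > {2 * hi} Hz, "
            f"got {raw.sfreq}"
        )
    x = signal.detrend(raw.data.astype(np.float64), axis=1, type="linear")
    sos = signal.butter(4, band, btype="bandpass", fs=raw.sfreq, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    if notch is not None:
        bn, an = signal.iirnotch(notch, notch_q, fs=raw.sfreq)
        x = signal.filtfilt(bn, an, x, axis=1)
    if hook is not None:
        x = hook(x)
    return replace(raw, data=x.astype(np.float32))


#: Epoch windows in seconds relative to the phase's go event: [start, end).
EPOCH_WINDOWS = {"forward": (-3.0, 2.0), "backward_prep": (-2.0, 0.0)}


def make_epochs(c: ContinuousEEG, phase: str = "forward") -> EpochsSet:
    """Cut per-trial epochs around the forward or backward go signal."""
    if phase not in EPOCH_WINDOWS:
        raise ValueError(f"phase must be one of {tuple(EPOCH_WINDOWS)}")
    t0, t1 = EPOCH_WINDOWS[phase]
    n_samp = int(round((t1 - t0) * c.sfreq))
    go_col = 1 if phase == "forward" else 2
    starts = np.round((c.events[:, go_col] + t0) * c.sfreq).astype(int)
    bad = [
        int(i) for i, s in enumerate(starts)
        if s < 0 or s + n_samp > c.data.shape[1]
    ]
    if bad:
        raise EpochError(
            f"epoch window outside recording for trial(s) {bad}"
        )
    data = np.stack(
        [c.data[:, s:s + n_samp] for s in starts]
    ).astype(np.float32)
    times = t0 + np.arange(n_samp) / c.sfreq
    return EpochsSet(
        data=data, sfreq=c.sfreq, times=times, labels=c.labels.copy(),
        label_names=c.label_names, montage=c.montage,
        subject_id=c.subject_id, phase=phase,
    )


def baseline_means(
    e: EpochsSet, baseline: tuple[float, float] = (-3.0, -2.0)
) -> np.ndarray:
    """Per-trial, per-channel mean over the baseline interval."""
    mask = e.time_mask(baseline)
    if not mask.any():
        raise ValueError(f"baseline {baseline} outside epoch span")
    return e.data[:, :, mask].mean(axis=2)


def baseline_correct(
    e: EpochsSet,
    baseline: tuple[float, float] = (-3.0, -2.0),
    external_baseline: np.ndarray | None = None,
) -> EpochsSet:
    """Subtract the per-trial/channel baseline mean from every sample.

    Backward-preparation epochs do not contain the baseline interval; for
    those, pass ``external_baseline`` — the (trials, channels) means taken
    from the corresponding forward epochs.
    """
    if external_baseline is not None:
        means = np.asarray(external_baseline)
        if means.shape != e.data.shape[:2]:
            raise ValueError(
                f"external_baseline must be (trials, channels) = "
                f"{e.data.shape[:2]}, got {means.shape}"
            )
    else:
        means = baseline_means(e, baseline)
    data = e.data - means[:, :, None].astype(e.data.dtype)
    return e.copy(data=data)


def car_downsample(e: EpochsSet, target_sfreq: float = 128.0) -> EpochsSet:
    """Common-average re-reference, then decimate to ``target_sfreq``.

    Decimation applies a zero-phase order-8 Chebyshev-I anti-alias low-pass
    before subsampling.  The decimation factor must be an integer.
    """
    factor = e.sfreq / target_sfreq
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"sfreq {e.sfreq} is not an integer multiple of {target_sfreq}"
        )
    factor = int(round(factor))
    data = e.data.astype(np.float64)
    data -= data.mean(axis=1, keepdims=True)  # CAR: channel mean -> 0
    if factor > 1:
        data = signal.decimate(data, factor, axis=2, ftype="iir",
                               zero_phase=True)
    times = e.times[::factor]
    return EpochsSet(
        data=data.astype(np.float32), sfreq=target_sfreq, times=times,
        labels=e.labels.copy(), label_names=e.label_names,
        montage=e.montage, subject_id=e.subject_id, phase=e.phase,
    )


def preprocess_epochs(
    forward_raw: EpochsSet,
    backward_raw: EpochsSet | None = None,
    target_sfreq: float = 128.0,
) -> tuple[EpochsSet, EpochsSet | None]:
    """Baseline-correct + CAR/downsample already-epoched raw data.

    Backward epochs are corrected with the forward trials' baselines, as
    they contain no baseline interval of their own.
    """
    fw_means = baseline_means(forward_raw)
    fw = baseline_correct(forward_raw)
    fw = car_downsample(fw, target_sfreq)
    bw = None
    if backward_raw is not None:
        bw = baseline_correct(backward_raw, external_baseline=fw_means)
        bw = car_downsample(bw, target_sfreq)
    return fw, bw
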