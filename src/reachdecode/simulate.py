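"""Synthetic delayed center-out-reaching EEG cohorts with known ground truth.

Signal model
------------
Each channel is a sum of three parts, generated at the acquisition rate
(512 Hz) so the preprocessing stage is genuinely exercised:

* **1/f background**: Gaussian noise spectrally shaped as ``1/f**exponent``,
  independent per channel.
* **Alpha rhythm** (10 Hz) and **beta rhythm** (20 Hz): one coherent
  oscillator per band — regional generators reach the electrodes through
  volume conduction at near-zero lag, so channels share the carrier phase
  and differ in amplitude topography (alpha posterior-weighted, beta
  central-weighted).  The carrier runs continuously; because inter-trial
  rest durations are randomized, its phase at any event is effectively
  random, so trial averages contain no phase-locked (evoked) component.

The envelopes follow the classical ERD/ERS sequence around each trial's
events (interval-wise constant gains joined by 100 ms cosine ramps, which
avoids filter ringing at interval edges):

* cue ERS — posterior amplitude gain > 1 in the 0.5 s after the cue;
* preparation ERD — posterior/central gain < 1 from cue+0.5 s to the go;
* execution ERD — central, left-lateralized gain < 1 during the movement.

Direction information is injected into the *preparation* ERD only: its
depth on posterior channels varies linearly with the target's azimuth,
through a hemispheric interaction (left targets ⇒ deeper right-posterior
ERD and vice versa), a scalp-common azimuth gradient, and a weaker
eccentricity gradient (see :func:`class_prep_gain_map`).  Execution ERD is
identical across classes, so the execution interval is deliberately
uninformative — the contrast that the occlusion analysis is designed to
detect.  Backward
preparation epochs reuse the trial's class with the same preparation-type
structure and no cue-locked component (the backward go brings no new
visual information about the class).

Every injected gain and channel weight map is recorded in a
:class:`GroundTruth` ledger so recovery tests can compare what the analysis
finds against what was put in.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .containers import TARGETS, EpochsSet
from .montage import Montage, standard_60_montage
from .preprocess import ContinuousEEG, make_epochs

ALPHA_HZ = 10.0
BETA_HZ = 20.0
RAMP_S = 0.10  # cosine ramp between envelope plateaus

#: left-to-right position score per target, in TARGETS order
TARGET_SCORES = np.linspace(-1.0, 1.0, 5)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate the study's structure.

    Amplitudes are in microvolt.  ``direction_effect`` scales the
    class-dependent lateralization of the preparation ERD; 0 makes the five
    classes statistically indistinguishable.
    """

    n_subjects: int = 20
    trials_per_target: int = 60
    sfreq_raw: float = 512.0
    noise_exponent: float = 1.0
    noise_amp: float = 4.0
    alpha_amp: float = 8.0
    beta_amp: float = 4.0
    cue_ers_gain: float = 1.5
    prep_erd_gain: float = 0.55
    exec_erd_gain: float = 0.50
    direction_effect: float = 0.6
    effect_jitter: float = 0.0
    rest_range_s: tuple[float, float] = (2.0, 3.0)
    movement_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_target < 2:
            raise ValueError("trials_per_target must be >= 2")
        for name in ("cue_ers_gain", "prep_erd_gain", "exec_erd_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.direction_effect < 0:
            raise ValueError("direction_effect must be >= 0")


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests.

    ``class_prep_gain`` holds the per-class, per-channel preparation-ERD
    amplitude gain actually applied (n_classes × n_channels); the
    direction information lives entirely in its variation across classes.
    Intervals are (start, end) in seconds relative to the forward go.
    """

    class_prep_gain: np.ndarray
    cue_gain_map: np.ndarray        # per-channel cue-ERS amplitude gain
    exec_gain_map: np.ndarray       # per-channel execution-ERD gain
    informative_interval: tuple[float, float]
    uninformative_interval: tuple[float, float]
    cue_interval: tuple[float, float]
    band_centers_hz: tuple[float, float] = (ALPHA_HZ, BETA_HZ)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                exponent: float, amp: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with unit-RMS scaled to ``amp``."""
    if amp == 0:
        # keep the RNG stream aligned whether or not noise is audible
        rng.standard_normal((n_ch, n_samp))
        return np.zeros((n_ch, n_samp), dtype=np.float32)
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    n_fft = next_fast_len(n_samp)
    f = rfftfreq(n_fft)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.empty((n_ch, n_samp), dtype=np.float32)
    for c0 in range(0, n_ch, 8):  # chunk channels to bound memory
        white = rng.standard_normal((min(8, n_ch - c0), n_samp))
        spec = rfft(white, n=n_fft, axis=1)
        spec *= shape
        x = irfft(spec, n=n_fft, axis=1)[:, :n_samp]
        rms = x.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        out[c0:c0 + white.shape[0]] = amp * x / rms
    return out


def _gaussian_weight(montage: Montage, center: tuple[float, float],
                     width: float) -> np.ndarray:
    """Spatial profile in [0, 1] peaking at ``center`` on the 2-D scalp."""
    d2 = ((montage.positions - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * width ** 2))


def _topographies(montage: Montage) -> dict[str, np.ndarray]:
    """Fixed spatial profiles used by the generator (all in [0, 1])."""
    posterior = _gaussian_weight(montage, (0.0, -0.75), 0.45)
    central = _gaussian_weight(montage, (0.0, 0.0), 0.55)
    central_left = _gaussian_weight(montage, (-0.35, 0.0), 0.5)
    return {
        "alpha": 0.35 + 0.65 * posterior,     # alpha strongest posteriorly
        "beta": 0.35 + 0.65 * central,        # beta strongest centrally
        "posterior": posterior,
        "central": central,
        "central_left": central_left,
    }


#: relative weight of the scalp-common azimuth-linear ERD gradient
AZIMUTH_MIX = 0.6
#: relative weight of the eccentricity (|azimuth|) ERD gradient
ECCENTRICITY_MIX = 0.4


def class_prep_gain_map(cfg: SimulationConfig, montage: Montage,
                        direction_effect: float | None = None) -> np.ndarray:
    """Preparation-ERD amplitude gain per (class, channel).

    The per-channel gain is ``prep_erd_gain ** w_post(i)`` (posterior
    channels carry the full ERD) modulated by a linear function of the
    target's azimuth score s(c) in [-1, 1]:

        1 + direction_effect * w_post(i) * (lat(i) * s  +  0.6 * s
                                            + 0.4 * (|s| - 0.5))

    i.e. a hemispheric interaction (left targets deepen right-posterior
    ERD and vice versa), a scalp-common azimuth gradient, and a weaker
    eccentricity gradient separating lateral from intermediate targets.
    ``lat`` is the signed left–right channel coordinate.
    """
    de = cfg.direction_effect if direction_effect is None else direction_effect
    topo = _topographies(montage)
    w_post = topo["posterior"]
    lat = montage.lateralization()
    base = cfg.prep_erd_gain ** w_post            # in (prep_erd_gain, 1]
    s = TARGET_SCORES[:, None]
    grad = (lat[None, :] * s + AZIMUTH_MIX * s
            + ECCENTRICITY_MIX * (np.abs(s) - 0.5))
    mod = 1.0 + de * w_post[None, :] * grad
    return np.clip(base[None, :] * mod, 0.05, 2.0)


def simulate_continuous(
    cfg: SimulationConfig, subject_id: str = "S00",
    rng: np.random.Generator | None = None,
) -> tuple[ContinuousEEG, GroundTruth]:
    """Generate one subject's continuous 512 Hz recording with events.

    Trial timeline (per trial): 2–3 s rest (uniform, trial RNG), cue,
    2 s preparation, forward go, ``movement_s`` execution, 2 s backward
    preparation, backward go, ``movement_s`` backward movement, 0.5 s tail.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    montage = standard_60_montage()
    n_ch = montage.n_channels
    sf = cfg.sfreq_raw
    n_trials = 5 * cfg.trials_per_target

    # balanced, shuffled label sequence
    labels = np.repeat(np.arange(5), cfg.trials_per_target)
    rng.shuffle(labels)

    rests = rng.uniform(*cfg.rest_range_s, size=n_trials)
    # events per trial, relative to trial start
    cue_off, go_f_off = rests, rests + 2.0
    go_b_off = go_f_off + cfg.movement_s + 2.0
    trial_len = go_b_off + cfg.movement_s + 0.5
    starts = np.concatenate([[1.0], 1.0 + np.cumsum(trial_len[:-1])])
    n_samp = int(round((starts[-1] + trial_len[-1] + 1.0) * sf))
    events = np.column_stack(
        [starts + cue_off, starts + go_f_off, starts + go_b_off]
    )

    topo = _topographies(montage)
    jitter = 1.0 + cfg.effect_jitter * rng.standard_normal()
    de = max(cfg.direction_effect * jitter, 0.0)
    prep_gain = class_prep_gain_map(cfg, montage, direction_effect=de)
    cue_gain = cfg.cue_ers_gain ** topo["posterior"]
    exec_gain = cfg.exec_erd_gain ** topo["central_left"]

    # amplitude envelopes per band, (channels, samples), start at 1
    env = {b: np.ones((n_ch, n_samp), dtype=np.float32)
           for b in ("alpha", "beta")}
    ramp_n = int(round(RAMP_S * sf))

    def paint(target: np.ndarray, t0: float, t1: float,
              gains: np.ndarray) -> None:
        """Multiply [t0, t1) by per-channel gains with cosine ramps."""
        i0, i1 = int(round(t0 * sf)), int(round(t1 * sf))
        i0, i1 = max(i0, 0), min(i1, n_samp)
        if i1 <= i0:
            return
        seg = np.ones(i1 - i0, dtype=np.float32)
        k = min(ramp_n, (i1 - i0) // 2)
        if k > 0:
            up = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
            seg[:k] = up
            seg[-k:] = up[::-1]
        target[:, i0:i1] *= 1.0 + (gains[:, None].astype(np.float32) - 1.0) * seg

    for tr in range(n_trials):
        cue_t, go_f, go_b = events[tr]
        g_prep = prep_gain[labels[tr]]
        for b in ("alpha", "beta"):
            paint(env[b], cue_t, cue_t + 0.5, cue_gain)
            paint(env[b], cue_t + 0.5, go_f, g_prep)
            paint(env[b], go_f, go_f + cfg.movement_s, exec_gain)
            # backward preparation: direction-coded ERD, no cue transient
            paint(env[b], go_b - 2.0, go_b, g_prep)
            paint(env[b], go_b, go_b + cfg.movement_s, exec_gain)

    data = _pink_noise(rng, n_ch, n_samp, cfg.noise_exponent, cfg.noise_amp)
    chunk = 1 << 19  # synthesize carriers in sample chunks to bound memory
    for b, f0, amp in (("alpha", ALPHA_HZ, cfg.alpha_amp),
                       ("beta", BETA_HZ, cfg.beta_amp)):
        # one coherent carrier per band: a regional generator seen through
        # volume conduction is near-zero-lag across electrodes, so channels
        # share the oscillator phase and differ only in amplitude topography
        phase = rng.uniform(0, 2 * np.pi)
        w = (amp * topo[b]).astype(np.float32)[:, None]
        for s0 in range(0, n_samp, chunk):
            s1 = min(s0 + chunk, n_samp)
            t = np.arange(s0, s1, dtype=np.float64) / sf
            carrier = np.cos(2 * np.pi * f0 * t + phase).astype(
                np.float32)[None, :]
            data[:, s0:s1] += env[b][:, s0:s1] * (w * carrier)
    del env

    truth = GroundTruth(
        class_prep_gain=prep_gain,
        cue_gain_map=cue_gain,
        exec_gain_map=exec_gain,
        informative_interval=(-1.5, 0.0),
        uninformative_interval=(0.0, cfg.movement_s),
        cue_interval=(-2.0, -1.5),
    )
    cont = ContinuousEEG(
        data=data, sfreq=sf, events=events, labels=labels,
        montage=montage, label_names=TARGETS, subject_id=subject_id,
    )
    return cont, truth


def simulate_subject(
    cfg: SimulationConfig, subject_id: str = "S00",
    rng: np.random.Generator | None = None,
) -> tuple[EpochsSet, EpochsSet, GroundTruth]:
    """One subject's raw (unpreprocessed, 512 Hz) forward and backward epochs.

    Forward epochs span [−3, +2) s around the forward go; backward epochs
    span [−2, 0) s before the backward go.  Deterministic for a fixed seed.
    """
    cont, truth = simulate_continuous(cfg, subject_id, rng=rng)
    forward = make_epochs(cont, "forward")
    backward = make_epochs(cont, "backward_prep")
    return forward, backward, truth


def subject_rng(cfg: SimulationConfig, index: int) -> np.random.Generator:
    """Deterministic per-subject generator derived from the cohort seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(index,))
    )


def simulate_cohort(
    cfg: SimulationConfig, n_subjects: int | None = None,
) -> list[tuple[EpochsSet, EpochsSet, GroundTruth]]:
    """Simulate ``n_subjects`` independent subjects (default from config).

    Subject seeds are spawned deterministically from ``cfg.seed``; subjects
    share the effect structure (up to ``effect_jitter``) but differ in
    realized noise, rhythm phases and trial order.
    """
    n = cfg.n_subjects if n_subjects is None else n_subjects
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for i in range(n):
        out.append(
            simulate_subject(cfg, subject_id=f"S{i:02d}", rng=subject_rng(cfg, i))
        )
    return out


def cohort_manifest(cfg: SimulationConfig, n_subjects: int | None = None) -> dict:
    """JSON-serializable record of the cohort's configuration and seeds."""
    n = cfg.n_subjects if n_subjects is None else n_subjects
    d = asdict(cfg)
    d["rest_range_s"] = list(cfg.rest_range_s)
    return {
        "config": d,
        "subjects": [f"S{i:02d}" for i in range(n)],
        "subject_seed_spawn": [[cfg.seed, i] for i in range(n)],
    }
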