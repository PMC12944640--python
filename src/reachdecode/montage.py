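"""60-channel 10–10 scalp montage with 2-D projected positions and region labels.

The montage mirrors a 60-electrode active-cap layout (ground at AFz, which is
therefore absent from the channel set).  Electrode coordinates come from the
standard 10–05 template positions and are azimuthally projected onto the unit
disc, so ``positions`` are unitless with head radius 1 and Cz at the origin.

Channels are partitioned into three scalp regions used throughout the
analysis — frontal, central, and parietal–occipital — by label prefix:

* ``Fp*``, ``AF*``, ``F*`` (but not ``FC*``/``FT*``) → ``frontal``
* ``FC*``, ``FT*``, ``C*``, ``CP*``, ``TP*``, ``T*`` → ``central``
* ``P*``, ``PO*``, ``O*`` → ``parietal_occipital``

The rule is overridable by passing an explicit region mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("frontal", "central", "parietal_occipital")

#: The 60 channel labels, ordered front to back, left to right.
STANDARD_60_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

# Prefix rules checked longest-first so FC/FT/CP/TP/PO beat F/C/P/T/O.
_PREFIX_REGIONS = (
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("FC", "central"),
    ("FT", "central"),
    ("CP", "central"),
    ("TP", "central"),
    ("PO", "parietal_occipital"),
    ("F", "frontal"),
    ("C", "central"),
    ("T", "central"),
    ("P", "parietal_occipital"),
    ("O", "parietal_occipital"),
)


def region_for_channel(name: str) -> str:
    """Region label for a single 10–10 channel name (prefix rule)."""
    for prefix, region in _PREFIX_REGIONS:
        if name.startswith(prefix):
            return region
    raise ValueError(f"cannot assign a region to channel {name!r}")


@dataclass(frozen=True)
class Montage:
    """Channel names, projected 2-D positions and region assignment.

    Attributes
    ----------
    channel_names
        Unique channel labels.
    positions
        ``(n_channels, 2)`` array; azimuthal-equidistant projection of the
        scalp sphere with Cz at the origin, nose along +y, radius 1 at the
        equatorial ring.  Unitless.
    regions
        Per-channel region label, one of :data:`REGIONS`.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(names), 2):
            raise ValueError(
                f"positions must be ({len(names)}, 2), got {self.positions.shape}"
            )
        if len(self.regions) != len(names):
            raise ValueError("regions must cover every channel")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def region_channels(self, region: str) -> list[int]:
        """Indices of all channels carrying ``region``.

        Raises
        ------
        ValueError
            If ``region`` is not one of :data:`REGIONS`.
        """
        if region not in REGIONS:
            raise ValueError(
                f"unknown region {region!r}; expected one of {REGIONS}"
            )
        return [i for i, r in enumerate(self.regions) if r == region]

    def lateralization(self) -> np.ndarray:
        """Signed left–right coordinate per channel, scaled to [-1, 1].

        Negative = left hemisphere, positive = right, 0 on the midline.
        Used by the synthetic generator to lateralize effects.
        """
        x = self.positions[:, 0]
        return x / np.abs(x).max()


def _project_azimuthal(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of head-frame 3-D points to 2-D.

    Points are first centred and normalized to the unit sphere; the polar
    angle from the vertex (Cz direction, +z) becomes the radius, normalized
    so the equator maps to radius 1.
    """
    centered = pos3d - pos3d.mean(axis=0, keepdims=True)
    # Re-centre on the sphere best fitting the electrode cloud: the template
    # positions are already roughly head-centred, so the centroid suffices.
    r = np.linalg.norm(centered, axis=1, keepdims=True)
    unit = centered / r
    polar = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # angle from vertex
    azim = np.arctan2(unit[:, 1], unit[:, 0])
    rad = polar / (np.pi / 2.0)
    return np.column_stack([rad * np.cos(azim), rad * np.sin(azim)])


import functools


@functools.lru_cache(maxsize=1)
def standard_60_montage() -> Montage:
    """Build the default 60-channel 10–10 montage.

    3-D template coordinates are taken from the standard 10–05 electrode
    position set and projected to 2-D.  Deterministic; the instance is
    cached (treat it as read-only).
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        # template renamed upstream; either name carries the same coordinates
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [n for n in STANDARD_60_NAMES if n not in ch_pos]
    if missing:  # pragma: no cover - template always carries 10-10 labels
        raise RuntimeError(f"template montage lacks channels: {missing}")
    pos3d = np.array([ch_pos[n] for n in STANDARD_60_NAMES], dtype=float)
    pos2d = _project_azimuthal(pos3d)
    regions = tuple(region_for_channel(n) for n in STANDARD_60_NAMES)
    return Montage(STANDARD_60_NAMES, pos2d, regions)


def region_channels(montage: Montage, region: str) -> list[int]:
    """Functional alias for :meth:`Montage.region_channels`."""
    return montage.region_channels(region)
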