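"""Core data model: channel layouts, trials, windows and muscle-set selection.

A recording session is organised as labelled trials: one steady-state,
multi-channel surface-EMG recording per (motion class, wrist position,
repetition).  Four hand postures are recognised (rest, hand open, key grip,
chuck grip), each performed in seven wrist positions.  Electrodes fall into
two groups: *extrinsic* channels on the forearm (muscles crossing the wrist,
hence modulated by wrist posture) and *intrinsic* channels on the hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Closed set of recognisable hand postures.
MOTION_CLASSES: tuple[str, ...] = ("rest", "open", "key", "chuck")

#: Closed set of wrist positions in the recording protocol.
WRIST_POSITIONS: tuple[str, ...] = (
    "neutral",
    "flexion",
    "extension",
    "pronation",
    "supination",
    "abduction",
    "adduction",
)

CHANNEL_GROUPS: tuple[str, ...] = ("extrinsic", "intrinsic")
MUSCLE_SETS: tuple[str, ...] = ("extrinsic", "intrinsic", "combined")


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered electrode montage with a muscle group per channel.

    Parameters
    ----------
    channel_ids
        Ordered channel labels, e.g. ``("ext1", ..., "int4")``.
    groups
        Muscle group per channel, each ``"extrinsic"`` or ``"intrinsic"``,
        aligned with ``channel_ids``.
    sampling_rate
        Sampling rate in Hz (> 0).
    """

    channel_ids: tuple[str, ...]
    groups: tuple[str, ...]
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_ids) == 0:
            raise ValueError("layout needs at least one channel")
        if len(self.channel_ids) != len(self.groups):
            raise ValueError("channel_ids and groups must have equal length")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        bad = set(self.groups) - set(CHANNEL_GROUPS)
        if bad:
            raise ValueError(f"unknown channel group(s): {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def channels_in_group(self, group: str) -> tuple[str, ...]:
        if group not in CHANNEL_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return tuple(
            cid for cid, g in zip(self.channel_ids, self.groups) if g == group
        )

    def subset(self, channel_ids: Sequence[str]) -> "ChannelLayout":
        """Layout restricted to ``channel_ids`` (original order preserved)."""
        keep = [cid for cid in self.channel_ids if cid in set(channel_ids)]
        idx = {cid: g for cid, g in zip(self.channel_ids, self.groups)}
        return ChannelLayout(
            channel_ids=tuple(keep),
            groups=tuple(idx[c] for c in keep),
            sampling_rate=self.sampling_rate,
        )


@dataclass(frozen=True)
class MuscleSet:
    """A named channel subset: extrinsic, intrinsic, or their union."""

    name: str
    channel_ids: tuple[str, ...]

    @classmethod
    def resolve(cls, name: str, layout: ChannelLayout) -> "MuscleSet":
        if name not in MUSCLE_SETS:
            raise ValueError(f"unknown muscle set {name!r}; choose from {MUSCLE_SETS}")
        if name == "combined":
            channels = layout.channel_ids
        else:
            channels = layout.channels_in_group(name)
        if not channels:
            raise ValueError(f"layout has no {name!r} channels")
        return cls(name=name, channel_ids=channels)


@dataclass(frozen=True)
class Trial:
    """One labelled steady-state EMG recording.

    ``signal`` is a (channels, samples) float array in millivolt-scale
    arbitrary units; rows follow ``layout.channel_ids``.
    """

    subject_id: str
    motion_class: str
    wrist_position: str
    repetition: int
    signal: np.ndarray
    layout: ChannelLayout

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(
                f"motion_class {self.motion_class!r} not in {MOTION_CLASSES}"
            )
        if self.wrist_position not in WRIST_POSITIONS:
            raise ValueError(
                f"wrist_position {self.wrist_position!r} not in {WRIST_POSITIONS}"
            )
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be a 2-D (channels, samples) array")
        if sig.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"signal has {sig.shape[0]} channels, layout has "
                f"{self.layout.n_channels}"
            )
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.layout.sampling_rate


@dataclass(frozen=True)
class Window:
    """A fixed-length multi-channel segment cut from a trial.

    Inherits all trial labels; ``start_offset`` is the 0-based sample index
    of the window start within its trial.
    """

    data: np.ndarray  # (channels, L)
    subject_id: str
    motion_class: str
    wrist_position: str
    repetition: int
    start_offset: int
    layout: ChannelLayout = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def window_count(n_samples: int, window_len: int, increment: int) -> int:
    """Number of complete sliding windows: ``floor((N - L)/inc) + 1``."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // increment + 1


def segment_windows(
    trial: Trial, window_ms: float = 200.0, increment_ms: float = 20.0
) -> list[Window]:
    """Cut a trial into overlapping analysis windows.

    Windows of ``window_ms`` duration start at offsets 0, inc, 2*inc, ...
    (``increment_ms`` frame increment); incomplete trailing windows are
    discarded so every window has identical length.

    Raises
    ------
    ValueError
        If the trial is shorter than one window.
    """
    fs = trial.layout.sampling_rate
    L = int(round(window_ms * fs / 1000.0))
    inc = int(round(increment_ms * fs / 1000.0))
    if L < 1 or inc < 1:
        raise ValueError("window and increment must span at least one sample")
    n = trial.n_samples
    if n < L:
        raise ValueError(
            f"trial of {n} samples is shorter than one {L}-sample window"
        )
    count = window_count(n, L, inc)
    out = []
    for k in range(count):
        start = k * inc
        out.append(
            Window(
                data=trial.signal[:, start : start + L],
                subject_id=trial.subject_id,
                motion_class=trial.motion_class,
                wrist_position=trial.wrist_position,
                repetition=trial.repetition,
                start_offset=start,
                layout=trial.layout,
            )
        )
    return out


def select_muscle_set(trials: Sequence[Trial], set_name: str) -> list[Trial]:
    """Restrict every trial to the channels of one muscle set.

    Channel order is preserved and sample values are untouched.
    """
    if not trials:
        return []
    layout = trials[0].layout
    mset = MuscleSet.resolve(set_name, layout)
    if mset.channel_ids == layout.channel_ids:
        return list(trials)
    idx = [layout.channel_ids.index(c) for c in mset.channel_ids]
    sub_layout = layout.subset(mset.channel_ids)
    return [
        replace(t, signal=t.signal[idx, :], layout=sub_layout) for t in trials
    ]
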