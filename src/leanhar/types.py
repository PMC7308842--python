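"""Core data containers shared across the pipeline.

The pipeline moves through three representations:

``SensorRecording``
    one subject x device: synchronized tri-axial accelerometer (and
    optionally gyroscope / magnetometer) series with per-sample labels.
``ChannelBundle``
    the derived per-device channel set after gravity/motion decomposition:
    3 raw acceleration, 3 AC (dynamic), 3 DC (gravitational) channels, plus
    the untouched gyroscope / magnetometer channels.
``WindowedSignal``
    a single fixed-length segment of one channel carrying its majority
    activity label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: Body locations the readers and the synthetic generator know about.
DEVICE_LOCATIONS = ("ankle", "chest", "hip", "wrist", "lower_arm")

#: Fixed ordering of channel kinds inside a bundle; feature-matrix columns
#: follow this order so schemas are stable across runs.
CHANNEL_KINDS = ("acc", "ac", "dc", "gyro", "mag")

AXES = ("x", "y", "z")


def _as_3xt(name: str, arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.shape[0] != 3:
        raise ValueError(f"{name} must be a 3 x T array, got shape {a.shape}")
    return a


@dataclass
class SensorRecording:
    """One subject x device recording of synchronized labelled series."""

    subject_id: str
    device_location: str
    sampling_rate_hz: float
    acc: np.ndarray                     # (3, T)
    labels: np.ndarray                  # (T,) integer activity codes
    gyro: Optional[np.ndarray] = None   # (3, T)
    mag: Optional[np.ndarray] = None    # (3, T)

    def __post_init__(self) -> None:
        if self.device_location not in DEVICE_LOCATIONS:
            raise ValueError(
                f"unknown device location {self.device_location!r}; "
                f"expected one of {DEVICE_LOCATIONS}"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.acc = _as_3xt("acc", self.acc)
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.shape[0] != self.acc.shape[1]:
            raise ValueError("labels must be 1-D with the same length as acc")
        for name in ("gyro", "mag"):
            arr = getattr(self, name)
            if arr is not None:
                arr = _as_3xt(name, arr)
                if arr.shape[1] != self.acc.shape[1]:
                    raise ValueError(f"{name} length differs from acc length")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class ChannelBundle:
    """Per-device derived channels: raw acc, AC, DC (+ gyro / mag).

    AC is the dynamic (body-motion) component and DC the gravitational one;
    by construction ``ac + dc == acc`` elementwise, so a bundle carries 12
    channels when a gyroscope is present (3 raw + 3 AC + 3 DC + 3 gyro).
    """

    subject_id: str
    device_location: str
    sampling_rate_hz: float
    acc: np.ndarray
    ac: np.ndarray
    dc: np.ndarray
    labels: np.ndarray
    gyro: Optional[np.ndarray] = None
    mag: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    def channels(self, include_gyro: bool = True,
                 include_mag: bool = False) -> Iterator[tuple[str, np.ndarray]]:
        """Yield ``(channel_id, series)`` in the canonical, stable order."""
        for kind in CHANNEL_KINDS:
            if kind == "gyro" and not include_gyro:
                continue
            if kind == "mag" and not include_mag:
                continue
            block = getattr(self, kind)
            if block is None:
                if kind in ("gyro", "mag"):
                    continue
                raise ValueError(f"bundle is missing required channels {kind!r}")
            for axis, series in zip(AXES, block):
                yield f"{kind}_{axis}", series


@dataclass
class WindowedSignal:
    """One fixed-length segment of one channel with its activity label."""

    x: np.ndarray
    label: object
    subject_id: str = ""
    channel_id: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValueError("window must be a 1-D vector")

    @property
    def n(self) -> int:
        return self.x.shape[0]
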