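"""Readers for delimited-text sensor datasets.

A :class:`DatasetLayout` maps file columns to devices and channels, so any
per-subject delimited-text dump can be loaded by describing it rather than
writing a parser. Layouts for the public DaLiAc and mHealth directory
structures ship with the package.

DaLiAc caveat: the per-sensor column order inside the raw files is not
standardized across mirrors of the dataset; the shipped layout assumes
blocks of (acc x,y,z, gyro x,y,z) per sensor in the order wrist, chest,
hip, ankle with the label in the last column. If your copy differs, pass a
corrected :class:`DatasetLayout` — it is plain data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import SensorRecording

__all__ = [
    "DeviceColumns",
    "DatasetLayout",
    "DALIAC_LAYOUT",
    "MHEALTH_LAYOUT",
    "read_recording",
    "load_dataset",
]


@dataclass(frozen=True)
class DeviceColumns:
    """0-based column indices of one device's channels in a file."""

    location: str
    acc: tuple[int, int, int]
    gyro: tuple[int, int, int] | None = None
    mag: tuple[int, int, int] | None = None


@dataclass(frozen=True)
class DatasetLayout:
    """How a dataset directory maps onto recordings."""

    name: str
    sampling_rate_hz: float
    devices: tuple[DeviceColumns, ...]
    label_column: int
    file_glob: str
    subject_pattern: str          # regex with one group capturing the subject id
    delimiter: str | None = None  # None = any whitespace
    has_header: bool = False
    drop_labels: tuple = ()       # e.g. mHealth's null class 0
    recommended_stride: int = 1   # decimation stride to reach 51.2 Hz


def _block(start: int) -> tuple[int, int, int]:
    return (start, start + 1, start + 2)


#: DaLiAc: 19 subjects, 4 inertial sensors (acc + gyro each) at 204.8 Hz
#: (hence the recommended stride of 4 to reach 51.2 Hz), label in the last
#: column. See the module docstring for the column-order caveat.
DALIAC_LAYOUT = DatasetLayout(
    name="daliac",
    sampling_rate_hz=204.8,
    devices=(
        DeviceColumns("wrist", acc=_block(0), gyro=_block(3)),
        DeviceColumns("chest", acc=_block(6), gyro=_block(9)),
        DeviceColumns("hip", acc=_block(12), gyro=_block(15)),
        DeviceColumns("ankle", acc=_block(18), gyro=_block(21)),
    ),
    label_column=24,
    file_glob="dataset_*.txt",
    subject_pattern=r"dataset_(\d+)",
    delimiter=",",
    recommended_stride=4,
)

#: mHealth: 10 subjects at 50 Hz; chest carries acceleration (+ECG, ignored),
#: ankle and lower arm carry acc + gyro + mag; label 0 marks the null class
#: and is dropped on read.
MHEALTH_LAYOUT = DatasetLayout(
    name="mhealth",
    sampling_rate_hz=50.0,
    devices=(
        DeviceColumns("chest", acc=_block(0)),
        DeviceColumns("ankle", acc=_block(5), gyro=_block(8), mag=_block(11)),
        DeviceColumns("lower_arm", acc=_block(14), gyro=_block(17), mag=_block(20)),
    ),
    label_column=23,
    file_glob="mHealth_subject*.log",
    subject_pattern=r"mHealth_subject(\d+)",
    delimiter=None,
    drop_labels=(0,),
)

LAYOUTS = {"daliac": DALIAC_LAYOUT, "mhealth": MHEALTH_LAYOUT}


def read_recording(path, layout: DatasetLayout, device: DeviceColumns,
                   subject_id: str | None = None) -> SensorRecording:
    """Read one device's channels of one subject file."""
    path = Path(path)
    if subject_id is None:
        m = re.search(layout.subject_pattern, path.name)
        subject_id = m.group(1) if m else path.stem
    df = pd.read_csv(
        path,
        sep=layout.delimiter if layout.delimiter is not None else r"\s+",
        header=0 if layout.has_header else None,
        engine="python" if layout.delimiter is None else "c",
    )
    data = df.to_numpy()
    labels = data[:, layout.label_column].astype(int)
    keep = ~np.isin(labels, layout.drop_labels) if layout.drop_labels else slice(None)

    def _take(cols):
        if cols is None:
            return None
        return data[:, list(cols)].T[:, keep].astype(float)

    return SensorRecording(
        subject_id=str(subject_id),
        device_location=device.location,
        sampling_rate_hz=layout.sampling_rate_hz,
        acc=_take(device.acc),
        gyro=_take(device.gyro),
        mag=_take(device.mag),
        labels=labels[keep],
    )


def load_dataset(directory, layout: DatasetLayout,
                 devices: Sequence[str] | None = None) -> list[SensorRecording]:
    """Load every subject file in a directory into per-device recordings."""
    directory = Path(directory)
    files = sorted(directory.glob(layout.file_glob))
    if not files:
        raise FileNotFoundError(
            f"no files matching {layout.file_glob!r} under {directory}"
        )
    recordings = []
    for path in files:
        for device in layout.devices:
            if devices is not None and device.location not in devices:
                continue
            recordings.append(read_recording(path, layout, device))
    return recordings
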