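"""Raw-signal preprocessing: decimation, gravity/motion decomposition,
per-recording normalization and overlapping-window segmentation.

The default processing chain mirrors the lean pipeline this package
implements: decompose each acceleration axis into a gravitational (DC,
first-order Butterworth low-pass at 2 Hz, zero-phase) and a dynamic (AC =
raw - DC) component, decimate every channel by literal stride sampling (no
anti-alias filter by default, e.g. 204.8 Hz -> 51.2 Hz with stride 4),
z-score each channel over the whole recording, and cut 5-s windows with 50%
overlap (N = 256 samples at 51.2 Hz).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .types import ChannelBundle, SensorRecording, WindowedSignal

__all__ = [
    "PipelineConfig",
    "decimate",
    "decompose_acc",
    "normalize",
    "segment",
    "window_starts",
    "majority_label",
    "preprocess",
    "window_bundle",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable preprocessing parameters.

    decimation_stride
        keep every ``stride``-th sample (1 = no decimation). DaLiAc's
        204.8 Hz recordings use stride 4 to reach 51.2 Hz.
    cutoff_hz / filter_order
        Butterworth low-pass isolating the gravitational component.
    window_seconds / overlap
        segmentation; 5 s with 0.5 overlap gives N = 256 at 51.2 Hz.
    drop_mixed_windows
        discard windows whose per-sample labels are not unanimous instead
        of majority-voting them.
    anti_alias
        low-pass before decimating; off by default (the reference pipeline
        subsamples literally).
    normalize
        z-score each channel over the recording after decimation.
    """

    decimation_stride: int = 1
    cutoff_hz: float = 2.0
    filter_order: int = 1
    window_seconds: float = 5.0
    overlap: float = 0.5
    drop_mixed_windows: bool = False
    anti_alias: bool = False
    normalize: bool = True

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_seconds * fs))


def decimate(series: np.ndarray, stride: int, anti_alias: bool = False,
             fs: float | None = None) -> np.ndarray:
    """Keep every ``stride``-th sample: ``out[i] = series[i * stride]``.

    Output length is ``ceil(T / stride)``. By default this is literal
    subsampling with no anti-alias filter. With ``anti_alias=True`` a
    zero-phase 8th-order Chebyshev low-pass at 0.8 x the new Nyquist is
    applied first (``fs`` is then required only for documentation purposes;
    the cutoff is expressed as a fraction of the input rate).
    """
    if int(stride) != stride or stride < 1:
        raise ValueError(f"stride must be a positive integer, got {stride!r}")
    stride = int(stride)
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return series[:0]
    if stride == 1:
        return series.copy()
    if anti_alias:
        sos = _sig.cheby1(8, 0.05, 0.8 / stride, output="sos")
        series = _sig.sosfiltfilt(sos, series)
    return series[::stride].copy()


def decompose_acc(acc_channel: np.ndarray, fs: float, cutoff_hz: float = 2.0,
                  filter_order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Split one acceleration axis into (dc, ac) components.

    ``dc`` is the gravitational component: a zero-phase (forward-backward)
    Butterworth low-pass of the given order and cutoff. ``ac`` is obtained
    by subtraction, ``ac = acc - dc``, so ``ac + dc`` reconstructs the raw
    signal exactly.
    """
    acc_channel = np.asarray(acc_channel, dtype=float)
    if not fs > 2.0 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the cutoff "
            f"({cutoff_hz} Hz) for the low-pass to be realizable"
        )
    b, a = _sig.butter(filter_order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if acc_channel.size <= padlen:
        raise ValueError(
            f"series of length {acc_channel.size} is too short for "
            f"zero-phase filtering (needs > {padlen} samples)"
        )
    dc = _sig.filtfilt(b, a, acc_channel)
    ac = acc_channel - dc
    return dc, ac


def normalize(series: np.ndarray) -> np.ndarray:
    """Z-score a channel: ``(x - mean) / std`` (population std).

    A zero-variance channel normalizes to all zeros rather than raising, so
    degenerate (perfectly static) inputs pass through the pipeline.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("normalize requires at least 2 samples")
    sd = series.std()
    if sd == 0:
        return np.zeros_like(series)
    return (series - series.mean()) / sd


def window_starts(n_samples: int, window_samples: int, overlap: float) -> np.ndarray:
    """Start indices of full windows: multiples of ``round(N*(1-overlap))``."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(window_samples * (1.0 - overlap)))
    step = max(step, 1)
    if n_samples < window_samples:
        return np.empty(0, dtype=int)
    count = (n_samples - window_samples) // step + 1
    return np.arange(count) * step


def majority_label(labels: np.ndarray):
    """Majority vote; ties resolved toward the earliest-occurring label."""
    labels = np.asarray(labels)
    values, first_index, counts = np.unique(
        labels, return_index=True, return_counts=True
    )
    best = counts.max()
    contenders = counts == best
    return values[contenders][np.argmin(first_index[contenders])]


def segment(series: np.ndarray, labels: np.ndarray, window_samples: int,
            overlap_fraction: float, drop_mixed: bool = False,
            subject_id: str = "", channel_id: str = "") -> list[WindowedSignal]:
    """Cut a labelled series into overlapping fixed-length windows.

    Windows start at multiples of ``round(N * (1 - overlap))``; a trailing
    partial window is discarded; a series shorter than one window yields an
    empty list. Each window carries the majority label of its samples.
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != series.shape[0]:
        raise ValueError("labels must align with the series")
    out: list[WindowedSignal] = []
    for start in window_starts(series.shape[0], window_samples, overlap_fraction):
        win_labels = labels[start:start + window_samples]
        if drop_mixed and np.unique(win_labels).size > 1:
            continue
        out.append(
            WindowedSignal(
                x=series[start:start + window_samples],
                label=majority_label(win_labels),
                subject_id=subject_id,
                channel_id=channel_id,
                start=int(start),
            )
        )
    return out


def preprocess(recording: SensorRecording,
               config: PipelineConfig = PipelineConfig()) -> ChannelBundle:
    """Turn a raw recording into a normalized, decomposed channel bundle.

    Order of operations: decompose acceleration at the native rate, decimate
    every channel (labels included) by stride sampling, then z-score each
    channel over the recording.
    """
    fs_in = recording.sampling_rate_hz
    stride = config.decimation_stride
    fs_out = fs_in / stride

    dc = np.empty_like(recording.acc)
    ac = np.empty_like(recording.acc)
    for i in range(3):
        dc[i], ac[i] = decompose_acc(
            recording.acc[i], fs_in, config.cutoff_hz, config.filter_order
        )

    def _dec_block(block):
        if block is None:
            return None
        return np.stack(
            [decimate(ch, stride, config.anti_alias) for ch in block]
        )

    acc_d = _dec_block(recording.acc)
    ac_d = _dec_block(ac)
    dc_d = _dec_block(dc)
    gyro_d = _dec_block(recording.gyro)
    mag_d = _dec_block(recording.mag)
    labels_d = recording.labels[::stride].copy()

    if config.normalize:
        def _norm_block(block):
            if block is None:
                return None
            return np.stack([normalize(ch) for ch in block])
        acc_d, ac_d, dc_d, gyro_d, mag_d = (
            _norm_block(acc_d), _norm_block(ac_d), _norm_block(dc_d),
            _norm_block(gyro_d), _norm_block(mag_d),
        )

    return ChannelBundle(
        subject_id=recording.subject_id,
        device_location=recording.device_location,
        sampling_rate_hz=fs_out,
        acc=acc_d, ac=ac_d, dc=dc_d,
        gyro=gyro_d, mag=mag_d,
        labels=labels_d,
    )


def window_bundle(bundle: ChannelBundle, config: PipelineConfig = PipelineConfig(),
                  include_gyro: bool = True, include_mag: bool = False):
    """Window every channel of a bundle on a shared grid.

    Returns ``(channel_windows, labels, starts)`` where ``channel_windows``
    is an ordered mapping ``channel_id -> (n_windows, N) array``; all
    channels share the same starts and window labels.
    """
    n = config.window_samples(bundle.sampling_rate_hz)
    starts = window_starts(bundle.n_samples, n, config.overlap)
    keep = np.ones(starts.shape[0], dtype=bool)
    labels = []
    for j, start in enumerate(starts):
        win_labels = bundle.labels[start:start + n]
        if config.drop_mixed_windows and np.unique(win_labels).size > 1:
            keep[j] = False
            labels.append(None)
        else:
            labels.append(majority_label(win_labels))
    starts = starts[keep]
    labels = np.asarray([l for l, k in zip(labels, keep) if k])

    channel_windows: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for channel_id, series in bundle.channels(include_gyro, include_mag):
        channel_windows[channel_id] = np.stack(
            [series[s:s + n] for s in starts]
        ) if starts.size else np.empty((0, n))
    return channel_windows, labels, starts
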