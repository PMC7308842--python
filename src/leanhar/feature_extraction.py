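"""The compact per-window feature set: 20 time-domain and 5 frequency-domain
statistics per channel.

Time domain (20): mean, population standard deviation, population skewness,
non-excess kurtosis, the 13 percentiles [0, 5, 10, 20, 30, 40, 50, 60, 70,
80, 90, 95, 100], range, RMS, and the zero-crossing count of the
mean-subtracted signal.

Frequency domain (5), computed on the one-sided amplitude spectrum
``xhat[xi] = |DFT(x - mean(x))[xi]|`` for bins xi = 0..N/2:

* energy            E = sum(xhat^2)
* spectral entropy  H = -sum(p log2 p) / log2(N/2), with p = xhat/sum(xhat)
* spectral centroid c = sum(xi * p)                     (bin-index units)
* spectral bandwidth b = sum(|xi - c| * p)
* max frequency     argmax(xhat), ties to the lowest bin

An all-zero spectrum (constant window) takes the convention
E = H = c = b = max_frequency = 0.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_pipeline import PipelineConfig, window_bundle
from .types import ChannelBundle, DEVICE_LOCATIONS, WindowedSignal

__all__ = [
    "PERCENTILES",
    "FEATURE_NAMES",
    "AmplitudeSpectrum",
    "amplitude_spectrum",
    "time_features",
    "freq_features",
    "window_features",
    "FeatureMatrix",
    "build_feature_matrix",
    "bin_to_hz",
    "MissingDeviceError",
]

PERCENTILES = (0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 100)

FEATURE_NAMES: tuple[str, ...] = (
    "mean", "std", "skewness", "kurtosis",
    *[f"p{q}" for q in PERCENTILES],
    "range", "rms", "zero_crossings",
    "energy", "entropy", "centroid", "bandwidth", "max_frequency",
)
assert len(FEATURE_NAMES) == 25


class MissingDeviceError(KeyError):
    """A requested device location is absent from the data."""


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a mean-subtracted window."""

    xhat: np.ndarray   # (N/2 + 1,) nonnegative amplitudes
    n: int             # source window length N

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.n // 2 + 1)

    @property
    def p(self) -> np.ndarray:
        """Normalized spectrum xhat / sum(xhat); zeros if the mass is zero."""
        s = self.xhat.sum()
        if s == 0:
            return np.zeros_like(self.xhat)
        return self.xhat / s


def amplitude_spectrum(x) -> AmplitudeSpectrum:
    """Absolute one-sided DFT of the mean-subtracted window (even N >= 2)."""
    if isinstance(x, WindowedSignal):
        x = x.x
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2 or n % 2 != 0:
        raise ValueError(f"window length must be even and >= 2, got {n}")
    centered = x - x.mean(axis=-1, keepdims=True)
    xhat = np.abs(np.fft.rfft(centered, axis=-1))
    return AmplitudeSpectrum(xhat=xhat, n=n)


def bin_to_hz(bin_index, n: int, fs: float):
    """Convert a spectral bin index (0..N/2) to Hz for a given window."""
    return np.asarray(bin_index, dtype=float) * fs / n


# -- batch kernels -----------------------------------------------------------

def _time_features_batch(windows: np.ndarray) -> np.ndarray:
    """(n_windows, N) -> (n_windows, 20), vectorized over windows."""
    w = np.asarray(windows, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    n = w.shape[1]
    if n < 2:
        raise ValueError("windows must have at least 2 samples")

    mean = w.mean(axis=1)
    centered = w - mean[:, None]
    m2 = (centered ** 2).mean(axis=1)
    m3 = (centered ** 3).mean(axis=1)
    m4 = (centered ** 4).mean(axis=1)
    std = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2, 0.0)

    pct = np.percentile(w, PERCENTILES, axis=1).T   # (n, 13), linear interp
    rng = w.max(axis=1) - w.min(axis=1)
    rms = np.sqrt((w ** 2).mean(axis=1))

    zc = np.empty(w.shape[0])
    for i in range(w.shape[0]):
        s = np.sign(centered[i])
        s = s[s != 0]
        zc[i] = 0 if s.size < 2 else np.count_nonzero(s[1:] != s[:-1])

    return np.column_stack([mean, std, skew, kurt, pct, rng, rms, zc])


def _freq_features_batch(xhat: np.ndarray, n: int) -> np.ndarray:
    """(n_windows, N/2+1) amplitude spectra -> (n_windows, 5)."""
    xhat = np.asarray(xhat, dtype=float)
    if xhat.ndim == 1:
        xhat = xhat[None, :]
    bins = np.arange(xhat.shape[1], dtype=float)

    energy = (xhat ** 2).sum(axis=1)
    total = xhat.sum(axis=1)
    nonzero = total > 0
    p = np.zeros_like(xhat)
    p[nonzero] = xhat[nonzero] / total[nonzero, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = np.where(nonzero, -plogp.sum(axis=1) / np.log2(n / 2), 0.0)
    centroid = (bins * p).sum(axis=1)
    bandwidth = (np.abs(bins[None, :] - centroid[:, None]) * p).sum(axis=1)
    max_freq = np.where(nonzero, np.argmax(xhat, axis=1), 0).astype(float)

    return np.column_stack([energy, entropy, centroid, bandwidth, max_freq])


# -- public single-window surface -------------------------------------------

def time_features(x) -> np.ndarray:
    """The 20 time-domain statistics of one window, in FEATURE_NAMES order."""
    if isinstance(x, WindowedSignal):
        x = x.x
    return _time_features_batch(np.asarray(x, dtype=float)[None, :])[0]


def freq_features(s: AmplitudeSpectrum) -> np.ndarray:
    """The 5 spectral statistics: energy, entropy, centroid, bandwidth,
    max-frequency bin."""
    return _freq_features_batch(s.xhat, s.n)[0]


def window_features(windows: np.ndarray) -> np.ndarray:
    """All 25 features for a batch of windows: (n_windows, N) -> (n_windows, 25)."""
    w = np.asarray(windows, dtype=float)
    single = w.ndim == 1
    if single:
        w = w[None, :]
    spectra = amplitude_spectrum(w)
    feats = np.column_stack([
        _time_features_batch(w),
        _freq_features_batch(spectra.xhat, spectra.n),
    ])
    return feats[0] if single else feats


# -- feature matrices --------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x features matrix with a stable, documented column schema.

    Columns are ordered by (device, channel kind, axis, feature); each name
    is ``device|channel|feature`` (e.g. ``ankle|ac_z|entropy``).
    """

    X: np.ndarray
    columns: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def select(self, devices: Sequence[str] | None = None,
               include_gyro: bool = True,
               include_mag: bool = True) -> "FeatureMatrix":
        """Column subset restricted to given devices / channel kinds."""
        keep_idx, keep_cols = [], []
        for j, name in enumerate(self.columns):
            device, channel, _ = name.split("|")
            kind = channel.rsplit("_", 1)[0]
            if devices is not None and device not in devices:
                continue
            if kind == "gyro" and not include_gyro:
                continue
            if kind == "mag" and not include_mag:
                continue
            keep_idx.append(j)
            keep_cols.append(name)
        if devices is not None:
            present = {c.split("|")[0] for c in keep_cols}
            missing = [d for d in devices if d not in present]
            if missing:
                raise MissingDeviceError(
                    f"devices {missing} absent from the feature matrix"
                )
        return FeatureMatrix(
            X=self.X[:, keep_idx], columns=keep_cols,
            labels=self.labels, subject_ids=self.subject_ids,
            config=dict(self.config),
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the matrix as CSV plus a JSON sidecar with the schema."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)
        if sidecar:
            meta = {"columns": self.columns, "config": self.config,
                    "n_rows": int(self.X.shape[0])}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2)
            )


def _canonical_device_order(locations: Iterable[str]) -> list[str]:
    order = {loc: i for i, loc in enumerate(DEVICE_LOCATIONS)}
    return sorted(set(locations), key=lambda loc: order[loc])


def build_feature_matrix(bundles: Sequence[ChannelBundle],
                         devices: Sequence[str] | None = None,
                         include_gyro: bool = True,
                         include_mag: bool = False,
                         config: PipelineConfig = PipelineConfig()) -> FeatureMatrix:
    """Assemble one feature row per window across the selected devices.

    Every subject must supply all requested devices, windowed identically
    (same length, same labels); per-subject rows concatenate the per-device
    channel features side by side.
    """
    by_subject: dict[str, dict[str, ChannelBundle]] = {}
    for b in bundles:
        by_subject.setdefault(b.subject_id, {})[b.device_location] = b
    if devices is None:
        devices = _canonical_device_order(
            loc for devs in by_subject.values() for loc in devs
        )
    else:
        devices = list(devices)

    rows, labels, subjects = [], [], []
    columns: list[str] | None = None
    for subject_id, devs in by_subject.items():
        missing = [d for d in devices if d not in devs]
        if missing:
            raise MissingDeviceError(
                f"subject {subject_id!r} is missing device(s) {missing}"
            )
        per_device_blocks = []
        subject_cols: list[str] = []
        ref_labels = None
        for device in devices:
            channel_windows, win_labels, _ = window_bundle(
                devs[device], config, include_gyro, include_mag
            )
            if ref_labels is None:
                ref_labels = win_labels
            elif (len(win_labels) != len(ref_labels)
                  or not np.array_equal(win_labels, ref_labels)):
                raise ValueError(
                    f"subject {subject_id!r}: devices are not windowed "
                    "identically (different counts or labels)"
                )
            for channel_id, wins in channel_windows.items():
                per_device_blocks.append(window_features(wins))
                subject_cols.extend(
                    f"{device}|{channel_id}|{feat}" for feat in FEATURE_NAMES
                )
        if columns is None:
            columns = subject_cols
        elif columns != subject_cols:
            raise ValueError("bundles have inconsistent channel sets")
        if ref_labels is None or len(ref_labels) == 0:
            continue
        rows.append(np.hstack(per_device_blocks))
        labels.append(np.asarray(ref_labels))
        subjects.append(np.repeat(subject_id, len(ref_labels)))

    if not rows:
        raise ValueError("no windows produced: recordings shorter than one window?")
    return FeatureMatrix(
        X=np.vstack(rows),
        columns=list(columns),
        labels=np.concatenate(labels),
        subject_ids=np.concatenate(subjects),
        config={
            "devices": list(devices),
            "include_gyro": include_gyro,
            "include_mag": include_mag,
            "window_seconds": config.window_seconds,
            "overlap": config.overlap,
            "cutoff_hz": config.cutoff_hz,
            "filter_order": config.filter_order,
            "decimation_stride": config.decimation_stride,
        },
    )
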