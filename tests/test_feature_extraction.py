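"""The 25-feature set against independent brute-force references."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leanhar as lh
from leanhar.feature_extraction import FEATURE_NAMES, bin_to_hz

from oracles import (
    naive_dft_amplitude,
    naive_freq_features,
    naive_time_features,
    naive_two_sided_power,
)

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


class TestAmplitudeSpectrum:
    def test_pure_tone_peaks_at_its_bin(self):
        n, k = 256, 17
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        s = lh.amplitude_spectrum(x)
        assert int(np.argmax(s.xhat)) == k

    def test_constant_window_has_empty_spectrum(self):
        s = lh.amplitude_spectrum(np.full(64, 2.5))
        assert np.max(s.xhat) < 1e-10

    def test_matches_naive_dft(self, rng):
        x = rng.normal(size=64)
        np.testing.assert_allclose(
            lh.amplitude_spectrum(x).xhat, naive_dft_amplitude(x), atol=1e-8
        )

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            lh.amplitude_spectrum(np.zeros(63))

    def test_bin_zero_vanishes_by_mean_subtraction(self, rng):
        s = lh.amplitude_spectrum(rng.normal(size=128) + 42.0)
        assert s.xhat[0] < 1e-9
        assert abs(s.p.sum() - 1.0) < 1e-12


class TestTimeFeatures:
    def test_constant_window(self):
        f = lh.time_features(np.full(256, -3.0))
        assert f[IDX["mean"]] == -3.0
        assert f[IDX["std"]] == 0.0
        assert f[IDX["range"]] == 0.0
        assert f[IDX["rms"]] == pytest.approx(3.0)
        assert f[IDX["zero_crossings"]] == 0

    def test_alternating_signal(self):
        x = np.tile([-1.0, 1.0], 128)
        f = lh.time_features(x)
        assert f[IDX["zero_crossings"]] == 255
        assert f[IDX["rms"]] == pytest.approx(1.0)
        assert f[IDX["range"]] == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=256) * rng.uniform(0.1, 10)
            np.testing.assert_allclose(
                lh.time_features(x), naive_time_features(x), atol=1e-10
            )

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=64))
    def test_percentile_edges(self, values):
        x = np.asarray(values)
        f = lh.time_features(x)
        assert f[IDX["p0"]] == x.min()
        assert f[IDX["p100"]] == x.max()
        assert f[IDX["p50"]] == pytest.approx(np.median(x))
        pct = f[IDX["p0"]:IDX["p100"] + 1]
        assert np.all(np.diff(pct) >= 0)


class TestFreqFeatures:
    def _spec(self, xhat, n):
        return lh.AmplitudeSpectrum(xhat=np.asarray(xhat, float), n=n)

    def test_point_mass(self):
        xhat = np.zeros(129)
        xhat[37] = 2.0
        e, h, c, b, mf = lh.freq_features(self._spec(xhat, 256))
        assert e == pytest.approx(4.0)
        assert h == pytest.approx(0.0)
        assert c == pytest.approx(37.0)
        assert b == pytest.approx(0.0)
        assert mf == 37

    def test_uniform_spectrum_closed_form(self):
        e, h, c, b, mf = lh.freq_features(self._spec(np.ones(129), 256))
        assert h == pytest.approx(np.log2(129) / np.log2(128))
        assert c == pytest.approx(64.0)
        assert mf == 0  # ties resolve to the lowest bin

    def test_two_equal_peaks(self):
        xhat = np.zeros(129)
        xhat[10] = xhat[20] = 1.0
        _, _, c, b, mf = lh.freq_features(self._spec(xhat, 256))
        assert c == pytest.approx(15.0)
        assert b == pytest.approx(5.0)
        assert mf == 10

    def test_zero_spectrum_convention(self):
        np.testing.assert_array_equal(
            lh.freq_features(self._spec(np.zeros(129), 256)), np.zeros(5)
        )

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            xhat = np.abs(rng.normal(size=33))
            np.testing.assert_allclose(
                lh.freq_features(self._spec(xhat, 64)),
                naive_freq_features(xhat, 64), atol=1e-10,
            )

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e3), min_size=9, max_size=9))
    def test_bounds(self, amps):
        n = 16
        e, h, c, b, mf = lh.freq_features(self._spec(np.asarray(amps), n))
        assert 0 <= h <= np.log2(n / 2 + 1) / np.log2(n / 2) + 1e-12
        assert 0 <= c <= n / 2
        assert 0 <= b <= n / 2
        assert mf in range(n // 2 + 1)

    def test_parseval_energy_vs_variance(self, rng):
        # two-sided spectral power equals N * sum of squared deviations
        x = rng.normal(size=32)
        n = len(x)
        centered = x - x.mean()
        assert naive_two_sided_power(x) == pytest.approx(
            n * np.sum(centered ** 2), rel=1e-10
        )

    def test_hz_conversion_helper(self):
        assert bin_to_hz(5, 256, 51.2) == pytest.approx(1.0)


class TestFeatureMatrix:
    def test_column_counts(self, features6):
        assert features6.shape[1] == 4 * 12 * 25  # 4 devices x 12 channels x 25
        one = features6.select(devices=["ankle"])
        assert one.shape[1] == 300
        acc_only = features6.select(devices=["ankle"], include_gyro=False)
        assert acc_only.shape[1] == 225

    def test_column_order_stable_and_documented(self, features6):
        assert features6.columns[0] == "ankle|acc_x|mean"
        assert features6.columns[24] == "ankle|acc_x|max_frequency"
        assert features6.columns[25] == "ankle|acc_y|mean"
        # devices in canonical order, features in declared order
        devices = list(dict.fromkeys(c.split("|")[0] for c in features6.columns))
        assert devices == ["ankle", "chest", "hip", "wrist"]

    def test_missing_device_raises(self, features6):
        with pytest.raises(lh.MissingDeviceError):
            features6.select(devices=["ankle", "lower_arm"])

    def test_extraction_is_pure(self, rng):
        w = rng.normal(size=(5, 256))
        a = lh.window_features(w)
        b = lh.window_features(w.copy())
        np.testing.assert_array_equal(a, b)

    def test_csv_roundtrip_with_sidecar(self, small_features, tmp_path):
        import pandas as pd

        path = tmp_path / "features.csv"
        small_features.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[2:]) == small_features.columns
        np.testing.assert_allclose(df.iloc[:, 2:].to_numpy(),
                                   small_features.X, rtol=1e-6)
        meta = json.loads((tmp_path / "features.csv.json").read_text())
        assert meta["columns"] == small_features.columns
        assert "overlap" in meta["config"]
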