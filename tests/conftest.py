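import warnings

import numpy as np
import pytest

import leanhar as lh

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def benchmark6() -> lh.SyntheticDataset:
    """The standard 6-subject, 4-device, 13-activity synthetic benchmark."""
    return lh.default_benchmark(6, seed=7, duration_s=30.0)


@pytest.fixture(scope="session")
def features6(benchmark6) -> lh.FeatureMatrix:
    """Feature matrix of the standard benchmark (all devices, gyro on)."""
    bundles = [lh.preprocess(r) for r in benchmark6.recordings]
    return lh.build_feature_matrix(bundles)


@pytest.fixture(scope="session")
def small_features() -> lh.FeatureMatrix:
    """A small 3-subject feature matrix for quick classifier tests."""
    ds = lh.default_benchmark(3, seed=11, duration_s=15.0)
    bundles = [lh.preprocess(r) for r in ds.recordings]
    return lh.build_feature_matrix(bundles)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
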