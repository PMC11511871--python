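import warnings

import numpy as np
import pytest

import eegrobust as er


@pytest.fixture(scope="session")
def labels8():
    return er.benchmarks.BENCHMARK_CHANNELS


@pytest.fixture(scope="session")
def small_cohort(labels8):
    """A tiny cohort (5+3 subjects) for fast structural tests."""
    cfg = er.CohortConfig(
        n_pos_subjects=5, n_neg_subjects=3, epochs_per_subject=3,
        channel_labels=labels8,
        signature=er.benchmarks.sparse_benchmark_signature(0.4), seed=11)
    return cfg, er.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    _, cohort = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return er.extract_features(cohort)


@pytest.fixture(scope="session")
def tiny_index():
    """3 channels x 2 frequencies = 12 features."""
    return er.FeatureIndex(channel_labels=("A", "B", "C"),
                           frequencies=(10.0, 20.0))


def _silence(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


@pytest.fixture(scope="session")
def trend_results():
    """Shared sweep on the sparse-signature benchmark cohort."""
    return _silence(er.benchmarks.trend_benchmark)


@pytest.fixture(scope="session")
def sirt_results():
    """Shared SIRT on/off comparison under heavy band nuisance."""
    return _silence(er.benchmarks.sirt_benchmark)


@pytest.fixture(scope="session")
def recovery_results():
    """Shared ground-truth recovery run."""
    return _silence(er.benchmarks.recovery_benchmark)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
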