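import numpy as np
import pytest

from mrsnmf import CohortConfig, LabelVector, SpectrumTable, default_lte_classes, simulate_cohort


def random_table(rng: np.random.Generator, d: int = 12, n: int = 6,
                 labels=None, mixed_sign: bool = True) -> SpectrumTable:
    """Small random spectra table for unit tests."""
    V = rng.normal(size=(d, n)) if mixed_sign else rng.random((d, n)) + 0.05
    ppm = np.linspace(4.0, 0.5, d)
    return SpectrumTable(ppm, V, [f"c{i}" for i in range(n)], labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture(scope="session")
def lte3_cohort():
    """A 3-class LTE-like cohort at the standard study conditions."""
    cfg = CohortConfig(classes=default_lte_classes()[:3], n_per_class=20,
                       dominance=0.8, noise_sd=0.005, seed=11)
    return simulate_cohort(config=cfg)


@pytest.fixture(scope="session")
def lte3_labels(lte3_cohort):
    return LabelVector(list(lte3_cohort.table.labels))
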