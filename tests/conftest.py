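import numpy as np
import pandas as pd
import pytest

from codawork.preprocess import complete_case_filter, preprocess
from codawork.simulate import DETERMINANTS, SimulationConfig, generate_dataset


def random_compositions(n: int, seed: int = 0) -> np.ndarray:
    """Strictly positive random three-part compositions (Dirichlet)."""
    rng = np.random.default_rng(seed)
    comps = rng.dirichlet([2.0, 2.0, 2.0], size=n)
    return np.clip(comps, 1e-9, None) / np.clip(comps, 1e-9, None).sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def default_dataset():
    """One study-sized simulated dataset (default config)."""
    cfg = SimulationConfig(seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def analysis_workers(default_dataset):
    workers, days = default_dataset
    analysis, _ = preprocess(workers, days)
    return analysis


@pytest.fixture(scope="session")
def complete_workers(analysis_workers):
    complete, _ = complete_case_filter(analysis_workers, DETERMINANTS)
    return complete
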