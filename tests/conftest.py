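import numpy as np
import pytest

from stabdim.climate import SeasonClassification


LAB = {"N": "normal", "D": "dry", "W": "wet"}


def make_classification(code: str, spei=None, cutoff=0.67, site="s", start=2001):
    """Build a season classification from a compact label string like 'NDWN'."""
    years = np.arange(start, start + len(code))
    labels = [LAB[c] for c in code]
    if spei is None:
        spei = [0.0 if l == "normal" else (-1.0 if l == "dry" else 1.0) for l in labels]
    return SeasonClassification(site, cutoff, years, labels, np.asarray(spei, dtype=float))


@pytest.fixture
def classification_factory():
    return make_classification


@pytest.fixture(scope="session")
def small_dataset():
    """One small noisy synthetic experiment shared across tests."""
    from stabdim.synthetic import SimulationConfig, gen_dataset

    config = SimulationConfig(n_sites=4, n_years_experiment=8, noise_sd=0.08, seed=11)
    return gen_dataset(config)
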