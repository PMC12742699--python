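import numpy as np
import pandas as pd
import pytest

from ncmorph import SynthConfig, generate_specimens, published_site_counts, sites_from_class_counts


@pytest.fixture(scope="session")
def small_synth():
    """A reduced two-species specimen set with known truth (fast stages)."""
    config = SynthConfig(nests=(12, 14), seed=11)
    records, truth = generate_specimens(config)
    return records, truth


@pytest.fixture(scope="session")
def default_synth():
    """The generator at its default study-design settings."""
    config = SynthConfig(seed=5)
    records, truth = generate_specimens(config)
    return records, truth


@pytest.fixture(scope="session")
def survey_sites():
    """Per-site table expanded from the published class-level counts."""
    return sites_from_class_counts(published_site_counts())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
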