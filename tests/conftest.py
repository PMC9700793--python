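import numpy as np
import pytest
from hypothesis import settings

from prsf.preprocess import dictionary_backend
from prsf.synthetic import default_pd_scenario, generate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_backend():
    """Exact dictionary backend for hand-traceable preprocessing."""
    return dictionary_backend(
        lemmas={"salto": "saltar", "veces": "vez", "corrio": "correr"},
        tags={"salto": "VERB", "corrio": "VERB", "saltar": "VERB", "correr": "VERB"},
        stopwords={"el", "la", "y"},
    )


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study at the default cohort sizes."""
    return generate_study(default_pd_scenario(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
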