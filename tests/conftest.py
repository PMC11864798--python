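import numpy as np
import pytest
from hypothesis import settings

from viewmatch.corpus import CorpusSpec, make_corpus
from viewmatch.models import StimulusDataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small rendered corpus shared across tests: 3 categories x 6 objects
    x 4 views at 24x24."""
    spec = CorpusSpec(
        n_categories=3,
        objects_per_category=6,
        views_per_object=4,
        resolution=(24, 24),
        seed=11,
    )
    stimuli, categories = make_corpus(spec)
    return stimuli, categories, spec


@pytest.fixture(scope="session")
def tiny_dataset(tiny_corpus):
    stimuli, categories, _ = tiny_corpus
    return StimulusDataset.from_stimuli(stimuli, categories)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
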