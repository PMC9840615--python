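import numpy as np
import pytest

from numprops.features import extract_dataset
from numprops.stimgen import generate_dataset, render_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def d1_run(tmp_path_factory):
    """Full D1-style set: pairs, rendered images, extracted features.

    Session-scoped because generation + rendering + extraction of 120 pairs
    is the suite's most expensive fixture.
    """
    pics = tmp_path_factory.mktemp("d1_pics")
    pairs = generate_dataset("D1", seed=7)
    stimlist = render_dataset(pairs, pics, seed=7)
    features = extract_dataset(stimlist, pics)
    return {"pairs": pairs, "stimlist": stimlist, "features": features,
            "pics": pics}


@pytest.fixture(scope="session")
def d2_run(tmp_path_factory):
    """Small D2-style set (36 pairs) for cheap end-to-end checks."""
    pics = tmp_path_factory.mktemp("d2_pics")
    pairs = generate_dataset("D2", seed=3)
    stimlist = render_dataset(pairs, pics, seed=3)
    features = extract_dataset(stimlist, pics)
    return {"pairs": pairs, "stimlist": stimlist, "features": features,
            "pics": pics}
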