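import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic planted-texture phantom case."""
    from dlrs.phantoms import PhantomSpec, generate_case

    spec = PhantomSpec(seed=7)
    return generate_case(spec, np.random.default_rng(7), case_id="fixture")


@pytest.fixture(scope="session")
def preprocessed_case(phantom_case):
    from dlrs.pipeline import PreprocessConfig, preprocess_case

    return preprocess_case(
        phantom_case.volume, phantom_case.mask, PreprocessConfig(), case_id="fixture"
    )


def random_label_image(rng, shape=(8, 8), max_bins=6, mask_density=0.85):
    """A random small LabelImage for oracle comparisons."""
    from dlrs.features import LabelImage

    nb = int(rng.integers(2, max_bins + 1))
    mask = rng.random(shape) < mask_density
    while mask.sum() < 4:
        mask = rng.random(shape) < mask_density
    labels = np.where(mask, rng.integers(1, nb + 1, size=shape), 0)
    return LabelImage(labels=labels, mask=mask, n_bins=nb)
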