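import numpy as np
import pytest

from tasksal import SyntheticConfig, generate_dataset
from tasksal.learning import compute_stacks


@pytest.fixture(scope="session")
def toy_dataset():
    """Small 2-category synthetic dataset shared across tests."""
    cfg = SyntheticConfig(
        n_images_per_category=4,
        categories=("car", "dog"),
        target_present_fraction=0.75,
        n_subjects=3,
        n_gaze_per_subject_per_image=15,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_stacks(toy_dataset):
    return compute_stacks(toy_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
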