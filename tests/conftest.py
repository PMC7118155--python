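import numpy as np
import pytest

from burntex import extract_feature_matrix, generate_dataset


@pytest.fixture(scope="session")
def phantom_dataset():
    """Default 4-class phantom dataset, 30 images per class, fixed seed."""
    manifest, images = generate_dataset(n_per_class=30, seed=0)
    return manifest, images


@pytest.fixture(scope="session")
def phantom_features(phantom_dataset):
    """19 default texture features of the session phantom dataset."""
    manifest, images = phantom_dataset
    return extract_feature_matrix(
        [images[k] for k, _ in manifest.entries],
        [lab for _, lab in manifest.entries],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
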