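"""Shared fixtures: phantom batches and a small trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model keeps the expensive fit out of individual tests.
"""

import numpy as np
import pytest

from shapenca import PhantomSpec, ShapeGuidedNCASegmenter, generate_dataset
from shapenca.preprocessing import PreprocConfig, preprocess_image


def make_phantom_arrays(n, seed, height=32, width=32, contrast=3.0, n_lesions=1,
                        radius_range=(4.0, 7.0)):
    spec = PhantomSpec(
        height=height, width=width, n_lesions=n_lesions, contrast=contrast,
        radius_range=radius_range, seed=0,
    )
    phantoms, manifest = generate_dataset(spec, n, seed=seed)
    cfg = PreprocConfig(target_size=(height, width))
    X = np.stack([preprocess_image(p.image, cfg) for p in phantoms])
    y = np.stack([p.mask for p in phantoms]).astype(np.float32)
    return X, y, manifest


@pytest.fixture(scope="session")
def phantom_batch():
    """24 preprocessed 32x32 phantoms with masks."""
    X, y, _ = make_phantom_arrays(24, seed=11)
    return X, y


@pytest.fixture(scope="session")
def trained_model(phantom_batch):
    """A small segmenter trained briefly on 32x32 phantoms."""
    X, y = phantom_batch
    model = ShapeGuidedNCASegmenter(
        n_hidden=6, hidden_width=12, n_levels=1, steps_coarse=4, steps_fine=4,
        n_segments=16, learning_rate=3e-3, max_epochs=25, steps_per_epoch=4,
        batch_size=4, random_state=0,
    )
    model.fit(X, y)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
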