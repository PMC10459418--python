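import numpy as np
import pytest

from tsidl.confmat import ConfusionMatrix
from tsidl.model import TrainConfig
from tsidl.synthetic import SynthParams, generate_dataset


def random_cm(rng: np.random.Generator, r: int | None = None, max_count: int = 50) -> ConfusionMatrix:
    r = r or int(rng.integers(2, 13))
    labels = tuple(f"c{k:02d}" for k in range(r))
    counts = rng.integers(0, max_count + 1, size=(r, r))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return ConfusionMatrix(labels, counts)


@pytest.fixture(scope="session")
def tiny_params() -> SynthParams:
    """A minute planted dataset for pipeline unit tests: 2 packages x 2
    classes, one planted lookalike pair, 12 images per class."""
    return SynthParams(
        n_packages=2,
        classes_per_package=2,
        planted_groups={0: ((0, 1),)},
        image_side=48,
        rotations=4,
        tilts=3,
        imprint_side=8,
        imprint_contrast=0.15,
        noise_sd=0.05,
        split_counts=(8, 2, 2),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_params):
    return generate_dataset(tiny_params)


@pytest.fixture(scope="session")
def quick_config() -> TrainConfig:
    return TrainConfig(learning_rate=0.05, batch_size=8, max_epochs=5, seed=3)
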