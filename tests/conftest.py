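import numpy as np
import pytest

from gelfeat.image_io import ImageDataset, ImageSample
from gelfeat.synthetic import GelClassSpec, GenConfig, generate_dataset


def make_dataset(arrays, labels):
    """Build an ImageDataset from (array, label) pairs with unique ids."""
    samples = [
        ImageSample(pixels=np.asarray(a, dtype=float), label=lab, id=f"{lab}/{i}")
        for i, (a, lab) in enumerate(zip(arrays, labels))
    ]
    return ImageDataset(samples=samples)


def random_dataset(rng, n_classes=2, per_class=5, shape=(8, 8)):
    """Unstructured random dataset (no class signal)."""
    arrays, labels = [], []
    for c in range(n_classes):
        for _ in range(per_class):
            arrays.append(rng.uniform(0, 1, size=shape))
            labels.append(f"c{c}")
    return make_dataset(arrays, labels)


@pytest.fixture(scope="session")
def gel_dataset_small():
    """4 gel states x 8 images, 32x32 — fast, clearly separable."""
    classes = tuple(
        GelClassSpec(
            label=f"s{i}",
            pore_density=4.0 + 12.0 * i,
            base_intensity=0.85 - 0.17 * i,
            pore_concentration=0.25 * i,
        )
        for i in range(4)
    )
    return generate_dataset(
        GenConfig(classes=classes, per_class=8, image_size=(32, 32), seed=1)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1)
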