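import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quick_result():
    """One full quick-mode experiment (simulate -> extract -> augment ->
    benchmark -> confidence), shared across the suite.  Seed fixed."""
    from rootclass.pipeline import RunConfig, run_experiment

    return run_experiment(RunConfig.quick(seed=0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small labeled trait dataset (8 roots per class, low resolution)
    for fast model-level tests."""
    from rootclass.evaluate import LabeledDataset
    from rootclass.synthetic_roots import generate_dataset
    from rootclass.traits import TRAIT_NAMES, batch_extract

    images, truths = generate_dataset({"B": 8, "T": 8, "TB": 8},
                                      px_per_mm_range=(3.0, 4.0), seed=7)
    table, failures = batch_extract(images)
    assert not failures
    labels = np.array([gt.label for gt in truths])
    return LabeledDataset(table[list(TRAIT_NAMES)], labels,
                          table["image_id"].tolist())


def bar_image(length_px=100, width_px=5, px_per_mm=10.0, pad=10):
    """Vertical bar foreground, used as an analytic-geometry oracle."""
    from rootclass.synthetic_roots import BinaryRootImage

    arr = np.zeros((length_px + 2 * pad, width_px + 2 * pad), dtype=bool)
    arr[pad:pad + length_px, pad:pad + width_px] = True
    return BinaryRootImage(arr, px_per_mm, "bar")
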