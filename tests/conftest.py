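import numpy as np
import pandas as pd
import pytest

from moanet.simulate import ModuleSpec, StudyDesign


@pytest.fixture
def design():
    return StudyDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ratio_frame(rng):
    """10 genes x 6 samples with 2 route batches, for centering tests."""
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    data = pd.DataFrame(rng.normal(size=(10, 6)), index=genes, columns=samples)
    batch = pd.Series(["a", "a", "a", "b", "b", "b"], index=samples)
    return data, batch


def make_modules(*sizes, loading=(0.5, 0.9), preserved=True):
    return [
        ModuleSpec(f"M{i + 1}", s, eigengene_loading_range=loading, preserved_in_test=preserved)
        for i, s in enumerate(sizes)
    ]
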