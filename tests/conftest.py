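import numpy as np
import pandas as pd
import pytest

from corecruit.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """A full-scale dataset at the default study conditions."""
    cfg = GeneratorConfig(seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = GeneratorConfig(n_regions=400, seed=7)
    return generate_dataset(cfg)


def array_profile(values, element_bp=800, chrom="chr1", prefix="e"):
    """Assemble an element-level array profile from a value vector."""
    n = len(values)
    return pd.DataFrame({
        "region_id": [f"{prefix}{i}" for i in range(n)],
        "chrom": chrom,
        "start": np.arange(n) * element_bp,
        "end": (np.arange(n) + 1) * element_bp,
        "value": np.asarray(values, dtype=float),
    })


@pytest.fixture
def make_array_profile():
    return array_profile
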