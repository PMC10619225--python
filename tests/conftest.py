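import numpy as np
import pytest

from hascad import SyntheticDesign, build_reference, generate_cells


@pytest.fixture(scope="session")
def small_cells():
    """Tiny 2-batch fixture for fast unit tests."""
    design = SyntheticDesign(
        n_batches=2,
        cells_per_type_per_batch=12,
        n_genes=300,
        batch_effect_sd=0.8,
        seed=11,
    )
    return generate_cells(design)


@pytest.fixture(scope="session")
def small_reference(small_cells):
    return build_reference(small_cells, n_top=128, d=12, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
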