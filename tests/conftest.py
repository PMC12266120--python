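import numpy as np
import pytest

from parabio_rescue.preprocess import normalize, qc_filter
from parabio_rescue.simulate import GeneratorParams, generate_dataset


SMALL_PARAMS = GeneratorParams(
    seed=0,
    n_cell_types=2,
    cells_per_group_per_type=80,
    n_genes=800,
    aging_genes_per_type=40,
    n_shared_aging_genes=4,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset: raw counts, annotation, ground truth."""
    return generate_dataset(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    """QC-filtered and normalized version of the small dataset."""
    cm, ann, truth = small_dataset
    cm, ann = qc_filter(cm, ann)
    cm = normalize(cm)
    return cm, ann, truth
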