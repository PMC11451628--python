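import numpy as np
import pytest
import scipy.sparse as sp

from psynmap.io import CellRecord, CountMatrix
from psynmap.synth import GenerativeParams, generate_study


@pytest.fixture(scope="session")
def default_study():
    """A 2+2-sample study under default generator conditions (~6k cells)."""
    params = GenerativeParams(n_samples_per_genotype=2, seed=7)
    return generate_study(params)


@pytest.fixture
def square_cell():
    return CellRecord(
        cell_id="c1", sample_id="s1", genotype="tg", sex="M", region="cortex",
        nucleus_centroid=(1.0, 1.0),
        polygon=np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]]),
    )


def make_counts(mat, gene_ids=None, panel=None, species=None, cell_ids=None):
    """Small dense-count CountMatrix builder for unit tests."""
    mat = np.asarray(mat)
    n, g = mat.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    return CountMatrix(
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids,
        counts=sp.csr_matrix(mat),
        panel=np.asarray(panel if panel is not None else ["base"] * g, dtype=object),
        species_tag=np.asarray(species if species is not None else ["mouse"] * g,
                               dtype=object),
    )


@pytest.fixture
def counts_builder():
    return make_counts
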