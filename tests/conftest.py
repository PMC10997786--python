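import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from metacourse.core_data import AnnotatedExpressionMatrix, TimeGrid
from metacourse.synthetic import SimConfig, simulate_timecourse


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulation shared across modules (3 types, 2 states)."""
    cfg = SimConfig(
        seed=7,
        n_cell_types=3,
        n_states_per_type=2,
        cells_per_type_day=40,
        n_genes=300,
        n_de_per_trend=3,
    )
    matrix, truth = simulate_timecourse(cfg)
    matrix.normalize()
    return matrix, truth


@pytest.fixture(scope="session")
def embedded_sim(small_sim):
    from metacourse.core_data import compute_embedding, select_hvgs

    matrix, truth = small_sim
    if matrix.embedding is None:
        hvgs = select_hvgs(matrix, 200)
        matrix.embedding = compute_embedding(matrix, hvgs, n_components=20)
    return matrix, truth


@pytest.fixture
def toy_matrix():
    """3 cells x 2 genes with full metadata, counts chosen by hand."""
    counts = sp.csr_matrix(np.array([[1, 2], [3, 0], [0, 5]]))
    meta = pd.DataFrame(
        {
            "cell_id": ["c0", "c1", "c2"],
            "sample_id": ["s0", "s0", "s1"],
            "patient_id": ["p0", "p0", "p1"],
            "day": [3, 3, 7],
            "cell_type": ["A", "A", "B"],
            "severity": ["mild", "mild", "severe"],
        }
    )
    return AnnotatedExpressionMatrix(
        counts=counts, cell_meta=meta, gene_ids=["g0", "g1"], time_grid=TimeGrid((3, 7))
    )
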