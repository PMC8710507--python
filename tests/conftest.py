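import numpy as np
import pytest

from glutme import (ExpressionMatrix, builtin_signature_collection,
                    generate_bulk_cohort, generate_sc_counts)


@pytest.fixture(scope="session")
def signatures():
    return builtin_signature_collection()


@pytest.fixture(scope="session")
def small_bulk():
    """60-sample bulk cohort with a strong planted immune effect."""
    return generate_bulk_cohort(n_samples=60, n_genes=200, immune_effect=8, seed=0)


SC_FIXTURE_ARGS = dict(
    n_cells=1200,
    type_proportions={"cancer": 0.3, "Tcell": 0.3, "Bcell": 0.2, "myeloid": 0.2},
    glut_effect=6, marker_effect=6, seed=0)


@pytest.fixture(scope="session")
def small_sc():
    """1200-cell four-type single-cell dataset with strong planted effects."""
    return generate_sc_counts(**SC_FIXTURE_ARGS)


@pytest.fixture
def tiny_counts():
    """3-gene x 4-observation counts matrix with hand-checkable values."""
    values = np.array([[1.0, 0.0, 5.0, 2.0],
                       [3.0, 2.0, 0.0, 2.0],
                       [0.0, 2.0, 5.0, 6.0]])
    return ExpressionMatrix(values, ["G1", "G2", "G3"],
                            ["s1", "s2", "s3", "s4"], "counts")
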