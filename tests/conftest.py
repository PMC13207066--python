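import numpy as np
import pandas as pd
import pytest

from cpcellsub import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
    SimulationSpec,
    log_normalize,
    simulate_scrna,
)


@pytest.fixture(scope="session")
def small_scrna():
    """Three subpopulations, 60 cells each, 400 genes, planted markers."""
    spec = SimulationSpec(
        seed=7, n_genes=400, n_subpops=3, n_cells_per_subpop=60,
        n_markers_per_subpop=20,
    )
    expr, ann, markers = simulate_scrna(spec)
    return expr, ann, markers


@pytest.fixture(scope="session")
def small_lognorm(small_scrna):
    expr, ann, markers = small_scrna
    return log_normalize(expr), ann, markers


@pytest.fixture
def toy_expression():
    """4 genes x 3 units with a clean ranking in every unit."""
    df = pd.DataFrame(
        {"u1": [8.0, 6.0, 4.0, 2.0], "u2": [1.0, 2.0, 3.0, 4.0], "u3": [5.0, 5.0, 1.0, 0.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def toy_sets():
    return GeneSetCollection({"top": ["g1", "g2"], "bottom": ["g3", "g4"]})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
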