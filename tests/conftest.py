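import numpy as np
import pandas as pd
import pytest

from gbmstate import ExpressionMatrix, SimulationConfig, gen_state_counts
from gbmstate.preprocess import lognormalize, relative_expression


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-state dataset shared by recovery-style tests."""
    config = SimulationConfig(
        n_cells=1000, n_genes=800, markers_per_state=30, marker_effect=1.0, seed=11
    )
    matrix, meta, catalog, truth = gen_state_counts(config)
    return {"config": config, "matrix": matrix, "meta": meta, "catalog": catalog, "truth": truth}


@pytest.fixture(scope="session")
def small_layers(small_sim):
    lognorm = lognormalize(small_sim["matrix"])
    return {"lognorm": lognorm, "relative": relative_expression(lognorm)}


@pytest.fixture
def tiny_counts():
    """A deterministic 6-gene x 4-cell count matrix for hand-oracle tests."""
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(
        rng.integers(0, 40, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(4)],
    )
    vals.iloc[0, :] += 1  # keep at least one gene nonzero everywhere
    return ExpressionMatrix.from_counts(vals)
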