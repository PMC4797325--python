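import numpy as np
import pandas as pd
import pytest

from hybherit.containers import CROSS_TYPES, ExpressionMatrix
from hybherit.simulate import SimulationConfig, simulate_experiment


def make_samples(replicates: int = 6) -> pd.DataFrame:
    rows = [
        {"array_id": f"{ct}_r{r}", "file": "", "cross_type": ct,
         "replicate": r, "slide_id": f"slide{r}"}
        for r in range(1, replicates + 1)
        for ct in CROSS_TYPES
    ]
    return pd.DataFrame(rows).set_index("array_id")


def make_matrix(values: np.ndarray, replicates: int = 6,
                row_ids=None) -> ExpressionMatrix:
    """Wrap a genes x (4*replicates) array as an ExpressionMatrix.

    Columns are ordered WW, WD, DW, DD blocks of `replicates` arrays each.
    """
    samples = make_samples(replicates)
    cols = [f"{ct}_r{r}" for ct in CROSS_TYPES for r in range(1, replicates + 1)]
    if row_ids is None:
        row_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=row_ids, columns=cols), samples)


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment (session-cached; it is deterministic)."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_experiment():
    """A small, fast synthetic experiment for IO round-trips."""
    return simulate_experiment(
        SimulationConfig(
            n_genes=120, n_controls=10, n_gene_sets=4, null_set_size=12,
            planted_set_spec=(("up", 1.0, 15),), de_fraction=0.3, seed=1,
        )
    )
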