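import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from markertyper.preprocess import ExpressionMatrix, log_normalize, z_scale_genes
from markertyper.synthetic import separation_spec, simulate_counts

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class SeparationData:
    """Separation-regime dataset shared across tests (seed fixed)."""

    def __init__(self, seed: int = 11):
        self.spec = separation_spec(seed=seed)
        self.counts, self.meta, self.truth, self.db = simulate_counts(self.spec)
        self.lognorm = log_normalize(self.counts)
        self.scaled = z_scale_genes(self.lognorm)
        self.markers = list(self.db.sets)


@pytest.fixture(scope="session")
def separation_data() -> SeparationData:
    return SeparationData()


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 3 cells, hand-set scaled values for distance oracles."""
    vals = np.array(
        [
            [1.0, -1.0, 0.5],
            [1.0, -0.5, -0.5],
            [-1.0, 1.0, 0.25],
            [-1.0, 0.5, -0.25],
        ]
    )
    return ExpressionMatrix(vals, ["GA", "GB", "GC", "GD"], ["c1", "c2", "c3"], "scaled")


def accuracy(result, truth_types: pd.Series) -> float:
    assigned = result.assignments.loc[truth_types.index]
    return float((assigned.to_numpy() == truth_types.to_numpy()).mean())
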