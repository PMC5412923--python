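import numpy as np
import pytest

from crmineff import DoseGrid, ModelSpec, TrialHistory, scenario1


@pytest.fixture(scope="session")
def grid():
    return DoseGrid()


@pytest.fixture(scope="session")
def model():
    return ModelSpec()


@pytest.fixture(scope="session")
def sc1():
    return scenario1()


@pytest.fixture(scope="session")
def random_history(grid):
    """Factory for random trial histories on the default grid."""

    def make(rng: np.random.Generator, n_records: int = 18) -> TrialHistory:
        history = TrialHistory()
        for _ in range(n_records):
            dose = int(rng.choice(grid.actual_mg))
            history.append(dose, int(rng.random() < 0.5), period=int(rng.choice([1, 2])))
        return history

    return make
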