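import numpy as np
import pytest

from cortexgrowth import build_default_schedule
from cortexgrowth.core import CohortDesign
from cortexgrowth.simulate import CohortSimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded realistic cohort table shared across tests."""
    table, truth = simulate_cohort(CohortSimulationSpec(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def balanced_cohort():
    """Complete participation with shared scan ages: the OLS-oracle design."""
    spec = CohortSimulationSpec(design=CohortDesign.complete(), tau=0.0,
                                sigma=0.03, shared_ages=True, seed=7)
    table, truth = simulate_cohort(spec)
    return table, truth


def ols_fit(table):
    """Closed-form normal-equation OLS of value on age (the LMM oracle)."""
    X = np.column_stack([np.ones(len(table)), table["age_days"].to_numpy(float)])
    y = table["value"].to_numpy(float)
    return np.linalg.solve(X.T @ X, X.T @ y)
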