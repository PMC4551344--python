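import numpy as np
import pandas as pd
import pytest

from stromasig.datatypes import ExpressionCohort
from stromasig.discovery import DiscoveryConfig, discover_signature
from stromasig.synthetic import CohortSpec, generate_survival_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted-signature cohort with its ground truth."""
    return generate_survival_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def fitted_signature(planted_cohort):
    cohort, _ = planted_cohort
    model, screen = discover_signature(
        cohort, DiscoveryConfig(n_perm=1000, seed=11))
    return model, screen


@pytest.fixture
def tiny_cohort():
    """Hand-sized cohort: 6 transcripts x 8 samples with survival."""
    rng = np.random.default_rng(5)
    samples = [f"s{i}" for i in range(8)]
    matrix = pd.DataFrame(rng.normal(size=(6, 8)),
                          index=[f"g{i}" for i in range(6)], columns=samples)
    time = pd.Series(rng.exponential(10, size=8) + 0.5, index=samples)
    event = pd.Series([1, 1, 0, 1, 1, 0, 1, 1], index=samples)
    return ExpressionCohort(matrix=matrix, time=time, event=event)


def brute_force_cox_score(z, time, event):
    """Cox partial-likelihood score at beta=0, divided by n (oracle)."""
    n = len(z)
    total = 0.0
    for i in range(n):
        if event[i]:
            risk = [z[j] for j in range(n) if time[j] >= time[i]]
            total += z[i] - np.mean(risk)
    return total / n
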