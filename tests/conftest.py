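import numpy as np
import pandas as pd
import pytest

import pathbn


@pytest.fixture(scope="session")
def compact_spec():
    return pathbn.compact_truth()


@pytest.fixture(scope="session")
def compact_cohort(compact_spec):
    """Complete 2000-record cohort from the fixed 14-node truth."""
    table = pathbn.simulate_cohort(compact_spec, 2000, 0)
    return table.drop(columns=["participant_id", "study_id"])


@pytest.fixture(scope="session")
def demo_spec():
    return pathbn.demo_truth()


def two_node_chain(coef=1.5, noise=1.0, n=2000, seed=0):
    """Data from A -> B with A at an earlier wave (orientation forced)."""
    from pathbn.variables import Continuous, VariableSpec

    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = coef * a + np.sqrt(noise) * rng.standard_normal(n)
    variables = [
        VariableSpec("A", "a", "T1", Continuous(), "determinant"),
        VariableSpec("B", "b", "T2", Continuous(), "determinant"),
    ]
    return pd.DataFrame({"A": a, "B": b}), variables
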