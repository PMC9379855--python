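import numpy as np
import pandas as pd
import pytest

from regenpath import sem
from regenpath.dataset import STUDY_VARIABLES, load_study_table
from regenpath.pipeline import study_model


@pytest.fixture(scope="session")
def study_records() -> pd.DataFrame:
    return load_study_table()


@pytest.fixture(scope="session")
def study_fit(study_records):
    moments = sem.sample_moments(study_records, STUDY_VARIABLES)
    return sem.fit_ml(study_model(), moments)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_dag_model(rng: np.random.Generator, p_max: int = 5):
    """Random acyclic path model plus simulation settings (coefs, variances)."""
    p = int(rng.integers(2, p_max + 1))
    names = [f"v{i}" for i in range(p)]
    paths = []
    for j in range(1, p):  # edges only from lower to higher index -> acyclic
        for i in range(j):
            if rng.random() < 0.5:
                paths.append((names[i], names[j]))
    if not paths:
        paths.append((names[0], names[-1]))
    model = sem.build_model(names, paths)
    coefs = {pth: float(rng.uniform(-1.2, 1.2)) for pth in model.paths}
    variances = {v: float(rng.uniform(0.4, 2.0)) for v in names}
    return model, coefs, variances


def simulate_from(model, coefs, variances, n, rng):
    """Draw n observations from a recursive model (independent of regenpath.simulate)."""
    data = {}
    for v in model.variables:  # variables are already in topological order
        eps = rng.normal(0.0, np.sqrt(variances[v]), size=n)
        y = eps
        for s in model.parents(v):
            y = y + coefs[(s, v)] * data[s]
        data[v] = y
    return pd.DataFrame(data)
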