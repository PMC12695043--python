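import numpy as np
import pandas as pd
import pytest

from treefx import (
    CovariateSpec,
    FitConfig,
    SimulationConfig,
    TrialDataset,
    covariate_catalog,
    generate_trial,
)
from treefx.report import prepare_outcome


@pytest.fixture(scope="session")
def catalog():
    return covariate_catalog()


def make_dataset(y, w, X: dict[str, np.ndarray], catalog=None):
    """Minimal dataset with a precomputed outcome, for tree unit tests."""
    n = len(y)
    if catalog is None:
        catalog = tuple(
            CovariateSpec(name, "continuous") for name in X
        )
    w0 = np.full(n, 85.0)
    return TrialDataset(
        patient_id=tuple(f"p{i}" for i in range(n)),
        arm=np.asarray(w, dtype=int),
        ppfvc=pd.DataFrame({0: w0, 24: w0 + np.asarray(y, float)}),
        covariates=pd.DataFrame({k: np.asarray(v, float) for k, v in X.items()}),
        catalog=tuple(catalog),
        delta_ppfvc=np.asarray(y, dtype=float),
    )


@pytest.fixture(scope="session")
def default_trial_2000():
    """Default planted generator at n=2000, outcome prepared; shared by slow tests."""
    ds = generate_trial(SimulationConfig(n=2000, seed=1))
    return prepare_outcome(ds, 24)


@pytest.fixture(scope="session")
def fitted_default_tree(default_trial_2000):
    from treefx import fit_causal_tree

    return fit_causal_tree(default_trial_2000, FitConfig(seed=1))
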