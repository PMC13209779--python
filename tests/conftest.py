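import numpy as np
import pandas as pd
import pytest

from plgarelease import (
    SimulationConfig,
    generate_dataset,
    groupkfold_evaluate,
    oof_slow_release_probabilities,
)
from plgarelease.stage2 import assemble_regression_matrix

SEED = 1


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset (15 drugs) for unit-level checks."""
    cfg = SimulationConfig(n_drugs=15)
    return generate_dataset(cfg, seed=SEED)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default study: ~90 drugs, ~300 formulations."""
    return generate_dataset(SimulationConfig(), seed=SEED)


@pytest.fixture(scope="session")
def default_oof(default_dataset):
    return oof_slow_release_probabilities(default_dataset.features, k=10, seed=SEED)


@pytest.fixture(scope="session")
def default_matrix(default_dataset, default_oof):
    return assemble_regression_matrix(
        default_dataset.features, default_oof, default_dataset.profiles
    )


@pytest.fixture(scope="session")
def model_comparison(default_dataset):
    """Group 5-fold comparison of all six algorithms plus the mean baseline."""
    return groupkfold_evaluate(
        default_dataset.features,
        default_dataset.profiles,
        algorithms=["lr", "svr", "dt", "rf", "xgb", "lgbm", "mean"],
        k=5,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def lodo_report(default_matrix, model_comparison):
    """LODO of the CV-selected model on the default study (shared: slow)."""
    from plgarelease.validation import lodo_evaluate

    return lodo_evaluate(default_matrix, model_comparison.best(), seed=SEED)


@pytest.fixture()
def toy_features():
    rng = np.random.default_rng(0)
    n = 8
    dm = rng.uniform(0.1, 0.4, n)
    ee = rng.uniform(0.5, 0.95, n)
    return pd.DataFrame({
        "formulation_id": [f"F{i}" for i in range(n)],
        "drug_id": [f"D{i // 2}" for i in range(n)],
        "polymer_mw": rng.uniform(10, 90, n),
        "la_ga": 1.0,
        "initial_dm_ratio": dm,
        "drug_mw": rng.uniform(300, 900, n),
        "drug_tpsa": rng.uniform(40, 140, n),
        "drug_logp": rng.normal(2, 1, n),
        "particle_size": rng.uniform(20, 120, n),
        # consistent with the encapsulation mass balance by construction
        "dlc": ee * dm / (1 + ee * dm),
        "ee": ee,
        "se": 0.0,
        "agitation_rpm": 100.0,
        "polymer_concentration": rng.uniform(0.05, 0.3, n),
        "acid_endcap": rng.integers(0, 2, n),
    })
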