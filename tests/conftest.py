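import numpy as np
import pytest

from fkmr import ScenarioConfig, simulate_dataset
from fkmr.fpca import build_feature_blocks, fit_fpca


@pytest.fixture(scope="session")
def scenario2_small():
    """One Scenario-2 replicate at n=300 with FPCA features extracted."""
    ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=300, seed=11))
    tr, te = ds.train_index, ds.test_index
    fpcas = [fit_fpca(c[tr], ds.grid, n_components=9) for c in ds.curves]
    Ztr = build_feature_blocks([f.features_ for f in fpcas]).matrix
    Zte = build_feature_blocks(
        [f.transform(c[te]) for f, c in zip(fpcas, ds.curves)]).matrix
    return {
        "ds": ds,
        "fpcas": fpcas,
        "X_train": np.hstack([ds.x[tr][:, None], Ztr]),
        "X_test": np.hstack([ds.x[te][:, None], Zte]),
        "y_train": ds.y[tr],
        "y_test": ds.y[te],
        "h_test": ds.true_h[te],
    }


@pytest.fixture(scope="session")
def scenario2_features():
    """True (not estimated) probit features of a small Scenario-2 draw."""
    ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=200, seed=5))
    return ds.true_zeta
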