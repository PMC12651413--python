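import numpy as np
import pandas as pd
import pytest

from tomarker.io import FeatureTable
from tomarker.simulate import SimulationConfig, simulate_feature_table


def make_table(values, missing=None, groups=None, sample_types=None, scale="raw",
               mz=None, rt=None, ion_mode=None):
    """Hand-built FeatureTable from a 2D list (None marks missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n_feat, n_inj = arr.shape
    miss = pd.DataFrame(
        np.isnan(arr) if missing is None else np.asarray(missing, dtype=bool),
        index=[f"F{i}" for i in range(n_feat)],
        columns=[f"inj{j}" for j in range(n_inj)],
    )
    vals = pd.DataFrame(arr, index=miss.index, columns=miss.columns)
    sample_types = sample_types or ["sample"] * n_inj
    if groups is None:
        groups = ["DO"] * n_inj
    groups = [g if t == "sample" else None for g, t in zip(groups, sample_types)]
    injections = pd.DataFrame(
        {
            "sample_type": sample_types,
            "group": groups,
            "injection_order": np.arange(1, n_inj + 1),
        },
        index=miss.columns,
    )
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 900, n_feat),
            "rt": rt if rt is not None else np.linspace(1, 10, n_feat),
            "ion_mode": ion_mode if ion_mode is not None else ["pos"] * n_feat,
        },
        index=miss.index,
    )
    return FeatureTable(features=features, injections=injections,
                        values=vals.where(~miss), missing=miss, scale=scale)


@pytest.fixture(scope="session")
def small_sim():
    """One default-structure simulated study, shared across tests."""
    cfg = SimulationConfig(n_features=60, seed=42)
    table, truth = simulate_feature_table(cfg)
    return cfg, table, truth


@pytest.fixture()
def four_group_table():
    """Noise-free 2-feature table over all four groups, 3 replicates each."""
    groups = ["DO"] * 3 + ["D"] * 3 + ["PF"] * 3 + ["PS"] * 3
    values = [
        [1e5] * 3 + [1e4] * 3 + [1e4] * 3 + [1e4] * 3,  # Organic "+" marker
        [2e4] * 12,
    ]
    return make_table(values, groups=groups)
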