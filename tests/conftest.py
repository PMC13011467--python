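import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from saltomics.metabolomics import FeatureTable
from saltomics.synthetic_data import sample_design


@pytest.fixture
def design():
    return sample_design()


def make_table(signals: np.ndarray, design: pd.DataFrame, rt=None, mode=None) -> FeatureTable:
    """Wrap a raw signal matrix (features x all samples) into a FeatureTable."""
    n = signals.shape[0]
    ids = pd.Index([f"F{i:04d}" for i in range(n)], name="feature_id")
    features = pd.DataFrame(
        {
            "mz": np.linspace(100, 900, n),
            "rt": np.full(n, 4.0) if rt is None else np.asarray(rt, dtype=float),
            "mode": ["positive"] * n if mode is None else list(mode),
        },
        index=ids,
    )
    sig = pd.DataFrame(signals, index=ids, columns=design.index)
    return FeatureTable(features=features, signals=sig, samples=design)


@pytest.fixture
def small_table(design):
    """Deterministic 4-feature table: 3 nulls + 1 strong interaction feature."""
    rng = np.random.default_rng(42)
    n_samples = len(design)
    base = np.full((4, n_samples), 5e7)
    base *= rng.lognormal(0.0, 0.05, size=base.shape)
    bio = ~design["is_blank"].to_numpy()
    base[:, ~bio] = 1e6
    # feature 3: salt @ t=48h cell boosted 200x
    cell = (design["condition"] == "salt") & (design["time_h"] == 48.0)
    base[3, cell.to_numpy()] *= 200.0
    return make_table(base, design)
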