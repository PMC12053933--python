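import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from glycodiff.glyco import GlycopeptideMatrix
from glycodiff.simulate import SimulationConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down cohort for fast end-to-end tests."""
    return SimulationConfig(
        n_proteins=400, n_glycoproteins=60, n_decoys=10, seed=101
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def study_scale():
    """Full study-scale synthetic cohort (12 + 12 samples, default sizes)."""
    return generate_study(SimulationConfig(seed=7))


def make_matrix(values, groups):
    """Small GlycopeptideMatrix from a dict of row-key -> per-sample values."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["protein", "site", "glycan"])
    return GlycopeptideMatrix(abundance=df, groups=pd.Series(groups))
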