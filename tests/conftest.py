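import numpy as np
import pandas as pd
import pytest

from npxcc.containers import NPXMatrix
from npxcc.simulate import SimConfig, null_config, simulate_cohorts


def make_npx(values, cohort="A", lod=None, bridge_rows=(), plates=None):
    """Small NPXMatrix from a dict/DataFrame of values (test helper)."""
    df = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values.copy()
    df.index = df.index.astype(str)
    lod = pd.Series(-np.inf, index=df.columns) if lod is None else pd.Series(lod)
    plates = pd.Series("P1", index=df.index) if plates is None else pd.Series(plates)
    stype = pd.Series(
        ["bridge" if s in set(bridge_rows) else "study" for s in df.index], index=df.index
    )
    return NPXMatrix(df, lod, plates, stype, cohort=cohort)


@pytest.fixture(scope="session")
def small_pair():
    """Small clean two-cohort simulation (no censoring/outliers, null effects)."""
    cfg = null_config(seed=11, n_a=60, n_b=80, n_proteins=20)
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def default_pair():
    """Full default-condition simulation (318/416 samples, 92 proteins)."""
    return simulate_cohorts(SimConfig(seed=7))
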