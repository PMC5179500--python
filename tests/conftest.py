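import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import srftarget as st

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_table() -> st.CountTable:
    """4 genes x 4 libraries (WT only, total+intronic), hand-made counts."""
    samples = [
        st.SampleDescriptor("WT", cond, rep, rc)
        for cond in ("resting", "TPA")
        for rep in (1, 2)
        for rc in ("total", "intronic")
    ]
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(100, size=(4, len(samples))),
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
        columns=[s.label() for s in samples],
    )
    return st.CountTable(counts, samples)


@pytest.fixture
def uniform_map() -> st.ContactMap:
    """60-bin map with every pair (including the diagonal) at count 8."""
    n = 60
    iu, ju = np.triu_indices(n)
    return st.ContactMap("chrU", 10_000, iu, ju, np.full(len(iu), 8), n_bins=n)
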