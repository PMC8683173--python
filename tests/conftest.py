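import numpy as np
import pandas as pd
import pytest

from lncnet import CASE, CONTROL, LNCRNA, MRNA, ExpressionMatrix


def make_matrix(values, biotypes=None, n_case=None, probe_ids=None, sample_ids=None):
    """Build an ExpressionMatrix from a 2-D array with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if probe_ids is None:
        probe_ids = [f"P{i}" for i in range(n_probes)]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    if biotypes is None:
        biotypes = [LNCRNA if i % 2 == 0 else MRNA for i in range(n_probes)]
    if n_case is None:
        n_case = n_samples // 2
    groups = [CASE] * n_case + [CONTROL] * (n_samples - n_case)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        biotype=pd.Series(biotypes, index=probe_ids),
        group=pd.Series(groups, index=sample_ids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_matrix(rng):
    """50 probes x (13 case + 9 control), null everywhere except 5 planted."""
    values = rng.normal(8.0, 0.5, size=(50, 22))
    values[:5, :13] += 1.5
    return make_matrix(values, n_case=13)
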