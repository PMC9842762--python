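import numpy as np
import pandas as pd
import pytest

from dppi.io_formats import ProteinQuantMatrix, SampleRecord


def make_matrix(values, sample_ids=None, genes=None, stage="raw"):
    """Build a ProteinQuantMatrix from a 2-D list/array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    n, k = arr.shape
    sample_ids = sample_ids or [f"S{j+1}" for j in range(k)]
    genes = genes or [f"G{i+1}" for i in range(n)]
    df = pd.DataFrame(arr, columns=sample_ids)
    return ProteinQuantMatrix([f"ACC{i+1}" for i in range(n)], list(genes), df, stage)


def two_group_sheet(n_a, n_b, prefix_a="A", prefix_b="B"):
    """One sample per patient, groups recurrence / no_recurrence."""
    recs = []
    for i in range(n_a):
        recs.append(SampleRecord(f"{prefix_a}{i+1}", f"{prefix_a}{i+1}", 1,
                                 "recurrence", 1))
    for i in range(n_b):
        recs.append(SampleRecord(f"{prefix_b}{i+1}", f"{prefix_b}{i+1}", 1,
                                 "no_recurrence", 1))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
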