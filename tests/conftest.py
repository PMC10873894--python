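import numpy as np
import pandas as pd
import pytest

from seedhet.datatypes import CountMatrix, NormalizedMatrix


def make_count_matrix(counts, intergenic=None, condition=None, class_label=None):
    """Build a small CountMatrix from a 2D list/array (seeds x genes)."""
    arr = np.asarray(counts, dtype=np.int64)
    n, p = arr.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="seed_id")
    cols = pd.Index([f"g{j}" for j in range(p)], name="gene_id")
    if intergenic is None:
        intergenic = np.zeros(n, dtype=np.int64)
    if condition is None:
        condition = ["c1"] * n
    return CountMatrix(
        counts=pd.DataFrame(arr, index=idx, columns=cols),
        intergenic=pd.Series(np.asarray(intergenic, dtype=np.int64), index=idx),
        condition=pd.Series(condition, index=idx),
        class_label=None if class_label is None else pd.Series(class_label, index=idx),
    )


def make_normalized(values, method_tag="raw"):
    """Wrap a 2D array of reals as a NormalizedMatrix (no log1p constraint)."""
    arr = np.asarray(values, dtype=float)
    n, p = arr.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="seed_id")
    cols = pd.Index([f"g{j}" for j in range(p)], name="gene_id")
    return NormalizedMatrix(
        values=pd.DataFrame(arr, index=idx, columns=cols), scale=1.0, method_tag=method_tag
    )


@pytest.fixture
def toy_counts():
    return make_count_matrix(
        [[2, 0, 3], [1, 4, 0]], intergenic=[5, 2], condition=["3d", "3d"]
    )
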