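import numpy as np
import pandas as pd
import pytest

from ffevomics import CountMatrix


@pytest.fixture
def small_matrix() -> CountMatrix:
    """Six features x four samples with clean group structure."""
    counts = pd.DataFrame(
        {
            "c1": [10, 20, 5, 0, 100, 7],
            "c2": [12, 18, 6, 0, 90, 9],
            "p1": [40, 21, 5, 0, 95, 30],
            "p2": [44, 19, 7, 0, 105, 28],
        },
        index=[f"mir{i}" for i in range(6)],
    )
    groups = pd.Series(
        {"c1": "control", "c2": "control", "p1": "case", "p2": "case"}, dtype=object
    )
    return CountMatrix(counts=counts, groups=groups)


def bh_oracle(p):
    """Brute-force BH: q_(k) = min over suffixes of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q
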