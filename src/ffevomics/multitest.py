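"""Multiple-testing correction shared by the miRNA and protein callers."""

from __future__ import annotations

import numpy as np
import numpy.typing as npt


def bh_fdr(p_values: npt.ArrayLike) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    For sorted p-values p_(1) <= ... <= p_(m) the adjusted value at rank k is
    ``q_(k) = min_{j >= k} (p_(j) * m / j)`` capped at 1, returned in the
    original input order. NaNs are not allowed: the callers exclude untestable
    features before correction so that m equals the number of tests performed.

    Parameters
    ----------
    p_values:
        Raw p-values, each in [0, 1].

    Returns
    -------
    numpy.ndarray of the same length, adjusted p-values in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q
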