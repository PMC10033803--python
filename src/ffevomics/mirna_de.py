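"""Differential expression of extracellular-vesicle miRNAs from a count matrix.

The analysis starts from an integer count matrix (miRNA x sample) with a
control/case group label per sample. Counts are normalised by median-of-ratios
size factors, expression is reported as TPM (counts per million; mature miRNAs
are near-constant in length so no length term is used), and per-miRNA
differences are tested with a Welch t-test on log2(normalised count +
pseudocount). A miRNA is called differentially expressed when
|log2FC| >= 1 and p <= 0.05 (both boundaries inclusive), with BH-FDR reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_fdr

GROUPS = ("control", "case")


@dataclass
class CountMatrix:
    """Integer miRNA counts (features x samples) with a group per sample.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``groups`` maps every sample id to "control" or "case".
    """

    counts: pd.DataFrame
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        self.groups = pd.Series(self.groups, dtype=object)
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.loc[list(self.counts.columns)]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be non-negative integers")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def compute_size_factors(matrix: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-feature geometric mean across samples,
    using only features expressed (count > 0) in every sample; the factor of a
    sample is the median over those features of count / reference. If no
    feature is expressed everywhere, pass ``pseudo_reference=True`` to add a
    0.5 pseudocount to all counts before forming the reference.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if pseudo_reference:
        counts = counts + 0.5
    expressed = np.all(counts > 0, axis=1)
    if not expressed.any():
        raise ValueError(
            "no feature expressed in all samples; re-run with pseudo_reference=True"
        )
    sub = counts[expressed]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean of factors -> 1
    return pd.Series(np.exp(log_factors), index=matrix.counts.columns, name="size_factor")


def compute_tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts scaled to a per-million column total (no length normalisation)."""
    totals = matrix.counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        zero = [s for s, t in zip(matrix.counts.columns, totals) if t <= 0]
        raise ValueError(f"all-zero sample(s): {zero}")
    return matrix.counts / totals * 1e6


def differential_mirnas(
    matrix: CountMatrix,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-miRNA differential table: log2FC, Welch-t p, BH-FDR, direction.

    log2FC compares normalised group means with a pseudocount,
    ``log2((mean_case + pc) / (mean_control + pc))``; the test is a two-sided
    Welch t on log2(normalised count + pc). Direction is "up"/"down" when
    |log2FC| >= lfc_min and p <= alpha (both inclusive), else "ns".

    Returns a DataFrame indexed by feature id with columns log2fc, p_value,
    fdr, direction, mean_control, mean_case.
    """
    ctrl = matrix.samples_in("control")
    case = matrix.samples_in("case")
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need at least 2 samples per group")
    if size_factors is None:
        size_factors = compute_size_factors(matrix)
    norm = matrix.counts / size_factors

    mean_ctrl = norm[ctrl].mean(axis=1).to_numpy()
    mean_case = norm[case].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_case + pseudocount) - np.log2(mean_ctrl + pseudocount)

    logs = np.log2(norm.to_numpy() + pseudocount)
    idx = {s: i for i, s in enumerate(norm.columns)}
    x = logs[:, [idx[s] for s in case]]
    y = logs[:, [idx[s] for s in ctrl]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0  # zero-variance features: no evidence of change

    fdr = bh_fdr(p)
    direction = np.where(
        (np.abs(log2fc) >= lfc_min) & (p <= alpha),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
        },
        index=matrix.counts.index.rename("feature_id"),
    )
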