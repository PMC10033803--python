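"""TMT reporter-ion quantification by a hierarchical median-of-ratios cascade.

Quantification starts from a PSM table (one row per peptide-spectrum match,
one reporter-intensity column per TMT channel) and a list of
(case_channel, control_channel) replicate pairs. For each replicate pair the
PSM ratio is case / control; the peptide ratio is the median of its PSM
ratios; the protein replicate ratio is the median of its peptide ratios; and
the combined protein ratio is the median across replicate pairs. Significance
is a one-sample t-test of the log2 replicate ratios against 0, and the
up/down fold-change cutoffs are robust: median +/- 2 * scaled IQR of all
quantified proteins' log2 ratios, with scaled IQR = IQR / 1.34898 (the
normal-consistent robust sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_fdr

#: IQR of the standard normal: 2 * Phi^-1(0.75). Dividing an IQR by this
#: makes it a consistent estimator of sigma under normality.
NORMAL_IQR = 1.34898

META_COLUMNS = ("psm_id", "peptide", "protein")


@dataclass
class PSMTable:
    """PSM-level reporter intensities plus the replicate channel pairing.

    ``frame`` must carry columns psm_id, peptide, protein and one numeric
    column per channel; ``pairing`` is an ordered list of
    (case_channel, control_channel) tuples. A protein field containing
    ';'-separated accessions is resolved by razor assignment: the PSM goes to
    the candidate protein with the most distinct peptides in the table, ties
    broken lexicographically.
    """

    frame: pd.DataFrame
    pairing: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise ValueError("empty PSM table")
        for col in META_COLUMNS:
            if col not in self.frame.columns:
                raise ValueError(f"PSM table missing column {col!r}")
        channels = {c for pair in self.pairing for c in pair}
        missing = channels - set(self.frame.columns)
        if missing:
            raise ValueError(f"pairing references absent channels: {sorted(missing)}")
        if not self.pairing:
            raise ValueError("at least one replicate channel pair is required")
        if self.frame["protein"].str.contains(";").any():
            self.frame = self.frame.assign(protein=_razor_assign(self.frame))


def _razor_assign(frame: pd.DataFrame) -> pd.Series:
    """Assign shared PSMs to the candidate with most distinct peptides."""
    singles = frame.loc[~frame["protein"].str.contains(";")]
    pep_counts = singles.groupby("protein")["peptide"].nunique().to_dict()

    def pick(field: str) -> str:
        cands = sorted(field.split(";"))  # ascending, so ties go to the smallest id
        best = max(pep_counts.get(p, 0) for p in cands)
        return next(p for p in cands if pep_counts.get(p, 0) == best)

    return frame["protein"].map(lambda f: pick(f) if ";" in f else f)


def protein_ratios_from_psms(psms: PSMTable) -> pd.DataFrame:
    """Median cascade PSM -> peptide -> protein -> across replicate pairs.

    PSMs with a non-positive or missing intensity in either channel of a pair
    are dropped for that pair. A protein with no usable PSM in a pair gets NaN
    for that replicate ratio; the combined ratio is the median of available
    replicate ratios.

    Returns a DataFrame indexed by protein_id with one ``ratio_<k>`` column
    per replicate pair plus combined_ratio, n_peptides, n_psms.
    """
    frame = psms.frame
    out: dict[str, pd.Series] = {}
    for k, (case_ch, ctrl_ch) in enumerate(psms.pairing, start=1):
        case = pd.to_numeric(frame[case_ch], errors="coerce")
        ctrl = pd.to_numeric(frame[ctrl_ch], errors="coerce")
        ok = (case > 0) & (ctrl > 0)
        sub = frame.loc[ok, ["protein", "peptide"]].copy()
        sub["ratio"] = (case[ok] / ctrl[ok]).to_numpy()
        pep = sub.groupby(["protein", "peptide"])["ratio"].median()
        out[f"ratio_{k}"] = pep.groupby(level="protein").median()

    ratios = pd.DataFrame(out)
    ratios = ratios.reindex(sorted(frame["protein"].unique()))
    ratios.index.name = "protein_id"
    ratios["combined_ratio"] = ratios[[c for c in ratios.columns]].median(axis=1, skipna=True)
    ratios["n_peptides"] = frame.groupby("protein")["peptide"].nunique()
    ratios["n_psms"] = frame.groupby("protein")["psm_id"].nunique()
    return ratios


def protein_significance(quants: pd.DataFrame) -> pd.DataFrame:
    """One-sample two-sided t on log2 replicate ratios against 0, plus BH-FDR.

    Proteins with fewer than 2 usable replicate ratios, or with zero variance
    across replicates, get a NaN p-value and ``degenerate=True`` (the second
    case only); both are excluded from the FDR computation.
    """
    ratio_cols = [c for c in quants.columns if c.startswith("ratio_")]
    logs = np.log2(quants[ratio_cols].to_numpy(dtype=float))
    n = np.sum(np.isfinite(logs), axis=1)
    mean = np.full(len(quants), np.nan)
    sd = np.full(len(quants), np.nan)
    for i, row in enumerate(logs):
        vals = row[np.isfinite(row)]
        if vals.size:
            mean[i] = vals.mean()
        if vals.size >= 2:
            sd[i] = vals.std(ddof=1)

    p = np.full(len(quants), np.nan)
    degenerate = np.zeros(len(quants), dtype=bool)
    testable = (n >= 2) & (sd > 0)
    degenerate[(n >= 2) & (sd == 0)] = True
    t = mean[testable] / (sd[testable] / np.sqrt(n[testable]))
    p[testable] = 2.0 * stats.t.sf(np.abs(t), df=n[testable] - 1)

    fdr = np.full(len(quants), np.nan)
    if testable.any():
        fdr[testable] = bh_fdr(p[testable])
    return pd.DataFrame(
        {"p_value": p, "fdr": fdr, "n_replicates": n, "degenerate": degenerate},
        index=quants.index,
    )


@dataclass(frozen=True)
class RobustThreshold:
    """Fold-change cutoffs: median +/- 2 * scaled IQR of the log2 ratios."""

    center: float
    s_iqr: float

    @property
    def upper_cut(self) -> float:
        return self.center + 2.0 * self.s_iqr

    @property
    def lower_cut(self) -> float:
        return self.center - 2.0 * self.s_iqr


def robust_cutoffs(log2fcs) -> RobustThreshold:
    """Robust two-sigma-analogue cutoffs from a sample of log2 fold changes.

    Quartiles use linear interpolation between order statistics (position
    1 + (n-1) q). Requires at least 4 finite values.
    """
    x = np.asarray(log2fcs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need at least 4 finite log2 fold changes")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return RobustThreshold(center=float(med), s_iqr=float((q3 - q1) / NORMAL_IQR))


def call_deps(
    quants: pd.DataFrame,
    significance: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, RobustThreshold]:
    """Call differential proteins with robust cutoffs and strict thresholds.

    up: log2(foldchange) > upper_cut and p < alpha;
    down: log2(foldchange) < lower_cut and p < alpha; otherwise ns.
    Cutoffs are computed from all quantified proteins. The returned table is
    sorted by foldchange descending.
    """
    if quants.empty:
        raise ValueError("empty protein quantification table")
    if significance is None:
        significance = protein_significance(quants)
    fc = quants["combined_ratio"].to_numpy(dtype=float)
    log2fc = np.log2(fc)
    thr = robust_cutoffs(log2fc)
    p = significance["p_value"].reindex(quants.index).to_numpy(dtype=float)
    callable_ = np.isfinite(p) & (significance["n_replicates"].reindex(quants.index) >= 2)
    direction = np.full(len(quants), "ns", dtype=object)
    up = callable_ & (log2fc > thr.upper_cut) & (p < alpha)
    down = callable_ & (log2fc < thr.lower_cut) & (p < alpha)
    direction[up] = "up"
    direction[down] = "down"
    table = pd.DataFrame(
        {
            "foldchange": fc,
            "p_value": p,
            "fdr": significance["fdr"].reindex(quants.index).to_numpy(dtype=float),
            "direction": direction,
        },
        index=quants.index,
    ).sort_values("foldchange", ascending=False)
    return table, thr
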