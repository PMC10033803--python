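"""Group comparisons of the clinical characteristics table (3 vs 3 subjects).

The cohort table records eleven clinical variables (age, BMI, gonadotropins,
steroid hormones, fasting glucose, infertility duration, prolactin, AMH and
antral follicle count) for three control and three PCOS subjects. Each
variable is compared with a two-sided Student t-test with pooled variance —
the test form that reproduces the published p-values at these group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    degenerate: bool = False  # both groups constant but unequal


def pooled_ttest(x, y) -> TTestResult:
    """Two-sided Student t with pooled variance; df = n1 + n2 - 2.

    Degenerate inputs: two constant equal groups give t = 0, p = 1; two
    constant unequal groups give p = 0 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(x.mean() - y.mean())
    df = x.size + y.size - 2
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, 0.0)
        return TTestResult(np.inf if diff > 0 else -np.inf, df, 0.0, diff, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), df, float(p), diff)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged clinical table: 11 variables x (3 control + 3 case).

    Columns: variable, units, control_1..3, case_1..3, printed_p (the p-value
    printed in the source table; "<0.0001" is kept as a string bound).
    """
    path = resources.files("ffevomics").joinpath("data/table1_clinical.tsv")
    with resources.as_file(path) as fh:
        return pd.read_csv(fh, sep="\t", dtype={"printed_p": str})


def compare_clinical_table(table: pd.DataFrame | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Pooled t-test per clinical variable plus a significance flag (p < alpha).

    Returns a DataFrame with variable, units, group means, t, df, p_value and
    significant columns; on the packaged fixture the flags reproduce the
    published bolding (7 of 11 rows).
    """
    if table is None:
        table = load_table1_fixture()
    ctrl_cols = [c for c in table.columns if c.startswith("control_")]
    case_cols = [c for c in table.columns if c.startswith("case_")]
    if table[ctrl_cols + case_cols].isna().any().any():
        raise ValueError("missing values in clinical table")
    rows = []
    for _, row in table.iterrows():
        x = row[ctrl_cols].to_numpy(dtype=float)
        y = row[case_cols].to_numpy(dtype=float)
        res = pooled_ttest(x, y)
        rows.append(
            {
                "variable": row["variable"],
                "units": row.get("units", ""),
                "mean_control": x.mean(),
                "mean_case": y.mean(),
                "t_statistic": res.t_statistic,
                "df": res.df,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
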