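"""Gene-set over-representation analysis (hypergeometric tail test).

Given a query gene list, a gene-set collection (GMT) and a background
universe, each set is scored by P(X >= k) under
Hypergeometric(N = |universe|, K = |set ∩ universe|, n = |query|), with
BH-FDR across the tested sets. Only over-representation is tested.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .multitest import bh_fdr


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into {set_name: (description, member genes)}.

    Each line is name<TAB>description<TAB>gene1<TAB>gene2...; duplicate
    members within a set are deduplicated, a malformed line (< 3 fields)
    raises, an empty file returns an empty collection with a warning.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (< 3 fields)")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = (desc, {m for m in members if m})
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return sets


def ora(
    query,
    sets: dict[str, tuple[str, set[str]]],
    universe,
) -> pd.DataFrame:
    """Over-representation of a query gene list in each gene set.

    Query genes outside the universe are dropped (their count is recorded in
    the ``dropped_from_query`` DataFrame attribute); sets with no member in
    the universe are skipped. Returns a DataFrame sorted by p with columns
    set_name, description, k (overlap), K (set size in universe), n (query
    size), N (universe size), p_value, fdr.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    dropped = len(query - universe)
    query &= universe
    n, N = len(query), len(universe)
    rows = []
    for name, (desc, members) in sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_name": name, "description": desc, "k": k, "K": K, "n": n, "N": N, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["set_name", "description", "k", "K", "n", "N", "p_value"])
    if not out.empty:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
    out.attrs["dropped_from_query"] = dropped
    return out
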