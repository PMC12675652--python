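"""Kendall-tau correlation screen with Benjamini-Hochberg FDR control.

All unordered indicator pairs are tested with tie-corrected Kendall tau-b on
pairwise-complete observations; the BH step-up adjustment is applied jointly
across every pair that produced a p-value, and significance is called at
q < 0.05.  Count-valued indicators tie heavily across small collections,
which is why the tie-corrected statistic is used.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NAN = float("nan")


def kendall_tau(x, y) -> tuple[float, float]:
    """Tau-b and two-sided p for two sequences, after dropping incomplete pairs.

    Returns (nan, nan) with a logged warning when fewer than 3 complete
    pairs remain or either sequence is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        logger.warning("kendall_tau: only %d complete pair(s); result missing", len(x))
        return NAN, NAN
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("kendall_tau: zero variance; result missing")
        return NAN, NAN
    res = sps.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(indicators: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Kendall screen over all indicator columns.

    Non-numeric columns (e.g. ``web_id``) are ignored.  Missing values are
    handled by pairwise-complete deletion, so ``n_used`` varies by pair; the
    BH family is the set of pairs with a computable p-value (constant or
    too-sparse columns are excluded and logged).  Returns a long-format
    frame: var1, var2, tau, p, q, n_used, significant.
    """
    data = indicators.select_dtypes(include=[np.number])
    if len(data) < 3:
        raise ValueError(f"need at least 3 rows, got {len(data)}")
    rows = []
    for a, b in itertools.combinations(data.columns, 2):
        x = data[a].to_numpy(dtype=float)
        y = data[b].to_numpy(dtype=float)
        n_used = int((~(np.isnan(x) | np.isnan(y))).sum())
        tau, p = kendall_tau(x, y)
        rows.append({"var1": a, "var2": b, "tau": tau, "p": p, "n_used": n_used})
    table = pd.DataFrame(rows)
    computable = table["p"].notna()
    if (~computable).any():
        logger.info(
            "%d pair(s) excluded from the BH family (no computable p)", int((~computable).sum())
        )
    q = np.full(len(table), NAN)
    if computable.any():
        q[computable.to_numpy()] = bh_adjust(table.loc[computable, "p"].to_numpy())
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return table


def tau_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Square tau matrix (heatmap-ready) from a long correlation table."""
    if columns is None:
        columns = sorted(set(table["var1"]) | set(table["var2"]))
    m = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for _, row in table.iterrows():
        m.loc[row["var1"], row["var2"]] = row["tau"]
        m.loc[row["var2"], row["var1"]] = row["tau"]
    return m


def significance_stars(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Star annotations from adjusted q: *** < 0.001, ** < 0.01, * < 0.05."""
    if columns is None:
        columns = sorted(set(table["var1"]) | set(table["var2"]))
    m = pd.DataFrame("", index=columns, columns=columns)

    def star(q: float) -> str:
        if np.isnan(q):
            return ""
        if q < 0.001:
            return "***"
        if q < 0.01:
            return "**"
        if q < 0.05:
            return "*"
        return ""

    for _, row in table.iterrows():
        s = star(row["q"])
        m.loc[row["var1"], row["var2"]] = s
        m.loc[row["var2"], row["var1"]] = s
    return m
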