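"""Cross-region correlation statistics with Bonferroni correction.

Regions of interest are the sampling units: animal tables are averaged
per region, each ROI contributes one point, and Pearson correlations
between vascular and cell-density measures are tested against the
no-correlation null (two-sided t, n−2 df).  Multiple comparisons use the
Bonferroni adjustment p_adj = min(1, m·p) with m the number of tested
pairs; significance is flagged at 0.05 and 0.005 on adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    r: float
    p_raw: float
    p_adjusted: float
    n_roi: int
    m_comparisons: int
    significant_005: bool   # p_adjusted < 0.05
    significant_0005: bool  # p_adjusted < 0.005


def aggregate_by_region(
    per_animal_tables: list[pd.DataFrame],
    qc_pass: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Average animal tables region-by-region (index = region id).

    ``qc_pass`` maps region id → bool from the vessel connectivity QC;
    failing regions are dropped and listed in ``df.attrs["qc_excluded"]``.
    Regions present in no table raise nothing — they simply don't exist;
    regions present in only some tables average over those animals.
    """
    if not per_animal_tables:
        raise ValueError("no animal tables given")
    combined = pd.concat(per_animal_tables)
    out = combined.groupby(level=0).mean()
    excluded: list = []
    if qc_pass is not None:
        qc = pd.Series(qc_pass)
        excluded = [r for r in out.index if not qc.get(r, True)]
        out = out.drop(index=excluded)
    out.attrs["qc_excluded"] = excluded
    return out


def correlate_bonferroni(
    x,
    y,
    m_comparisons: int = 1,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson correlation with Bonferroni-adjusted two-sided p.

    Zero variance in either variable leaves R undefined (NaN, reported
    missing rather than 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must pair over identical region sets")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 regions to correlate")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(names, np.nan, np.nan, np.nan, n,
                                 m_comparisons, False, False)
    r, p = sps.pearsonr(x, y)
    p_adj = min(1.0, m_comparisons * p)
    return CorrelationResult(
        names, float(r), float(p), float(p_adj), n, m_comparisons,
        p_adj < 0.05, p_adj < 0.005,
    )


def correlation_matrix(
    table: pd.DataFrame,
    x_columns=None,
    y_columns=None,
) -> pd.DataFrame:
    """All-pairs correlation between two column sets of one region table.

    m (recorded per row) = total number of tested pairs, applied as the
    Bonferroni multiplier to every pair.  Returns a long-format frame
    with one row per pair.
    """
    x_columns = list(x_columns if x_columns is not None else table.columns)
    y_columns = list(y_columns if y_columns is not None else table.columns)
    if x_columns == y_columns:
        pairs = [
            (a, b)
            for i, a in enumerate(x_columns)
            for b in x_columns[i + 1:]
        ]
    else:
        pairs = [(a, b) for a in x_columns for b in y_columns if a != b]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = correlate_bonferroni(table[a], table[b], m, names=(a, b))
        rows.append(
            dict(
                x=a, y=b, r=res.r, p_raw=res.p_raw, p_adjusted=res.p_adjusted,
                n_roi=res.n_roi, m=m,
                sig_005=res.significant_005, sig_0005=res.significant_0005,
            )
        )
    return pd.DataFrame(rows)
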