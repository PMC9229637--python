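"""Descriptor-activity correlation: Pearson r between reactivity descriptors
and docking binding energies.

Correlations use the *signed* binding energy (kcal/mol, negative favorable);
pass ``negate_score=True`` to correlate against the magnitude convention
instead, which flips every sign.  Rows with missing values in a correlated
column are dropped (and counted), never imputed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DESCRIPTOR_COLUMNS = ("mu", "omega", "eta", "softness", "gap")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sequences (n >= 3).

    Zero variance in either variable is an error: the correlation is
    undefined there, and silently returning 0 would hide it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    return float(stats.pearsonr(x, y).statistic)


def pearson_r_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r plus the two-sided t-based p-value."""
    r = pearson_r(x, y)  # runs the validity checks
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(
    table: pd.DataFrame,
    score_column: str = "binding_energy",
    descriptor_columns: Sequence[str] = DESCRIPTOR_COLUMNS,
    negate_score: bool = False,
    with_p: bool = False,
) -> pd.DataFrame:
    """Correlate each descriptor column against the docking score column.

    Returns a frame with columns ``descriptor``, ``r``, ``n`` (and ``p`` when
    requested), one row per descriptor in the given order.  Rows with any
    missing value among the correlated columns are dropped; the number of
    rows used (``n``) is embedded in the output.
    """
    cols = [*descriptor_columns, score_column]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks column(s): {', '.join(missing)}")
    clean = table[cols].dropna()
    if len(clean) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(clean)}")
    score = clean[score_column].to_numpy()
    if negate_score:
        score = -score
    rows = []
    for d in descriptor_columns:
        if with_p:
            r, p = pearson_r_with_p(clean[d].to_numpy(), score)
            rows.append({"descriptor": d, "r": r, "p": p, "n": len(clean)})
        else:
            rows.append(
                {"descriptor": d, "r": pearson_r(clean[d].to_numpy(), score), "n": len(clean)}
            )
    return pd.DataFrame(rows)
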