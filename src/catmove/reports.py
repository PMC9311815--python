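"""Stratified descriptive summaries for report tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

DESCRIPTIVE_COLS = ["n", "min", "q1", "median", "mean", "q3", "max", "sd"]


def _describe(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {c: (0 if c == "n" else np.nan) for c in DESCRIPTIVE_COLS}
    # quartiles by the linear-interpolation convention (type 7)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        "n": int(len(values)),
        "min": float(np.min(values)),
        "q1": float(q1),
        "median": float(med),
        "mean": float(np.mean(values)),
        "q3": float(q3),
        "max": float(np.max(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
    }


def report_descriptives(
    data: pd.DataFrame,
    value_col: str,
    strat_vars: list[str],
) -> pd.DataFrame:
    """Per-stratum n/min/quartiles/median/mean/max/SD plus an overall row.

    Empty strata appear with n = 0 and blank statistics so partition sums
    remain checkable.
    """
    rows = [{"variable": "overall", "level": "-",
             **_describe(data[value_col].to_numpy(dtype=float))}]
    for var in strat_vars:
        col = data[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        else:
            levels = sorted(col.dropna().unique())
        for lv in levels:
            vals = data.loc[col == lv, value_col].to_numpy(dtype=float)
            rows.append({"variable": var, "level": str(lv), **_describe(vals)})
    return pd.DataFrame(rows, columns=["variable", "level", *DESCRIPTIVE_COLS])
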