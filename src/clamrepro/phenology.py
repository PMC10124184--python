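"""Descriptive phenology: monthly environmental summaries and monthly
maturity-stage composition.

Bottom seawater temperature and chlorophyll-a drive the gametogenic
cycle; this module only summarizes them (monthly mean ± sample SD) and
tabulates the percentage of individuals per maturity stage and month —
no environmental-trigger model is fitted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Six-stage maturity scale (inactive, early active, late active, ripe,
#: partially spawned, regressing) for females and males; sexes are not
#: distinguishable in the inactive stage, reported as the merged code.
INACTIVE_CODE = "F1/M1"
STAGE_CODES = (
    INACTIVE_CODE,
    "F2",
    "F3",
    "F4A",
    "F4B",
    "F5",
    "M2",
    "M3",
    "M4A",
    "M4B",
    "M5",
)
_STAGE_NORMALIZE = {
    "F1": INACTIVE_CODE,
    "M1": INACTIVE_CODE,
    "indeterminate": INACTIVE_CODE,
    **{c: c for c in STAGE_CODES},
}


def monthly_summary(series: pd.DataFrame, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Per-calendar-month mean and sample SD of environmental variables.

    ``series`` needs a ``timestamp`` column (anything
    ``pandas.to_datetime`` accepts; 10-minute to daily cadences alike)
    plus one numeric column per variable.  Timestamps must be strictly
    increasing.  Months with no data are omitted with a warning.
    Returns a tidy frame (month, variable, mean, sd, n).
    """
    if len(series) == 0:
        raise ValueError("empty environmental series")
    if "timestamp" not in series.columns:
        raise ValueError("series needs a 'timestamp' column")
    ts = pd.to_datetime(series["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    if value_columns is None:
        value_columns = [
            c for c in series.columns if c != "timestamp" and pd.api.types.is_numeric_dtype(series[c])
        ]
    if not value_columns:
        raise ValueError("no numeric variables to summarize")

    month = ts.dt.to_period("M")
    out_rows = []
    for col in value_columns:
        grouped = series[col].groupby(month.values)
        agg = grouped.agg(["mean", "std", "count"])
        for m, row in agg.iterrows():
            out_rows.append(
                {
                    "month": str(m),
                    "variable": col,
                    "mean": float(row["mean"]),
                    "sd": float(row["std"]) if row["count"] > 1 else 0.0,
                    "n": int(row["count"]),
                }
            )
    out = pd.DataFrame(out_rows).sort_values(["variable", "month"]).reset_index(drop=True)

    span = pd.period_range(month.min(), month.max(), freq="M")
    observed = set(out["month"])
    empty = [str(m) for m in span if str(m) not in observed]
    if empty:
        warnings.warn(f"months with no data omitted: {empty}", UserWarning, stacklevel=2)
    return out


def stage_composition(records: pd.DataFrame) -> pd.DataFrame:
    """Monthly maturity-stage composition in percent, per sex.

    ``records`` needs columns month, sex, stage; stage codes follow the
    six-stage scale, with F1, M1 and indeterminate individuals merged
    into the inactive code ``F1/M1``.  Returns a tidy frame (month, sex,
    stage, percent, n_month) where percentages within each (month, sex)
    sum to 100.
    """
    required = {"month", "sex", "stage"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    stages = records["stage"].astype(str)
    unknown = sorted(set(stages) - set(_STAGE_NORMALIZE))
    if unknown:
        raise ValueError(
            f"unknown stage codes {unknown}; valid codes are "
            f"{sorted(set(_STAGE_NORMALIZE))}"
        )
    data = records.copy()
    data["stage"] = stages.map(_STAGE_NORMALIZE)
    data.loc[data["stage"] == INACTIVE_CODE, "sex"] = "indeterminate"

    rows = []
    for (m, sex), sub in data.groupby(["month", "sex"], observed=True):
        n = len(sub)
        counts = sub["stage"].value_counts()
        for stage, cnt in counts.items():
            rows.append(
                {
                    "month": m,
                    "sex": sex,
                    "stage": stage,
                    "percent": 100.0 * cnt / n,
                    "n_month": n,
                }
            )
    out = pd.DataFrame(rows).sort_values(["month", "sex", "stage"]).reset_index(drop=True)
    sums = out.groupby(["month", "sex"], observed=True)["percent"].sum()
    assert np.allclose(sums, 100.0, atol=0.01)
    return out
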