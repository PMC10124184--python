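"""Cohort-level statistics: size regressions, occupancy ANOVA/Tukey,
log-count ANCOVA and the MCRS egg-output scenario.

The reference analyses are the two ordinary-least-squares fits

    G_v = 17.2 · TL − 304.5        (gonad volume, mm³ on shell length, mm)
    PF  = 3.01e4 · TL − 5.21e5     (mature oocytes per ripe female)

with mean-response confidence intervals at a new length, a two-way
fixed-effects ANOVA of percent gonad occupancy on maturity stage (4A
ripe vs 4B partially spawned) × oocyte development stage (mature vs
immature) with Tukey HSD contrasts, an ANCOVA of log oocyte number on
the same factors controlling for log shell length, and the comparison
of predicted egg output between the old (25 mm) and the new (22 mm)
Minimum Conservation Reference Size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import MultiComparison


@dataclass
class LinearFit:
    """Simple linear regression y = slope·x + intercept with the design
    summaries needed for interval prediction."""

    slope: float
    intercept: float
    adj_r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    resid_se: float
    n: int
    x_mean: float
    ssx: float
    x_range: tuple[float, float]

    @classmethod
    def from_coefficients(cls, slope: float, intercept: float) -> "LinearFit":
        """A degenerate fit carrying only published coefficients; point
        predictions work, interval predictions collapse to the point."""
        return cls(
            slope=slope,
            intercept=intercept,
            adj_r2=float("nan"),
            f_stat=float("nan"),
            df=(1, 0),
            p_value=float("nan"),
            resid_se=0.0,
            n=0,
            x_mean=float("nan"),
            ssx=float("nan"),
            x_range=(float("-inf"), float("inf")),
        )

    def predict(self, x0: float) -> float:
        return self.slope * x0 + self.intercept


@dataclass
class McrsScenario:
    """Predicted egg output under two minimum landing sizes."""

    mcrs_new_mm: float
    mcrs_old_mm: float
    pf_new: float
    pf_old: float
    ci_new: tuple[float, float]
    ci_old: tuple[float, float]
    percent_reduction: float
    percent_reduction_rounded: float
    percent_increase_old_over_new: float

    def to_dict(self) -> dict:
        return {
            "mcrs_new_mm": self.mcrs_new_mm,
            "mcrs_old_mm": self.mcrs_old_mm,
            "pf_new": self.pf_new,
            "pf_old": self.pf_old,
            "ci_new": list(self.ci_new),
            "ci_old": list(self.ci_old),
            "percent_reduction": self.percent_reduction,
            "percent_reduction_rounded": self.percent_reduction_rounded,
            "percent_increase_old_over_new": self.percent_increase_old_over_new,
        }


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x with slope F-test and adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - res.fittedvalues
    sse = float(resid @ resid)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df=(1, n - 2),
        p_value=float(res.f_pvalue),
        resid_se=math.sqrt(sse / (n - 2)),
        n=n,
        x_mean=float(x.mean()),
        ssx=float(((x - x.mean()) ** 2).sum()),
        x_range=(float(x.min()), float(x.max())),
    )


def predict_with_ci(
    fit: LinearFit,
    x0: float,
    level: float = 0.95,
    interval: str = "mean",
) -> tuple[float, float, float]:
    """Point prediction at x0 with a t-based confidence interval.

    ``interval="mean"`` (default) gives the CI for the mean response;
    ``"prediction"`` widens it to a new single observation.  Predicting
    outside the observed x range records a warning but proceeds.
    """
    if interval not in ("mean", "prediction"):
        raise ValueError("interval must be 'mean' or 'prediction'")
    point = fit.predict(x0)
    if not fit.x_range[0] <= x0 <= fit.x_range[1]:
        warnings.warn(
            f"prediction at x0={x0} extrapolates beyond the observed range "
            f"{fit.x_range}",
            UserWarning,
            stacklevel=2,
        )
    if fit.resid_se == 0 or fit.n < 3 or not math.isfinite(fit.ssx):
        return (point, point, point)
    leverage = 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.ssx
    if interval == "prediction":
        leverage += 1.0
    se = fit.resid_se * math.sqrt(leverage)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n - 2)
    return (point, point - tq * se, point + tq * se)


def mcrs_scenario(
    fit: LinearFit,
    mcrs_new_mm: float = 22.0,
    mcrs_old_mm: float = 25.0,
    level: float = 0.95,
) -> McrsScenario:
    """Egg-output comparison between two minimum landing sizes.

    The headline percentage change is reported raw and rounded to the
    nearest multiple of 10, in both directions (reduction new-vs-old and
    increase old-vs-new).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p_new, lo_new, hi_new = predict_with_ci(fit, mcrs_new_mm, level)
        p_old, lo_old, hi_old = predict_with_ci(fit, mcrs_old_mm, level)
    if p_new <= 0 or p_old <= 0:
        raise ValueError(
            f"non-positive predicted egg output (new={p_new:.3g}, old={p_old:.3g})"
        )
    reduction = 100.0 * (p_old - p_new) / p_old
    return McrsScenario(
        mcrs_new_mm=mcrs_new_mm,
        mcrs_old_mm=mcrs_old_mm,
        pf_new=p_new,
        pf_old=p_old,
        ci_new=(lo_new, hi_new),
        ci_old=(lo_old, hi_old),
        percent_reduction=reduction,
        percent_reduction_rounded=10.0 * round(reduction / 10.0),
        percent_increase_old_over_new=100.0 * (p_old - p_new) / p_new,
    )


def _tukey_frame(mc: MultiComparison) -> pd.DataFrame:
    res = mc.tukeyhsd()
    table = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return table.rename(
        columns={"meandiff": "diff", "p-adj": "p_adj", "lower": "lwr", "upper": "upr"}
    )


def occupancy_anova(df: pd.DataFrame) -> dict:
    """Two-way ANOVA of percent occupancy on maturity stage × oocyte
    development stage, with Tukey HSD contrasts.

    ``df`` needs columns specimen_id, stage, dev_class, percent (one row
    per female and oocyte class).  Returns the type-II two-way table, a
    one-way ANOVA of per-female total occupancy on stage, and Tukey
    tables for the four cells and both marginals.  Type-II sums of
    squares are used because the reference design is unbalanced (20 ripe
    vs 6 partially spawned females).
    """
    required = {"specimen_id", "stage", "dev_class", "percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = df.copy()
    cells = data.groupby(["stage", "dev_class"], observed=True).size()
    for stage in data["stage"].unique():
        for dev_class in data["dev_class"].unique():
            n = cells.get((stage, dev_class), 0)
            if n < 2:
                raise ValueError(
                    f"cell (stage={stage}, dev_class={dev_class}) has {n} "
                    "observations; need at least 2"
                )

    model = smf.ols("percent ~ C(stage) * C(dev_class)", data=data).fit()
    twoway = anova_lm(model, typ=2)

    totals = (
        data.groupby(["specimen_id", "stage"], observed=True)["percent"]
        .sum()
        .reset_index()
    )
    oneway_model = smf.ols("percent ~ C(stage)", data=totals).fit()
    oneway = anova_lm(oneway_model, typ=2)

    cell_label = data["stage"].astype(str) + ":" + data["dev_class"].astype(str)
    tukey = {
        "cells": _tukey_frame(MultiComparison(data["percent"], cell_label)),
        "stage": _tukey_frame(MultiComparison(data["percent"], data["stage"])),
        "dev_class": _tukey_frame(MultiComparison(data["percent"], data["dev_class"])),
    }
    return {"anova": twoway, "oneway_total": oneway, "tukey": tukey}


def count_ancova(df: pd.DataFrame) -> dict:
    """Two-way ANCOVA of log oocyte number on maturity stage × oocyte
    development stage with log shell length as covariate.

    ``df`` needs columns specimen_id, stage, dev_class, count, TL_mm;
    counts and lengths are natural-log transformed.  The
    homogeneity-of-slopes check (covariate × factor interactions) is
    reported first; simple main effects compare maturity stages within
    each oocyte class, adjusted for length.
    """
    required = {"specimen_id", "stage", "dev_class", "count", "TL_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = df.copy()
    if (data["count"] <= 0).any() or (data["TL_mm"] <= 0).any():
        raise ValueError("counts and lengths must be positive for log transform")
    data["log_count"] = np.log(data["count"].astype(float))
    data["log_TL"] = np.log(data["TL_mm"].astype(float))

    full = smf.ols(
        "log_count ~ C(stage) * C(dev_class) * log_TL", data=data
    ).fit()
    additive = smf.ols(
        "log_count ~ C(stage) * C(dev_class) + log_TL", data=data
    ).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("singular design in homogeneity-of-slopes model")
    slopes_test = anova_lm(additive, full)

    ancova = anova_lm(additive, typ=2)

    simple_effects = {}
    for dev_class, sub in data.groupby("dev_class", observed=True):
        if sub["stage"].nunique() < 2:
            continue
        m = smf.ols("log_count ~ C(stage) + log_TL", data=sub).fit()
        tab = anova_lm(m, typ=2)
        adj = m.params.get("C(stage)[T.F4B]", np.nan)
        if np.isnan(adj):
            stage_terms = [p for p in m.params.index if p.startswith("C(stage)")]
            adj = m.params[stage_terms[0]] if stage_terms else np.nan
        simple_effects[dev_class] = {
            "anova": tab,
            "adjusted_log_difference": float(adj),
        }
    return {
        "homogeneity_of_slopes": slopes_test,
        "ancova": ancova,
        "simple_effects": simple_effects,
    }
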