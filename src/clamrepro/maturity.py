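"""Maturity classification and size-at-maturity (TL50) ogive fitting.

A clam is scored on a dichotomous scale: females are mature as soon as
any vitellogenic oocyte (maximum diameter above 60 μm) is seen in the
gonad smear, males when spermatozoa with well elongated tails are
present.  The proportion of mature individuals per shell-length class is
then fitted with a logistic ogive

    p(TL) = 1 / (1 + exp(-(a + b * TL)))

by binomial maximum likelihood on class midpoints; TL50 = -a/b is the
length at which half the population is mature, with a delta-method
standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

#: Maximum diameter (μm) separating previtellogenic (immature) from
#: vitellogenic (mature) oocytes.  A female is mature when any oocyte
#: exceeds this diameter.
MATURITY_THRESHOLD_UM = 60.0

VALID_SEXES = ("F", "M", "indeterminate")


@dataclass(frozen=True)
class MaturityRecord:
    """One specimen scored on the dichotomous maturity scale.

    ``mature`` is ``None`` for indeterminate individuals (sex not
    assignable); these are excluded from ogive fits.
    """

    specimen_id: str
    TL_mm: float
    sex: str
    mature: bool | None

    def __post_init__(self) -> None:
        if self.TL_mm <= 0:
            raise ValueError(f"TL must be positive, got {self.TL_mm}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.sex == "indeterminate" and self.mature is not None:
            raise ValueError("indeterminate specimens have undefined maturity")


@dataclass
class OgiveFit:
    """Fitted logistic maturity ogive."""

    a: float
    b: float
    se_a: float
    se_b: float
    tl50_mm: float
    se_tl50: float
    n_used: int
    sex_filter: str
    class_width_mm: float
    proportions: pd.DataFrame = field(repr=False)
    warnings: list[str] = field(default_factory=list)

    def predict(self, TL_mm):
        return logistic(TL_mm, self.a, self.b)


def logistic(x, a: float, b: float):
    """Logistic maturity probability 1/(1+exp(-(a+b*x)))."""
    return special.expit(a + b * np.asarray(x, dtype=float))


def classify_female(profile_d_max_um) -> str:
    """Classify a female from the oocyte maximum diameters seen in a smear.

    Mature iff any oocyte has d_max strictly above 60 μm; an empty
    observation (no oocytes seen) reads vacuously as "only immature
    oocytes" and classifies as immature.
    """
    d = np.asarray(list(profile_d_max_um), dtype=float)
    if d.size and (d < 0).any():
        raise ValueError("oocyte diameters must be non-negative")
    if d.size and (d > MATURITY_THRESHOLD_UM).any():
        return "mature"
    return "immature"


def classify_male(has_elongated_spermatozoa: bool) -> str:
    """Mature iff spermatozoa with well elongated tails are present."""
    return "mature" if has_elongated_spermatozoa else "immature"


def _binned_proportions(records: list[MaturityRecord], class_width_mm: float) -> pd.DataFrame:
    tl = np.array([r.TL_mm for r in records])
    mat = np.array([bool(r.mature) for r in records])
    bins = np.floor(tl / class_width_mm).astype(int)
    df = pd.DataFrame({"bin": bins, "mature": mat.astype(int)})
    grouped = df.groupby("bin")["mature"].agg(["sum", "count"]).reset_index()
    grouped["midpoint_mm"] = (grouped["bin"] + 0.5) * class_width_mm
    grouped = grouped.rename(columns={"sum": "n_mature", "count": "n"})
    grouped["proportion"] = grouped["n_mature"] / grouped["n"]
    return grouped[["midpoint_mm", "n", "n_mature", "proportion"]]


def _penalized_logistic(x: np.ndarray, succ: np.ndarray, n: np.ndarray, ridge: float = 1e-6):
    """Ridge-penalized binomial fit used when the IRLS fit breaks down
    (complete separation)."""

    def negll(theta):
        eta = theta[0] + theta[1] * x
        # log-likelihood of binomial proportions
        ll = succ * eta - n * np.logaddexp(0.0, eta)
        return -ll.sum() + ridge * (theta @ theta)

    res = optimize.minimize(negll, x0=np.array([0.0, 0.1]), method="BFGS")
    cov = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else np.eye(2)
    return res.x, cov


def fit_ogive(
    records: list[MaturityRecord],
    sex_filter: str = "all",
    class_width_mm: float = 1.0,
) -> OgiveFit:
    """Fit the logistic ogive to the proportion mature per size class.

    Indeterminate specimens are excluded.  The fit is a binomial GLM of
    per-class mature counts on class midpoints, i.e. it weights each
    class by its sample size.  A non-increasing fit (b <= 0) or
    quasi-separation is reported through the ``warnings`` field rather
    than failing silently.
    """
    if sex_filter not in ("all", "F", "M"):
        raise ValueError(f"sex_filter must be 'all', 'F' or 'M', got {sex_filter!r}")
    if class_width_mm <= 0:
        raise ValueError("class width must be positive")

    usable = [r for r in records if r.mature is not None]
    if sex_filter != "all":
        usable = [r for r in usable if r.sex == sex_filter]
    if len(usable) == 0:
        raise ValueError("no classifiable records after filtering")

    props = _binned_proportions(usable, class_width_mm)
    if len(props) < 2:
        raise ValueError("need at least 2 size classes to fit an ogive")
    total_mature = props["n_mature"].sum()
    if total_mature == 0 or total_mature == props["n"].sum():
        raise ValueError("all records share one outcome; ogive undefined")

    x = props["midpoint_mm"].to_numpy(dtype=float)
    succ = props["n_mature"].to_numpy(dtype=float)
    n = props["n"].to_numpy(dtype=float)
    endog = np.column_stack([succ, n - succ])
    exog = sm.add_constant(x)

    fit_warnings: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        for w in caught:
            if "separation" in str(w.message).lower() or "convergence" in str(w.message).lower():
                fit_warnings.append(str(w.message))
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            raise ValueError("non-finite GLM fit")
    except Exception as exc:  # separation or failed convergence
        params, cov = _penalized_logistic(x, succ, n)
        fit_warnings.append(f"fell back to penalized fit: {exc}")

    a, b = float(params[0]), float(params[1])
    if b == 0:
        raise ValueError("fitted slope is zero; TL50 undefined")
    if b < 0:
        fit_warnings.append("fitted ogive is decreasing (b < 0)")

    tl50 = -a / b
    grad = np.array([-1.0 / b, a / b**2])
    var_tl50 = float(grad @ cov @ grad)
    se_tl50 = math.sqrt(var_tl50) if var_tl50 > 0 else float("nan")

    return OgiveFit(
        a=a,
        b=b,
        se_a=float(np.sqrt(cov[0, 0])),
        se_b=float(np.sqrt(cov[1, 1])),
        tl50_mm=tl50,
        se_tl50=se_tl50,
        n_used=len(usable),
        sex_filter=sex_filter,
        class_width_mm=class_width_mm,
        proportions=props,
        warnings=fit_warnings,
    )


def bootstrap_tl50_ci(
    records: list[MaturityRecord],
    sex_filter: str = "all",
    class_width_mm: float = 1.0,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for TL50 (resampling individuals)."""
    rng = np.random.default_rng(seed)
    usable = [r for r in records if r.mature is not None]
    if sex_filter != "all":
        usable = [r for r in usable if r.sex == sex_filter]
    estimates = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(usable), size=len(usable))
        sample = [usable[i] for i in idx]
        try:
            estimates.append(fit_ogive(sample, "all", class_width_mm).tl50_mm)
        except ValueError:
            continue
    if not estimates:
        raise ValueError("no bootstrap replicate produced a fit")
    alpha = (1.0 - level) / 2.0
    return tuple(np.quantile(estimates, [alpha, 1.0 - alpha]))


def records_to_frame(records: list[MaturityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "TL_mm": [r.TL_mm for r in records],
            "sex": [r.sex for r in records],
            "mature": [r.mature for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[MaturityRecord]:
    out = []
    for row in df.itertuples(index=False):
        mature = row.mature
        if pd.isna(mature):
            mature = None
        elif isinstance(mature, str):
            mature = mature.strip().lower() in ("true", "1", "mature", "yes", "2")
        else:
            mature = bool(mature)
        out.append(MaturityRecord(str(row.specimen_id), float(row.TL_mm), str(row.sex), mature))
    return out
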