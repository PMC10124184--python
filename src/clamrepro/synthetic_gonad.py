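"""Synthetic 3-D gonad generator.

Gonads are modelled as germ-grain (Boolean) models: a prolate-spheroid
region whose volume follows the gonad-volume~shell-length regression
G_v = 17.2*TL - 304.5 (mm³, TL in mm), filled with oblate-spheroid
oocytes placed uniformly at random (overlap permitted).  Each oocyte
carries an equatorial diameter d_max, a polar (symmetry-axis) diameter
d_min = aspect*d_max, a random symmetry-axis orientation and a central
spherical nucleus (germinal vesicle).

Two calibration modes are provided:

* ``occupancy`` — oocytes of each developmental class (mature =
  vitellogenic, d_max > 60 μm; immature = previtellogenic) are added
  until their summed geometric volume reaches the configured percentage
  of the region volume (stage 4A: 19.1% mature + 20.5% immature;
  stage 4B: 7.8% + 14.0%).
* ``count`` — the number of mature oocytes is drawn from the partial
  fecundity regression PF = 3.01e4*TL - 5.21e5 with multiplicative
  noise, and the mature occupancy is whatever results; the immature
  class is still occupancy-calibrated.

The model is the ground truth for all downstream stereological
estimators: it records true volume, true per-class counts and true
per-class occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import special

from clamrepro._units import UM3_PER_MM3
from clamrepro.maturity import MaturityRecord

DEV_CLASSES = ("mature", "immature")
STAGE_ALIASES = {
    "4A": "F4A",
    "4B": "F4B",
    "F4A": "F4A",
    "F4B": "F4B",
}


class DiameterSpec(BaseModel):
    """Truncated-normal distribution of oocyte maximum diameter (μm)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    mean_um: float
    sd_um: float
    lower_um: float
    upper_um: float

    @model_validator(mode="after")
    def _check(self) -> "DiameterSpec":
        if self.sd_um <= 0:
            raise ValueError("sd_um must be positive")
        if not 0 < self.lower_um < self.upper_um:
            raise ValueError("need 0 < lower_um < upper_um")
        return self

    def _std_bounds(self) -> tuple[float, float]:
        a = (self.lower_um - self.mean_um) / self.sd_um
        b = (self.upper_um - self.mean_um) / self.sd_um
        return a, b

    def analytic_mean(self) -> float:
        """Mean of the truncated distribution (not the location parameter)."""
        a, b = self._std_bounds()
        phi = lambda t: math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)
        z = special.ndtr(b) - special.ndtr(a)
        return self.mean_um + self.sd_um * (phi(a) - phi(b)) / z

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # inverse-CDF sampling of the truncated normal
        a, b = self._std_bounds()
        ca, cb = special.ndtr(a), special.ndtr(b)
        u = rng.uniform(size=n)
        z = special.ndtri(ca + u * (cb - ca))
        return self.mean_um + self.sd_um * np.clip(
            z,
            (self.lower_um - self.mean_um) / self.sd_um,
            (self.upper_um - self.mean_um) / self.sd_um,
        )


class StageSpec(BaseModel):
    """Per-maturity-stage occupancy targets and diameter distributions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    occupancy_mature_pct: float
    occupancy_immature_pct: float
    dmax_mature: DiameterSpec
    dmax_immature: DiameterSpec

    @model_validator(mode="after")
    def _check(self) -> "StageSpec":
        if self.occupancy_mature_pct < 0 or self.occupancy_immature_pct < 0:
            raise ValueError("occupancy targets must be non-negative")
        if self.occupancy_mature_pct + self.occupancy_immature_pct > 100:
            raise ValueError("occupancy targets exceed 100%")
        return self

    @property
    def occupancy_total_pct(self) -> float:
        return self.occupancy_mature_pct + self.occupancy_immature_pct

    def diameter_spec(self, dev_class: str) -> DiameterSpec:
        return self.dmax_mature if dev_class == "mature" else self.dmax_immature

    def occupancy_pct(self, dev_class: str) -> float:
        return (
            self.occupancy_mature_pct
            if dev_class == "mature"
            else self.occupancy_immature_pct
        )


def _default_stages() -> dict:
    return {
        "F4A": StageSpec(
            occupancy_mature_pct=19.1,
            occupancy_immature_pct=20.5,
            dmax_mature=DiameterSpec(mean_um=70.3, sd_um=25.0, lower_um=60.0, upper_um=154.89),
            dmax_immature=DiameterSpec(mean_um=41.5, sd_um=15.0, lower_um=5.85, upper_um=60.0),
        ),
        "F4B": StageSpec(
            occupancy_mature_pct=7.8,
            occupancy_immature_pct=14.0,
            dmax_mature=DiameterSpec(mean_um=70.1, sd_um=25.0, lower_um=60.0, upper_um=139.21),
            dmax_immature=DiameterSpec(mean_um=38.6, sd_um=15.0, lower_um=9.54, upper_um=60.0),
        ),
    }


class GeneratorConfig(BaseModel):
    """All tunable parameters of the synthetic gonad model.

    Defaults reproduce the reported cohort summaries: the G_v~TL and
    PF~TL regressions, the stage-specific occupancy fractions, the
    stage- and class-specific oocyte diameter means and ranges, the
    60 μm vitellogenesis threshold, and a maturity ogive with
    TL50 = 11.2 mm that saturates (p > 0.99) above 15 mm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    gv_slope_mm3_per_mm: float = 17.2
    gv_intercept_mm3: float = -304.5
    gv_noise_cv: float = 0.08
    pf_slope_per_mm: float = 3.01e4
    pf_intercept: float = -5.21e5
    pf_noise_cv: float = 0.2
    stages: dict[str, StageSpec] = None  # type: ignore[assignment]
    aspect_ratio_range: tuple[float, float] = (0.65, 0.95)
    nucleus_fraction: float = 0.35
    maturity_threshold_um: float = 60.0
    calibration_mode: Literal["occupancy", "count"] = "occupancy"
    ogive_a: float = -16.8
    ogive_b: float = 1.5

    @model_validator(mode="before")
    @classmethod
    def _fill_stages(cls, data):
        if isinstance(data, dict):
            raw = data.get("stages")
            if raw is None:
                data = dict(data)
                data["stages"] = _default_stages()
            else:
                data = dict(data)
                data["stages"] = {
                    STAGE_ALIASES.get(str(k), str(k)): v for k, v in raw.items()
                }
        return data

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        lo, hi = self.aspect_ratio_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("aspect ratios must lie in (0, 1] with lo <= hi")
        if not 0 < self.nucleus_fraction <= lo:
            raise ValueError(
                "nucleus_fraction must be in (0, min aspect ratio] so the "
                "nucleus fits inside the oocyte"
            )
        if self.gv_noise_cv < 0 or self.pf_noise_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        for stage, spec in self.stages.items():
            if spec.dmax_mature.lower_um < self.maturity_threshold_um:
                raise ValueError(
                    f"{stage}: mature d_max lower bound below the "
                    f"{self.maturity_threshold_um} μm maturity threshold"
                )
            if spec.dmax_immature.upper_um > self.maturity_threshold_um:
                raise ValueError(
                    f"{stage}: immature d_max upper bound above the "
                    f"{self.maturity_threshold_um} μm maturity threshold"
                )
        return self

    @property
    def tl50_mm(self) -> float:
        if self.ogive_b == 0:
            raise ValueError("ogive slope b = 0; TL50 undefined")
        return -self.ogive_a / self.ogive_b

    def stage_spec(self, stage: str) -> StageSpec:
        key = STAGE_ALIASES.get(stage, stage)
        if key not in self.stages:
            raise ValueError(f"no stage configuration for {stage!r}")
        return self.stages[key]

    def mean_nucleus_diameters(self, stage: str) -> dict[str, float]:
        """Expected nucleus diameter per class: fraction × mean d_max of
        the (truncated) diameter distribution."""
        spec = self.stage_spec(stage)
        return {
            c: self.nucleus_fraction * spec.diameter_spec(c).analytic_mean()
            for c in DEV_CLASSES
        }

    def gv_mm3(self, TL_mm: float) -> float:
        return self.gv_slope_mm3_per_mm * TL_mm + self.gv_intercept_mm3

    def pf_mean(self, TL_mm: float) -> float:
        return self.pf_slope_per_mm * TL_mm + self.pf_intercept


@dataclass(frozen=True)
class OocyteSpec:
    """A single oocyte: an oblate spheroid with a central nucleus.

    ``d_max`` is the equatorial (maximum) diameter, ``d_min`` the
    diameter along the symmetry axis; ``orientation`` is the unit vector
    of the spheroid's distinct (symmetry) axis.  Geometric volume is
    π/6 · d_min · d_max².
    """

    center_um: tuple[float, float, float]
    d_max_um: float
    d_min_um: float
    orientation: tuple[float, float, float]
    nucleus_diameter_um: float
    dev_class: str
    nucleus_center_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.d_min_um <= self.d_max_um:
            raise ValueError("need 0 < d_min <= d_max")
        if not 0 < self.nucleus_diameter_um <= self.d_min_um:
            raise ValueError("need 0 < nucleus_diameter <= d_min")
        if self.dev_class not in DEV_CLASSES:
            raise ValueError(f"dev_class must be in {DEV_CLASSES}")
        if self.nucleus_center_um is None:
            object.__setattr__(self, "nucleus_center_um", self.center_um)

    @property
    def volume_um3(self) -> float:
        return math.pi / 6.0 * self.d_min_um * self.d_max_um**2


@dataclass
class Oocytes:
    """Column-oriented store for the oocytes of one gonad."""

    center_um: np.ndarray  # (n, 3)
    d_max_um: np.ndarray  # (n,)
    d_min_um: np.ndarray  # (n,)
    axis: np.ndarray  # (n, 3) unit symmetry axis
    nucleus_d_um: np.ndarray  # (n,)
    mature: np.ndarray  # (n,) bool

    @property
    def n(self) -> int:
        return int(self.d_max_um.shape[0])

    @property
    def volume_um3(self) -> np.ndarray:
        d_max = self.d_max_um.astype(float)
        return math.pi / 6.0 * self.d_min_um.astype(float) * d_max * d_max

    def spec(self, i: int) -> OocyteSpec:
        return OocyteSpec(
            center_um=tuple(float(v) for v in self.center_um[i]),
            d_max_um=float(self.d_max_um[i]),
            d_min_um=float(self.d_min_um[i]),
            orientation=tuple(float(v) for v in self.axis[i]),
            nucleus_diameter_um=float(self.nucleus_d_um[i]),
            dev_class="mature" if self.mature[i] else "immature",
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "oocyte_id": np.arange(self.n),
                "x_um": self.center_um[:, 0],
                "y_um": self.center_um[:, 1],
                "z_um": self.center_um[:, 2],
                "d_max_um": self.d_max_um,
                "d_min_um": self.d_min_um,
                "axis_x": self.axis[:, 0],
                "axis_y": self.axis[:, 1],
                "axis_z": self.axis[:, 2],
                "nucleus_d_um": self.nucleus_d_um,
                "dev_class": np.where(self.mature, "mature", "immature"),
            }
        )

    @staticmethod
    def concatenate(parts: list["Oocytes"]) -> "Oocytes":
        return Oocytes(
            center_um=np.concatenate([p.center_um for p in parts]),
            d_max_um=np.concatenate([p.d_max_um for p in parts]),
            d_min_um=np.concatenate([p.d_min_um for p in parts]),
            axis=np.concatenate([p.axis for p in parts]),
            nucleus_d_um=np.concatenate([p.nucleus_d_um for p in parts]),
            mature=np.concatenate([p.mature for p in parts]),
        )


@dataclass
class GonadModel:
    """A simulated gonad with full ground truth.

    The region is a prolate spheroid with semi-axes (a, a, 2a), its long
    axis along z spanning [0, 4a]; ``true_volume_mm3`` is its geometric
    volume.  ``true_occupancy_pct`` maps each class to the summed
    geometric oocyte volume as a percentage of the region volume.
    """

    specimen_id: str
    TL_mm: float
    sex: str
    stage: str
    semi_axes_um: tuple[float, float, float]
    true_volume_mm3: float
    oocytes: Oocytes
    true_counts: dict[str, int]
    true_occupancy_pct: dict[str, float]

    @property
    def axial_extent_um(self) -> float:
        return 2.0 * self.semi_axes_um[2]

    @property
    def true_occupancy_total_pct(self) -> float:
        return sum(self.true_occupancy_pct.values())

    def cross_section_radius_um(self, z_um) -> np.ndarray:
        """Radius of the (circular) region cross-section at height z."""
        a, _, c = self.semi_axes_um
        rel = (np.asarray(z_um, dtype=float) - c) / c
        r2 = 1.0 - rel * rel
        return a * np.sqrt(np.clip(r2, 0.0, None))

    def summary(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "TL_mm": round(self.TL_mm, 6),
            "sex": self.sex,
            "stage": self.stage,
            "true_volume_mm3": round(self.true_volume_mm3, 6),
            "n_oocytes": self.oocytes.n,
            "true_counts": dict(self.true_counts),
            "true_occupancy_pct": {
                k: round(v, 4) for k, v in self.true_occupancy_pct.items()
            },
        }


def _region_semi_axes(volume_um3: float) -> tuple[float, float, float]:
    # prolate spheroid with 2:1:1 axis ratio: V = 4/3 π a² (2a) = 8/3 π a³
    a = (3.0 * volume_um3 / (8.0 * math.pi)) ** (1.0 / 3.0)
    return (a, a, 2.0 * a)


def _uniform_in_spheroid(n: int, semi_axes, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    pts = v * r * np.asarray(semi_axes)
    pts[:, 2] += semi_axes[2]  # region spans z in [0, 2c]
    return pts


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _lognormal_factor(cv: float, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _draw_class(
    spec: DiameterSpec,
    config: GeneratorConfig,
    semi_axes,
    rng: np.random.Generator,
    mature: bool,
    n_target: int | None = None,
    volume_target_um3: float | None = None,
) -> Oocytes:
    """Draw oocytes of one class either to a fixed count or until their
    summed geometric volume first reaches a target."""
    if spec.upper_um > 2.0 * min(semi_axes):
        raise ValueError(
            f"largest possible oocyte ({spec.upper_um} μm) exceeds the region "
            f"minor diameter ({2.0 * min(semi_axes):.1f} μm)"
        )
    lo, hi = config.aspect_ratio_range
    mean_vol = math.pi / 6.0 * 0.5 * (lo + hi) * spec.analytic_mean() ** 3

    chunks: list[tuple[np.ndarray, np.ndarray]] = []
    total = 0
    cum = 0.0
    if n_target is not None:
        need = n_target
        while need > 0:
            d_max = spec.sample(need, rng)
            aspect = rng.uniform(lo, hi, size=need)
            chunks.append((d_max, aspect))
            total += need
            need = 0
    else:
        assert volume_target_um3 is not None
        while cum < volume_target_um3:
            guess = max(16, int(1.1 * (volume_target_um3 - cum) / mean_vol))
            d_max = spec.sample(guess, rng)
            aspect = rng.uniform(lo, hi, size=guess)
            vols = math.pi / 6.0 * aspect * d_max**3
            cumsum = cum + np.cumsum(vols)
            if cumsum[-1] >= volume_target_um3:
                k = int(np.searchsorted(cumsum, volume_target_um3)) + 1
                chunks.append((d_max[:k], aspect[:k]))
                total += k
                cum = float(cumsum[k - 1])
            else:
                chunks.append((d_max, aspect))
                total += guess
                cum = float(cumsum[-1])

    d_max = np.concatenate([c[0] for c in chunks]) if chunks else np.empty(0)
    aspect = np.concatenate([c[1] for c in chunks]) if chunks else np.empty(0)
    d_min = aspect * d_max
    centers = _uniform_in_spheroid(total, semi_axes, rng)
    axes = _random_unit_vectors(total, rng)
    return Oocytes(
        center_um=centers.astype(np.float32),
        d_max_um=d_max.astype(np.float32),
        d_min_um=d_min.astype(np.float32),
        axis=axes.astype(np.float32),
        nucleus_d_um=(config.nucleus_fraction * d_max).astype(np.float32),
        mature=np.full(total, mature),
    )


def generate_gonad(
    TL_mm: float,
    stage: str,
    config: GeneratorConfig | None = None,
    seed: int | np.random.Generator | None = None,
    specimen_id: str = "sim",
    noise: bool = True,
) -> GonadModel:
    """Generate one simulated gonad for a female of shell length TL.

    Only the two reproductively active stages (ripe, F4A, and partially
    spawned, F4B) carry a quantitative oocyte model.  ``noise=False``
    puts the gonad volume exactly on the G_v~TL regression line.
    """
    config = config or GeneratorConfig()
    key = STAGE_ALIASES.get(stage)
    if key is None:
        raise ValueError(f"stage must be 4A or 4B (got {stage!r})")
    spec = config.stage_spec(key)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gv = config.gv_mm3(TL_mm)
    if gv <= 0:
        raise ValueError(
            f"non-positive gonad volume at TL={TL_mm} mm "
            f"(slope {config.gv_slope_mm3_per_mm}, intercept "
            f"{config.gv_intercept_mm3} mm³)"
        )
    if noise:
        gv *= float(_lognormal_factor(config.gv_noise_cv, rng)[0])
    volume_um3 = gv * UM3_PER_MM3
    semi_axes = _region_semi_axes(volume_um3)

    parts: list[Oocytes] = []
    for dev_class in DEV_CLASSES:
        dspec = spec.diameter_spec(dev_class)
        if dev_class == "mature" and config.calibration_mode == "count":
            pf = config.pf_mean(TL_mm)
            if pf <= 0:
                raise ValueError(
                    f"non-positive mature-oocyte count at TL={TL_mm} mm under "
                    "the fecundity~TL model"
                )
            if noise:
                pf *= float(_lognormal_factor(config.pf_noise_cv, rng)[0])
            part = _draw_class(
                dspec, config, semi_axes, rng, mature=True, n_target=max(1, round(pf))
            )
        else:
            target = spec.occupancy_pct(dev_class) / 100.0 * volume_um3
            part = _draw_class(
                dspec,
                config,
                semi_axes,
                rng,
                mature=(dev_class == "mature"),
                volume_target_um3=target,
            )
        parts.append(part)

    oocytes = Oocytes.concatenate(parts)
    vols = oocytes.volume_um3
    true_counts = {
        "mature": int(oocytes.mature.sum()),
        "immature": int((~oocytes.mature).sum()),
    }
    true_occ = {
        "mature": float(vols[oocytes.mature].sum() / volume_um3 * 100.0),
        "immature": float(vols[~oocytes.mature].sum() / volume_um3 * 100.0),
    }
    return GonadModel(
        specimen_id=specimen_id,
        TL_mm=float(TL_mm),
        sex="F",
        stage=key,
        semi_axes_um=semi_axes,
        true_volume_mm3=volume_um3 / UM3_PER_MM3,
        oocytes=oocytes,
        true_counts=true_counts,
        true_occupancy_pct=true_occ,
    )


def _cohort_plan(
    n_4A: int,
    n_4B: int,
    TL_range_mm: tuple[float, float],
    seed: int | None,
):
    if n_4A < 0 or n_4B < 0 or n_4A + n_4B < 1:
        raise ValueError("cohort needs at least one specimen")
    lo, hi = TL_range_mm
    if not lo <= hi:
        raise ValueError(f"empty TL range {TL_range_mm}")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = n_4A + n_4B
    tls = rng.uniform(lo, hi, size=n)
    stages = ["4A"] * n_4A + ["4B"] * n_4B
    child_seeds = ss.spawn(n)
    return tls, stages, child_seeds


def iter_cohort(
    n_4A: int,
    n_4B: int,
    TL_range_mm: tuple[float, float],
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> Iterator[GonadModel]:
    """Stream the gonads of a cohort one at a time (memory-friendly)."""
    config = config or GeneratorConfig()
    tls, stages, child_seeds = _cohort_plan(n_4A, n_4B, TL_range_mm, seed)
    for i, (tl, stage, child) in enumerate(zip(tls, stages, child_seeds)):
        yield generate_gonad(
            tl,
            stage,
            config,
            seed=np.random.default_rng(child),
            specimen_id=f"sim-{i:03d}",
        )


def generate_cohort(
    n_4A: int,
    n_4B: int,
    TL_range_mm: tuple[float, float],
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> list[GonadModel]:
    """Generate a cohort of independent gonads; shell lengths are drawn
    uniformly over ``TL_range_mm`` and the first ``n_4A`` specimens are
    ripe (4A), the remainder partially spawned (4B)."""
    return list(iter_cohort(n_4A, n_4B, TL_range_mm, config, seed))


def generate_maturity_sample(
    n: int,
    TL_range_mm: tuple[float, float],
    a: float | None = None,
    b: float | None = None,
    seed: int | None = None,
    config: GeneratorConfig | None = None,
) -> list[MaturityRecord]:
    """Draw maturity records with Bernoulli maturity from the logistic
    ogive p = 1/(1+exp(-(a+b*TL))); lengths uniform over the range."""
    config = config or GeneratorConfig()
    a = config.ogive_a if a is None else a
    b = config.ogive_b if b is None else b
    if b == 0:
        raise ValueError("ogive slope b = 0; TL50 undefined")
    if n < 0:
        raise ValueError("n must be non-negative")
    lo, hi = TL_range_mm
    if not lo <= hi:
        raise ValueError(f"empty TL range {TL_range_mm}")
    rng = np.random.default_rng(seed)
    tls = rng.uniform(lo, hi, size=n)
    p = special.expit(a + b * tls)
    mature = rng.uniform(size=n) < p
    sexes = rng.choice(["F", "M"], size=n)
    return [
        MaturityRecord(f"mat-{i:04d}", float(tls[i]), str(sexes[i]), bool(mature[i]))
        for i in range(n)
    ]
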