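"""Stereological reconstruction of gonad volume, oocyte number,
occupancy and partial fecundity from section/field observations.

The estimation chain mirrors classical design-based stereology:

* gonad volume by the Cavalieri estimator, G_v = Σ G_a · spacing;
* oocyte number density from nucleus-hit profile counts in known field
  areas, converted to whole-gonad counts via G_v.  Under the
  "intersect" nucleus rule (a profile counts when the slab cuts the
  nucleus anywhere) raw counts overstate number and are de-biased with
  the Abercrombie correction T/(T + nucleus diameter); under the
  "center" rule (slab contains the nucleus centre) counts are unbiased
  as-is and serve as the internal oracle;
* per-class mean oocyte volume from the profile diameters of nucleus-hit
  profiles, assuming spheroidal cells;
* volume occupancy as number × mean volume / gonad volume, with the
  Delesse areal-fraction estimator available as a cross-check;
* partial fecundity (PF) as the estimated number of mature oocytes of a
  ripe (stage 4A) female.

Because larger nuclei are cut by more slabs, nucleus-hit profiles are a
size-biased sample within each class.  The count estimator is immune
(the class-mean Abercrombie factor cancels the mean inflation exactly),
but a plain mean of profile volumes is not; the mean volume therefore
weights each nucleus-hit profile by its own Abercrombie factor
1/(T + nucleus diameter), with the per-profile nucleus diameter read
as nucleus_fraction × profile d_max.  Under the "center" rule hits are
not size-biased and the unweighted mean is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from clamrepro._units import UM3_PER_MM3, UM_PER_MM
from clamrepro.sectioning import SectionPlan, SectionProfileTable
from clamrepro.synthetic_gonad import DEV_CLASSES, GeneratorConfig

VolumeMode = Literal["corrected", "paper"]


@dataclass
class FecundityEstimate:
    """Reconstructed quantities for one female."""

    specimen_id: str
    stage: str
    G_v_hat_mm3: float
    mean_O_v_um3: dict[str, float]
    N_hat: dict[str, float]
    occupancy_pct: dict[str, float]
    PF: float | None
    volume_mode: str
    nucleus_rule: str
    occupancy_delesse_pct: dict[str, float] | None = None

    @property
    def occupancy_total_pct(self) -> float:
        return sum(self.occupancy_pct.values())

    def to_row(self) -> dict:
        row = {
            "specimen_id": self.specimen_id,
            "stage": self.stage,
            "G_v_hat_mm3": self.G_v_hat_mm3,
            "PF": self.PF,
            "volume_mode": self.volume_mode,
            "nucleus_rule": self.nucleus_rule,
        }
        for c in DEV_CLASSES:
            row[f"N_hat_{c}"] = self.N_hat.get(c, 0.0)
            row[f"mean_O_v_um3_{c}"] = self.mean_O_v_um3.get(c, float("nan"))
            row[f"occupancy_pct_{c}"] = self.occupancy_pct.get(c, 0.0)
        row["occupancy_pct_total"] = self.occupancy_total_pct
        if self.occupancy_delesse_pct is not None:
            for c in DEV_CLASSES:
                row[f"occupancy_delesse_pct_{c}"] = self.occupancy_delesse_pct.get(c, 0.0)
        return row


def cavalieri_volume(areas_mm2, spacing_um: float) -> float:
    """Cavalieri volume estimate Σ G_a · spacing, in mm³.

    Exact for regions of constant cross-section and unbiased in general
    for systematic sections with random start.
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one section area")
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    if (areas < 0).any():
        raise ValueError("section areas must be non-negative")
    return float(areas.sum() * spacing_um / UM_PER_MM)


def oocyte_volume(d_min_um, d_max_um, mode: VolumeMode = "corrected"):
    """Spheroid oocyte volume from its minimum and maximum diameters.

    ``corrected`` (default) treats the diameters as full axes of an
    oblate spheroid: V = π/6 · d_min · d_max² (πd³/6 for a sphere).
    ``paper`` applies 4/3 · π · d_min · d_max² verbatim — the formula
    printed with full diameters in place of semi-axes, exactly 8× the
    corrected value — and exists for literal reproduction only.
    """
    d_min = np.asarray(d_min_um, dtype=float)
    d_max = np.asarray(d_max_um, dtype=float)
    if np.any(d_min <= 0) or np.any(d_max <= 0):
        raise ValueError("diameters must be positive")
    if np.any(d_min > d_max):
        raise ValueError("need d_min <= d_max")
    if mode == "corrected":
        out = math.pi / 6.0 * d_min * d_max**2
    elif mode == "paper":
        out = 4.0 / 3.0 * math.pi * d_min * d_max**2
    else:
        raise ValueError(f"unknown volume mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def abercrombie_correction(
    raw_count: float, thickness_um: float, mean_nucleus_diameter_um: float
) -> float:
    """Convert a profile count into a particle-number estimate.

    A nucleus of diameter h is cut by slabs over an axial window of
    length T + h, so raw nucleus-hit counts overstate number by
    (T + h)/T; the correction multiplies by T/(T + h).
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    if mean_nucleus_diameter_um < 0:
        raise ValueError("nucleus diameter must be non-negative")
    return raw_count * thickness_um / (thickness_um + mean_nucleus_diameter_um)


def _nucleus_diameters(
    mean_nucleus_diameter_um: float | Mapping[str, float]
) -> dict[str, float]:
    if isinstance(mean_nucleus_diameter_um, Mapping):
        return {c: float(mean_nucleus_diameter_um[c]) for c in DEV_CLASSES}
    return {c: float(mean_nucleus_diameter_um) for c in DEV_CLASSES}


def estimate_total_count(
    field_rows: pd.DataFrame,
    field_area_um2: float,
    thickness_um: float,
    mean_nucleus_diameter_um: float | Mapping[str, float],
    G_v_hat_mm3: float,
    nucleus_rule: str = "intersect",
) -> dict[str, float]:
    """Whole-gonad oocyte count per class from field observations.

    Only nucleus-hit rows are counted.  The per-class number density is
    (corrected count) / (total field area × thickness), the Abercrombie
    correction being applied only under the "intersect" rule, and the
    density is scaled to the reconstructed gonad volume.
    ``field_area_um2`` is the summed area of all sampled fields.
    """
    if field_area_um2 <= 0:
        raise ValueError("total field area must be positive")
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    if nucleus_rule not in ("intersect", "center"):
        raise ValueError(f"unknown nucleus rule {nucleus_rule!r}")
    dn = _nucleus_diameters(mean_nucleus_diameter_um)
    hits = field_rows[field_rows["nucleus_hit"].astype(bool)]
    out: dict[str, float] = {}
    for dev_class in DEV_CLASSES:
        raw = int((hits["dev_class"] == dev_class).sum())
        corrected = (
            abercrombie_correction(raw, thickness_um, dn[dev_class])
            if nucleus_rule == "intersect"
            else float(raw)
        )
        density = corrected / (field_area_um2 * thickness_um)  # per μm³
        out[dev_class] = density * G_v_hat_mm3 * UM3_PER_MM3
    return out


def occupancy_percent(N_hat: float, mean_O_v_um3: float, G_v_hat_mm3: float) -> float:
    """Percent of the gonad volume occupied: 100 · N · mean volume / G_v."""
    if G_v_hat_mm3 <= 0:
        raise ValueError("gonad volume must be positive")
    if N_hat < 0 or mean_O_v_um3 < 0:
        raise ValueError("inputs must be non-negative")
    return 100.0 * N_hat * mean_O_v_um3 / (G_v_hat_mm3 * UM3_PER_MM3)


def _cap_integral(y):
    """F(y) = ∫_0^y (1 - x²)^{3/2} dx (closed form)."""
    y = np.asarray(y, dtype=float)
    return (y * (1.0 - y * y) ** 1.5) / 4.0 + 0.375 * (
        y * np.sqrt(1.0 - y * y) + np.arcsin(y)
    )


def profile_shape_factor(
    d_max_um,
    thickness_um: float,
    nucleus_fraction: float,
    aspect_range: tuple[float, float],
    nucleus_rule: str = "intersect",
) -> np.ndarray:
    """Expected inflation of the best-plane profile volume of a randomly
    oriented oblate spheroid cut through its nucleus.

    The measured profile is the largest in-plane section within the
    slab, so its implied volume π/6·p_min·p_max² equals the true volume
    times s³/W̃, where W̃ = sqrt(1 - (1-q²)t²) is the normalized axial
    half-extent (q the aspect ratio, t the cosine of the symmetry-axis
    tilt) and s the offset scaling of the admissible plane closest to
    the centre.  Averaging over isotropic orientation, the configured
    aspect-ratio distribution and the cut-offset distribution given a
    nucleus hit yields a volume-weighted factor

        κ(d) = P₀·A + (1 - P₀)·B,     P₀ = T / (f·d + T)

    (P₀ the probability that the slab contains the centre, f the
    nucleus fraction); A and B are d-independent geometry constants.
    Dividing profile volumes by κ removes the measurement-convention
    bias.  Under the "center" rule the cut always passes through the
    centre, so κ = A.
    """
    lo, hi = aspect_range
    # Gauss-Legendre nodes over q (aspect) and t (axis tilt cosine)
    qx, qw = np.polynomial.legendre.leggauss(24)
    q = 0.5 * (hi - lo) * qx + 0.5 * (hi + lo)
    wq = 0.5 * (hi - lo) * qw
    t = 0.5 * qx + 0.5
    wt = 0.5 * qw
    Q, Tt = np.meshgrid(q, t, indexing="ij")
    W = np.sqrt(1.0 - (1.0 - Q * Q) * Tt * Tt)
    wgt = np.outer(wq * q, wt)  # volume (q-) weighted orientation average
    norm = wgt.sum()
    A = float((wgt / W).sum() / norm)
    f = nucleus_fraction
    B = float((wgt * _cap_integral(np.minimum(f / W, 1.0)) / f).sum() / norm)
    d = np.asarray(d_max_um, dtype=float)
    if nucleus_rule == "center":
        return np.full_like(d, A)
    p0 = thickness_um / (f * d + thickness_um)
    return p0 * A + (1.0 - p0) * B


def profile_mean_volume(
    class_hits: pd.DataFrame,
    mode: VolumeMode,
    thickness_um: float,
    nucleus_fraction: float | None,
    nucleus_rule: str,
    aspect_range: tuple[float, float] | None = None,
) -> float:
    """Mean oocyte volume over the nucleus-hit profiles of one class.

    Under the "intersect" rule profiles are weighted by their own
    Abercrombie factor 1/(T + nucleus_fraction · profile d_max) to undo
    the size bias of nucleus-hit sampling; with no nucleus-size model
    (``nucleus_fraction=None``) the plain mean is returned.  When the
    aspect-ratio range of the spheroid model is known, each profile
    volume is additionally divided by the analytic shape factor
    :func:`profile_shape_factor`.
    """
    if len(class_hits) == 0:
        return float("nan")
    p_max = class_hits["profile_d_max_um"].to_numpy()
    vols = oocyte_volume(
        class_hits["profile_d_min_um"].to_numpy(), p_max, mode
    )
    vols = np.atleast_1d(vols).astype(float)
    if aspect_range is not None and nucleus_fraction is not None:
        vols = vols / profile_shape_factor(
            p_max, thickness_um, nucleus_fraction, aspect_range, nucleus_rule
        )
    if nucleus_rule == "intersect" and nucleus_fraction is not None:
        weights = 1.0 / (thickness_um + nucleus_fraction * p_max)
        return float(np.average(vols, weights=weights))
    return float(vols.mean())


def delesse_occupancy(
    field_rows: pd.DataFrame, field_area_um2: float
) -> dict[str, float]:
    """Delesse areal-fraction occupancy: Σ profile ellipse areas / field
    area, per class (all profiles in the fields, not only nucleus hits)."""
    if field_area_um2 <= 0:
        raise ValueError("total field area must be positive")
    out = {}
    for dev_class in DEV_CLASSES:
        sub = field_rows[field_rows["dev_class"] == dev_class]
        areas = (
            math.pi
            / 4.0
            * sub["profile_d_min_um"].to_numpy()
            * sub["profile_d_max_um"].to_numpy()
        )
        out[dev_class] = float(areas.sum() / field_area_um2 * 100.0)
    return out


def estimate_fecundity(
    table: SectionProfileTable,
    config: GeneratorConfig | None = None,
    mode: VolumeMode = "corrected",
    nucleus_rule: str | None = None,
    mean_nucleus_diameter_um: float | Mapping[str, float] | None = None,
    nucleus_fraction: float | None = None,
    aspect_range: tuple[float, float] | None = None,
    delesse: bool = False,
) -> FecundityEstimate:
    """Full per-specimen reconstruction from a field-sampled table.

    Composes Cavalieri volume → total counts → occupancy; PF is the
    mature-oocyte count and is defined only for ripe (4A) females.
    ``mean_nucleus_diameter_um`` defaults to nucleus_fraction × class
    mean d_max from the generator configuration; for real data pass the
    measured values.
    """
    stage = table.stage
    if stage not in ("F4A", "F4B"):
        raise ValueError(
            f"fecundity estimation is defined for stages 4A/4B, got {stage!r}"
        )
    if table.total_field_area_um2 is None:
        raise ValueError("table has no sampled fields; run sample_fields first")
    plan: SectionPlan = table.plan
    rule = nucleus_rule or plan.nucleus_rule
    if mean_nucleus_diameter_um is None:
        if config is None:
            raise ValueError(
                "provide mean_nucleus_diameter_um or a GeneratorConfig to derive it"
            )
        mean_nucleus_diameter_um = config.mean_nucleus_diameters(stage)
    if nucleus_fraction is None and config is not None:
        nucleus_fraction = config.nucleus_fraction
    if aspect_range is None and config is not None:
        aspect_range = config.aspect_ratio_range

    G_v_hat = cavalieri_volume(table.areas["G_a_mm2"].to_numpy(), plan.spacing_um)
    field_rows = table.profiles
    N_hat = estimate_total_count(
        field_rows,
        table.total_field_area_um2,
        plan.thickness_um,
        mean_nucleus_diameter_um,
        G_v_hat,
        rule,
    )
    hits = field_rows[field_rows["nucleus_hit"].astype(bool)]
    mean_O_v: dict[str, float] = {}
    occupancy: dict[str, float] = {}
    for dev_class in DEV_CLASSES:
        class_hits = hits[hits["dev_class"] == dev_class]
        mean_O_v[dev_class] = profile_mean_volume(
            class_hits, mode, plan.thickness_um, nucleus_fraction, rule, aspect_range
        )
        if N_hat[dev_class] == 0 or math.isnan(mean_O_v[dev_class]):
            occupancy[dev_class] = 0.0
        else:
            occupancy[dev_class] = occupancy_percent(
                N_hat[dev_class], mean_O_v[dev_class], G_v_hat
            )
    occupancy_del = (
        delesse_occupancy(field_rows, table.total_field_area_um2) if delesse else None
    )
    return FecundityEstimate(
        specimen_id=table.specimen_id,
        stage=stage,
        G_v_hat_mm3=G_v_hat,
        mean_O_v_um3=mean_O_v,
        N_hat=N_hat,
        occupancy_pct=occupancy,
        PF=N_hat["mature"] if stage == "F4A" else None,
        volume_mode=mode,
        nucleus_rule=rule,
        occupancy_delesse_pct=occupancy_del,
    )


def estimates_to_frame(estimates: list[FecundityEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_row() for e in estimates])
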