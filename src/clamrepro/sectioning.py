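"""Virtual serial sectioning and microscope-field sampling.

A gonad model is cut into slabs of configurable thickness (default
6 μm) whose starts are spaced at a fixed step (default 100 μm) along
the region's long axis, mirroring the histological protocol of one
6-μm section every 100 μm.  Each slab yields

* the analytic cross-sectional area of the gonad region at the slab
  mid-plane (the per-section gonad area G_a), and
* one profile row per oocyte whose spheroid intersects the slab, with
  the maximum and minimum diameters of the largest in-plane
  cross-section within the slab and a flag recording whether the slab
  cuts through the nucleus.

Field sampling then retains only profiles whose centres fall in
randomly placed rectangular camera fields, reproducing the counting
protocol of a fixed number of random fields per gonad.

Geometry.  For an oblate spheroid with equatorial semi-axis ae =
d_max/2, polar semi-axis ap = d_min/2 and unit symmetry axis u, the
half-extent along the section normal e_z is w = sqrt(ae² + (ap² - ae²)
u_z²).  A plane at offset h (|h| < w) from the centre cuts an ellipse
with semi-axes ae·s and ae·ap·s/w where s = sqrt(1 - h²/w²); the
largest cross-section within a slab is attained at the admissible plane
closest to the centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from clamrepro._units import UM2_PER_MM2
from clamrepro.synthetic_gonad import GonadModel, OocyteSpec

PROFILE_COLUMNS = [
    "specimen_id",
    "section_index",
    "z_start_um",
    "field_id",
    "oocyte_id",
    "dev_class",
    "profile_d_max_um",
    "profile_d_min_um",
    "nucleus_hit",
]


class SectionPlan(BaseModel):
    """Sectioning and field-sampling protocol."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    thickness_um: float = 6.0
    spacing_um: float = 100.0
    field_count: int = 6
    field_width_um: float = 870.0
    field_height_um: float = 660.0
    nucleus_rule: Literal["intersect", "center"] = "intersect"

    @model_validator(mode="after")
    def _check(self) -> "SectionPlan":
        if self.spacing_um <= 0:
            raise ValueError("section spacing must be positive")
        if not 0 < self.thickness_um <= self.spacing_um:
            raise ValueError("need 0 < thickness <= spacing")
        if self.field_count < 1:
            raise ValueError("need at least one field")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        return self

    @property
    def field_area_um2(self) -> float:
        return self.field_width_um * self.field_height_um


@dataclass
class SectionProfileTable:
    """Per-section oocyte profile observations for one specimen.

    ``profiles`` holds one row per (oocyte, slab) intersection (columns
    in ``PROFILE_COLUMNS`` order plus the in-plane profile-centre
    coordinates used for field sampling); ``areas`` the per-section
    gonad cross-section areas.  After :func:`sample_fields`, ``fields``
    describes the placed fields and ``total_field_area_um2`` their
    summed effective area.
    """

    specimen_id: str
    stage: str
    plan: SectionPlan
    profiles: pd.DataFrame
    areas: pd.DataFrame
    fields: pd.DataFrame | None = None
    total_field_area_um2: float | None = None

    @property
    def n_sections(self) -> int:
        return len(self.areas)

    def profiles_csv_frame(self) -> pd.DataFrame:
        """Profiles with the canonical column order first."""
        extra = [c for c in self.profiles.columns if c not in PROFILE_COLUMNS]
        return self.profiles[PROFILE_COLUMNS + extra]


def slab_profile(
    oocyte: OocyteSpec,
    z_start_um: float,
    z_end_um: float,
    nucleus_rule: str = "intersect",
) -> tuple[float, float, bool] | None:
    """Profile of a single oocyte in the slab [z_start, z_end).

    Returns (profile_d_max, profile_d_min, nucleus_hit) in μm, or
    ``None`` when the spheroid does not intersect the slab.  The profile
    is the largest in-plane cross-section over planes inside the slab.
    """
    if not z_start_um < z_end_um:
        raise ValueError("need z_start < z_end")
    ae = oocyte.d_max_um / 2.0
    ap = oocyte.d_min_um / 2.0
    uz = oocyte.orientation[2]
    w = math.sqrt(ae * ae + (ap * ap - ae * ae) * uz * uz)
    zc = oocyte.center_um[2]
    z0 = min(max(zc, z_start_um), z_end_um)
    h = z0 - zc
    if abs(h) >= w:
        return None
    s = math.sqrt(1.0 - (h / w) ** 2)
    p_max = 2.0 * ae * s
    p_min = 2.0 * ae * ap * s / w
    zn = oocyte.nucleus_center_um[2]
    rn = oocyte.nucleus_diameter_um / 2.0
    if nucleus_rule == "intersect":
        hit = (zn + rn > z_start_um) and (zn - rn < z_end_um)
    elif nucleus_rule == "center":
        hit = z_start_um <= zn < z_end_um
    else:
        raise ValueError(f"unknown nucleus rule {nucleus_rule!r}")
    return (p_max, p_min, bool(hit))


def section_gonad(gonad: GonadModel, plan: SectionPlan | None = None) -> SectionProfileTable:
    """Cut a gonad model into serial slabs and tabulate all profiles.

    Deterministic given (gonad, plan): slabs start at z = 0 (the
    region's minimum axial extent) and tile its full length.
    """
    plan = plan or SectionPlan()
    extent = gonad.axial_extent_um
    if extent <= 0 or gonad.true_volume_mm3 <= 0:
        raise ValueError("gonad region is empty")
    sp = plan.spacing_um
    T = plan.thickness_um
    n_sections = int(math.ceil(extent / sp))
    starts = np.arange(n_sections) * sp
    mids = starts + T / 2.0
    radii = gonad.cross_section_radius_um(mids)
    areas_um2 = math.pi * radii * radii
    areas = pd.DataFrame(
        {
            "specimen_id": gonad.specimen_id,
            "section_index": np.arange(n_sections),
            "z_start_um": starts,
            "G_a_mm2": areas_um2 / UM2_PER_MM2,
        }
    )

    oo = gonad.oocytes
    if oo.n == 0:
        profiles = pd.DataFrame(
            columns=PROFILE_COLUMNS + ["profile_x_um", "profile_y_um"]
        )
        return SectionProfileTable(gonad.specimen_id, gonad.stage, plan, profiles, areas)

    ae = oo.d_max_um.astype(np.float64) / 2.0
    ap = oo.d_min_um.astype(np.float64) / 2.0
    uz = oo.axis[:, 2].astype(np.float64)
    w = np.sqrt(ae * ae + (ap * ap - ae * ae) * uz * uz)
    zc = oo.center_um[:, 2].astype(np.float64)

    # slab indices k with k*sp < zc + w and k*sp + T > zc - w
    k_min = np.maximum(np.floor((zc - w - T) / sp).astype(np.int64) + 1, 0)
    k_max = np.minimum(np.ceil((zc + w) / sp).astype(np.int64) - 1, n_sections - 1)
    counts = np.maximum(k_max - k_min + 1, 0)
    total = int(counts.sum())
    if total == 0:
        profiles = pd.DataFrame(
            columns=PROFILE_COLUMNS + ["profile_x_um", "profile_y_um"]
        )
        return SectionProfileTable(gonad.specimen_id, gonad.stage, plan, profiles, areas)

    idx = np.repeat(np.arange(oo.n), counts)
    group_start = np.repeat(np.cumsum(counts) - counts, counts)
    k = np.repeat(k_min, counts) + (np.arange(total) - group_start)

    zc_r = zc[idx]
    w_r = w[idx]
    z_start = k * sp
    z0 = np.clip(zc_r, z_start, z_start + T)
    h = z0 - zc_r
    keep = np.abs(h) < w_r
    idx, k, z_start, z0, h = idx[keep], k[keep], z_start[keep], z0[keep], h[keep]
    zc_r, w_r = zc_r[keep], w_r[keep]

    ae_r = ae[idx]
    ap_r = ap[idx]
    s = np.sqrt(1.0 - (h / w_r) ** 2)
    p_max = 2.0 * ae_r * s
    p_min = 2.0 * ae_r * ap_r * s / w_r

    # nucleus intersection along z (nucleus centred on the oocyte centre)
    rn = oo.nucleus_d_um.astype(np.float64)[idx] / 2.0
    if plan.nucleus_rule == "intersect":
        hit = (zc_r + rn > z_start) & (zc_r - rn < z_start + T)
    else:  # center rule
        hit = (z_start <= zc_r) & (zc_r < z_start + T)

    # in-plane centre of the profile ellipse: the section-ellipse centre
    # is offset from the oocyte centre by h * (M e_z)_xy / w², where
    # M = ae² I + (ap² - ae²) u uᵀ
    coef = (ap_r * ap_r - ae_r * ae_r) * oo.axis[idx, 2].astype(np.float64) * h / (w_r * w_r)
    px = oo.center_um[idx, 0].astype(np.float64) + coef * oo.axis[idx, 0].astype(np.float64)
    py = oo.center_um[idx, 1].astype(np.float64) + coef * oo.axis[idx, 1].astype(np.float64)

    profiles = pd.DataFrame(
        {
            "specimen_id": gonad.specimen_id,
            "section_index": k.astype(np.int64),
            "z_start_um": z_start,
            "field_id": pd.array([pd.NA] * len(k), dtype="Int64"),
            "oocyte_id": idx.astype(np.int64),
            "dev_class": np.where(oo.mature[idx], "mature", "immature"),
            "profile_d_max_um": p_max,
            "profile_d_min_um": p_min,
            "nucleus_hit": hit,
            "profile_x_um": px,
            "profile_y_um": py,
        }
    )
    return SectionProfileTable(gonad.specimen_id, gonad.stage, plan, profiles, areas)


def _place_field(
    rng: np.random.Generator, r_um: float, half_w: float, half_h: float
) -> tuple[float, float]:
    """Uniform centre of a rectangle constrained to lie fully inside a
    circle of radius r (rejection sampling on the far corner)."""
    max_x = r_um - half_w
    max_y = r_um - half_h
    while True:
        cx = rng.uniform(-max_x, max_x)
        cy = rng.uniform(-max_y, max_y)
        if (abs(cx) + half_w) ** 2 + (abs(cy) + half_h) ** 2 <= r_um * r_um:
            return cx, cy


def sample_fields(
    table: SectionProfileTable,
    plan: SectionPlan | None = None,
    seed: int | np.random.Generator | None = None,
) -> SectionProfileTable:
    """Restrict a profile table to randomly placed rectangular fields.

    ``plan.field_count`` fields are placed on sections chosen uniformly
    at random among those whose cross-section can host a field; each
    field is a uniformly positioned rectangle fully inside the circular
    gonad cross-section, and only profiles whose centres fall inside a
    field are retained (tagged with the field id).  A field large enough
    to cover the entire cross-section degenerates to whole-section
    counting with the cross-section itself as effective area.
    """
    plan = plan or table.plan
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half_w = plan.field_width_um / 2.0
    half_h = plan.field_height_um / 2.0
    half_diag = math.hypot(half_w, half_h)

    areas = table.areas
    radii = np.sqrt(areas["G_a_mm2"].to_numpy() * UM2_PER_MM2 / math.pi)
    fits = radii >= half_diag
    covers = (half_w >= radii) & (half_h >= radii) & (radii > 0)
    eligible = np.flatnonzero(fits | covers)
    if eligible.size == 0:
        raise ValueError(
            "no section cross-section can host a "
            f"{plan.field_width_um}x{plan.field_height_um} μm field"
        )

    replace = eligible.size < plan.field_count
    chosen = rng.choice(eligible, size=plan.field_count, replace=replace)

    prof = table.profiles
    sec_arr = prof["section_index"].to_numpy() if len(prof) else np.empty(0, dtype=int)
    px_arr = prof["profile_x_um"].to_numpy() if len(prof) else np.empty(0)
    py_arr = prof["profile_y_um"].to_numpy() if len(prof) else np.empty(0)
    retained = []
    field_rows = []
    for field_id, sec in enumerate(np.sort(chosen)):
        sec = int(sec)
        r = float(radii[sec])
        in_sec = sec_arr == sec
        if covers[sec] and not fits[sec]:
            take = np.flatnonzero(in_sec)
            eff_area = math.pi * r * r
            cx = cy = 0.0
        else:
            cx, cy = _place_field(rng, r, half_w, half_h)
            take = np.flatnonzero(
                in_sec
                & (px_arr >= cx - half_w)
                & (px_arr < cx + half_w)
                & (py_arr >= cy - half_h)
                & (py_arr < cy + half_h)
            )
            eff_area = plan.field_area_um2
        sub = prof.iloc[take].copy()
        sub["field_id"] = pd.array([field_id] * len(sub), dtype="Int64")
        retained.append(sub)
        field_rows.append(
            {
                "field_id": field_id,
                "section_index": sec,
                "center_x_um": cx,
                "center_y_um": cy,
                "width_um": plan.field_width_um,
                "height_um": plan.field_height_um,
                "effective_area_um2": eff_area,
            }
        )

    profiles = (
        pd.concat(retained, ignore_index=True)
        if retained
        else prof.iloc[0:0].copy()
    )
    fields = pd.DataFrame(field_rows)
    return SectionProfileTable(
        specimen_id=table.specimen_id,
        stage=table.stage,
        plan=plan,
        profiles=profiles,
        areas=table.areas,
        fields=fields,
        total_field_area_um2=float(fields["effective_area_um2"].sum()),
    )
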