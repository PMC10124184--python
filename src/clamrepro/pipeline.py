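"""End-to-end pipeline: simulate → section → estimate → cohort stats.

A single :class:`RunConfig` (YAML/JSON serializable, unknown keys
rejected) drives a reproducible run: per-stage seeds are derived
deterministically from the master seed, gonads are processed one at a
time (the generator can produce ~10⁶ oocytes per gonad, so cohorts are
streamed, never held in memory), and every output is written through
the documented CSV/JSON interfaces together with a manifest of
configuration, seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

import clamrepro
from clamrepro import cohort_stats, phenology, stereology
from clamrepro.sectioning import SectionPlan, sample_fields, section_gonad
from clamrepro.synthetic_gonad import GeneratorConfig, generate_gonad, _cohort_plan


class RunConfig(BaseModel):
    """Configuration of one end-to-end run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    generator: GeneratorConfig = GeneratorConfig()
    plan: SectionPlan = SectionPlan()
    n_4A: int = 20
    n_4B: int = 6
    tl_range_mm: tuple[float, float] = (19.0, 33.0)
    volume_mode: str = "corrected"
    delesse: bool = False
    mcrs_new_mm: float = 22.0
    mcrs_old_mm: float = 25.0
    seed: int = 0
    env_csv: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.n_4A + self.n_4B < 1:
            raise ValueError("cohort needs at least one specimen")
        lo, hi = self.tl_range_mm
        if not lo <= hi:
            raise ValueError(f"empty TL range {self.tl_range_mm}")
        if self.volume_mode not in ("corrected", "paper"):
            raise ValueError("volume_mode must be 'corrected' or 'paper'")
        # unit sanity: spacing in μm, not mm
        if self.plan.spacing_um < 1:
            raise ValueError(
                "section spacing below 1 μm — check that spacing is given in μm"
            )
        return self


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage_name}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def validate_config(raw_text: str) -> RunConfig:
    """Parse and schema-check a YAML/JSON run configuration.

    Unknown keys are rejected (no silent typos); defaults are filled in
    explicitly so the resulting object round-trips losslessly.
    """
    data = yaml.safe_load(raw_text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a mapping")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute a full run and write the report bundle to ``outdir``.

    Produces per-specimen fecundity estimates, the G_v~TL and PF~TL
    fits, the MCRS scenario, occupancy ANOVA tables, optional phenology
    summaries, and a manifest (config, per-stage seeds, output hashes)
    whose content depends only on configuration, seed and package
    version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: stage_seed(config.seed, name)
        for name in ("simulate", "fields", "stats")
    }

    tls, stages, child_seeds = _cohort_plan(
        config.n_4A, config.n_4B, config.tl_range_mm, seeds["simulate"]
    )
    field_rng = np.random.default_rng(seeds["fields"])
    estimates = []
    for i, (tl, stage, child) in enumerate(zip(tls, stages, child_seeds)):
        specimen_id = f"sim-{i:03d}"
        try:
            gonad = generate_gonad(
                tl,
                stage,
                config.generator,
                seed=np.random.default_rng(child),
                specimen_id=specimen_id,
            )
            table = section_gonad(gonad, config.plan)
            sampled = sample_fields(table, config.plan, seed=field_rng)
            est = stereology.estimate_fecundity(
                sampled,
                config=config.generator,
                mode=config.volume_mode,
                delesse=config.delesse,
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for specimen {specimen_id}: {exc}"
            ) from exc
        row = est.to_row()
        row["TL_mm"] = float(tl)
        row["true_volume_mm3"] = gonad.true_volume_mm3
        row["true_count_mature"] = gonad.true_counts["mature"]
        row["true_count_immature"] = gonad.true_counts["immature"]
        estimates.append(row)

    est_df = pd.DataFrame(estimates)
    est_path = outdir / "estimates.csv"
    est_df.to_csv(est_path, index=False)

    results: dict = {"estimates": est_df}

    gv_fit = cohort_stats.fit_linear(est_df["TL_mm"], est_df["G_v_hat_mm3"])
    results["gv_fit"] = gv_fit
    fits_out = {"gv_fit": _fit_to_dict(gv_fit)}

    ripe = est_df[est_df["stage"] == "F4A"]
    if len(ripe) >= 3 and ripe["TL_mm"].nunique() > 1:
        pf_fit = cohort_stats.fit_linear(ripe["TL_mm"], ripe["PF"])
        results["pf_fit"] = pf_fit
        fits_out["pf_fit"] = _fit_to_dict(pf_fit)
        scenario = cohort_stats.mcrs_scenario(
            pf_fit, config.mcrs_new_mm, config.mcrs_old_mm
        )
        results["mcrs"] = scenario
        (outdir / "mcrs.json").write_text(
            json.dumps(scenario.to_dict(), indent=2, sort_keys=True)
        )
    (outdir / "fits.json").write_text(json.dumps(fits_out, indent=2, sort_keys=True))

    occ_rows = est_df.melt(
        id_vars=["specimen_id", "stage"],
        value_vars=["occupancy_pct_mature", "occupancy_pct_immature"],
        var_name="dev_class",
        value_name="percent",
    )
    occ_rows["dev_class"] = occ_rows["dev_class"].str.replace("occupancy_pct_", "")
    try:
        anova = cohort_stats.occupancy_anova(occ_rows)
        anova["anova"].to_csv(outdir / "occupancy_anova.csv")
        anova["tukey"]["cells"].to_csv(outdir / "tukey_cells.csv", index=False)
        anova["tukey"]["stage"].to_csv(outdir / "tukey_stage.csv", index=False)
        results["anova"] = anova
    except ValueError as exc:
        warnings.warn(f"occupancy ANOVA skipped: {exc}", UserWarning, stacklevel=2)

    count_rows = est_df.melt(
        id_vars=["specimen_id", "stage", "TL_mm"],
        value_vars=["N_hat_mature", "N_hat_immature"],
        var_name="dev_class",
        value_name="count",
    )
    count_rows["dev_class"] = count_rows["dev_class"].str.replace("N_hat_", "")
    # zero counts (a class unseen in the sampled fields) cannot enter the
    # log-scale model
    count_rows = count_rows[count_rows["count"] > 0]
    try:
        ancova = cohort_stats.count_ancova(count_rows)
        ancova["ancova"].to_csv(outdir / "count_ancova.csv")
        results["ancova"] = ancova
    except (ValueError, KeyError) as exc:
        warnings.warn(f"count ANCOVA skipped: {exc}", UserWarning, stacklevel=2)

    if config.env_csv is not None:
        env = pd.read_csv(config.env_csv)
        summary = phenology.monthly_summary(env)
        summary.to_csv(outdir / "env_monthly.csv", index=False)
        results["env_monthly"] = summary

    outputs = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "clamrepro",
        "version": clamrepro.__version__,
        "config": json.loads(config.model_dump_json()),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _fit_to_dict(fit: cohort_stats.LinearFit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "adj_r2": fit.adj_r2,
        "f_stat": fit.f_stat,
        "df": list(fit.df),
        "p_value": fit.p_value,
        "resid_se": fit.resid_se,
        "n": fit.n,
    }
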