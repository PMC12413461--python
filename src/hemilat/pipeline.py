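"""End-to-end pipeline: laterality -> grouping -> models -> report.

The pipeline consumes either on-disk tables (biomarkers, covariates,
connectivity matrices) or, when no paths are configured, a synthetic
cohort generated from the configured seed.  Every stage's outputs are
written as delimited text next to a manifest recording the seed,
configuration and per-stage row counts; exclusions (borderline
subjects, skipped models) are logged with reasons.  Structural problems
fail fast; per-record problems are skipped and reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import laterality as lat
from . import models as mdl
from . import simulate as sim
from .core_data import load_atlas, read_biomarker_table, read_covariate_table

logger = logging.getLogger("hemilat")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Declarative settings for a full analysis run."""

    out_dir: str = "hemilat_out"
    seed: int = 0
    atlas: str = "dk84"
    biomarker_path: str | None = None
    covariate_path: str | None = None
    tau_cutoff: float = lat.TAU_CUTOFF
    abeta_cutoff: float = lat.ABETA_CUTOFF
    mask_fraction: float = 0.10
    nbs_thresholds: tuple[float, ...] = (2.5, 3.0, 3.5)
    nbs_permutations: int = 5000
    with_connectivity: bool = False
    with_longitudinal: bool = True
    generator: sim.GeneratorConfig = field(default_factory=sim.GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = sim.GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; return the in-memory result bundle.

    Stages: data (load or simulate) -> laterality -> classification ->
    cross-sectional model -> longitudinal models -> optional
    connectivity -> manifest.  All tables are also written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, rois = load_atlas(config.atlas)
    roi_by_name = {r.name: r for r in rois}
    manifest: dict = {"seed": config.seed, "stages": [], "exclusions": []}
    bundle: dict = {"config": config}
    gen = config.generator.with_seed(config.seed)

    # --- stage 1: inputs -------------------------------------------------
    if config.biomarker_path:
        biomarkers = read_biomarker_table(config.biomarker_path, atlas)
        if not config.covariate_path:
            raise FileNotFoundError("covariate_path required with biomarker_path")
        covariates = read_covariate_table(config.covariate_path)
    else:
        cohort = sim.simulate_cross_sectional(gen)
        biomarkers, covariates = cohort.biomarkers, cohort.covariates
    bundle["biomarkers"], bundle["covariates"] = biomarkers, covariates
    manifest["stages"].append({"name": "inputs", "rows": len(biomarkers)})

    # --- stage 2: laterality --------------------------------------------
    li_table = lat.laterality_table(biomarkers, rois)
    li_table.to_csv(out / "laterality.csv", index=False)
    bundle["laterality"] = li_table
    manifest["stages"].append({"name": "laterality", "rows": len(li_table)})

    # --- stage 3: status and grouping -----------------------------------
    status = lat.classify_status(
        biomarkers, roi_by_name["temporal"], roi_by_name.get("neocortical"),
        tau_cutoff=config.tau_cutoff, abeta_cutoff=config.abeta_cutoff)
    keys = ["subject_id", "timepoint_years"]
    temporal = li_table.query("tracer == 'tau' and target == 'temporal'")
    merged = temporal.merge(status, on=keys, how="left")
    eligible = merged[merged["tau_positive"].fillna(False).astype(bool)]
    thresholds = lat.derive_asymmetry_thresholds(eligible["li"])
    merged = merged.assign(
        asymmetry_group=lat.assign_asymmetry_group(
            merged["li"].to_numpy(), thresholds))
    n_border = int((merged["asymmetry_group"] == "borderline").sum())
    if n_border:
        manifest["exclusions"].append(
            {"stage": "grouping", "reason": "borderline LI", "n": n_border})
        logger.info("excluded %d borderline subjects from group contrasts",
                    n_border)
    merged.to_csv(out / "groups.csv", index=False)
    bundle["groups"] = merged
    bundle["thresholds"] = thresholds
    manifest["stages"].append({
        "name": "grouping", "rows": len(merged),
        "thresholds": [thresholds.threshold_low, thresholds.threshold_high],
    })

    # --- stage 4: cross-sectional laterality coupling -------------------
    def li_of(target, tracer):
        sub = li_table.query("tracer == @tracer and target == @target")
        return sub.set_index("subject_id")["li"]

    cross = pd.DataFrame({
        "tau_li": li_of("global", "tau"),
        "abeta_li": li_of("global", "abeta"),
    }).reset_index().merge(covariates, on="subject_id")
    spec = mdl.ModelSpec(outcome="tau_li",
                         predictors=("age_years", "sex", "abeta_li"),
                         focal_predictor="abeta_li")
    res = mdl.fit_cross_sectional(cross, spec)
    bundle["cross_sectional"] = res
    pd.DataFrame([res.to_dict()]).to_csv(out / "cross_sectional.csv", index=False)
    bundle["cross_data"] = cross
    manifest["stages"].append({"name": "cross_sectional", "rows": res.n_obs,
                               "beta_std": res.beta_std})

    # --- stage 5: longitudinal laterality + cognition -------------------
    if config.with_longitudinal:
        long_df = sim.simulate_cognition(gen)
        long_res = mdl.fit_longitudinal_laterality(long_df)
        cog = mdl.fit_cognition_models(long_df, variant="li_only")
        bundle["longitudinal"] = long_res
        bundle["longitudinal_data"] = long_df
        bundle["cognition"] = cog
        rows = [dict(stage="laterality", roi="global", **long_res.to_dict())]
        rows += [dict(stage="cognition", roi=roi, **r.to_dict())
                 for roi, r in cog.items()]
        pd.DataFrame(rows).to_csv(out / "longitudinal.csv", index=False)
        manifest["stages"].append({"name": "longitudinal",
                                   "rows": len(long_df),
                                   "beta_std": long_res.beta_std})

    # --- stage 6: connectivity ------------------------------------------
    if config.with_connectivity:
        controls, patients, info = sim.simulate_connectivity(gen, atlas)
        mask = conn.build_control_mask(controls, atlas, config.mask_fraction)
        info = info.copy()
        info["avg_interhemi"] = [
            conn.average_interhemispheric(m, mask) for m in patients]
        contrasts = conn.group_outcome_models(info, outcome="avg_interhemi")
        nbs_results = {}
        two = info["asymmetry_group"].isin(["LA", "S"])
        for thr in config.nbs_thresholds:
            nbs_results[thr] = conn.nbs(
                [m for m, keep in zip(patients, two) if keep],
                info.loc[two, "asymmetry_group"],
                info.loc[two], atlas, edge_threshold=thr,
                n_permutations=config.nbs_permutations, seed=config.seed,
                mask=mask)
        bundle["mask"] = mask
        bundle["group_contrasts"] = contrasts
        bundle["nbs"] = nbs_results
        bundle["connectivity_info"] = info
        rows = [dict(contrast=f"{a}-{b}", **r.to_dict())
                for (a, b), r in contrasts.items() if r is not None]
        pd.DataFrame(rows).to_csv(out / "group_contrasts.csv", index=False)
        comp_rows = [
            {"threshold": thr, "direction": c.direction, "size": c.size,
             "p_fwe": c.p_fwe}
            for thr, r in nbs_results.items() for c in r.components]
        pd.DataFrame(comp_rows, columns=["threshold", "direction", "size", "p_fwe"]) \
            .to_csv(out / "nbs_components.csv", index=False)
        manifest["stages"].append({"name": "connectivity",
                                   "rows": len(patients),
                                   "mask_edges": len(mask)})

    manifest["stages"].append({"name": "manifest", "rows": 0})
    manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable))
    bundle["manifest"] = manifest
    return bundle


def render_report(bundle: dict, out_dir: str | Path | None = None) -> list[Path]:
    """Render figures for a result bundle; every figure gets a data file.

    Sections whose stage is absent from the bundle are skipped with a
    notice.  Returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir or bundle["config"].out_dir) / "report"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(fig, name: str, data: pd.DataFrame):
        fig_path = out / f"{name}.png"
        data_path = out / f"{name}.csv"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        data.to_csv(data_path, index=False)
        written.extend([fig_path, data_path])

    if "groups" in bundle:
        g = bundle["groups"]
        keep = g[g["asymmetry_group"] != "borderline"]
        fig, ax = plt.subplots(figsize=(5, 4))
        order = ["LA", "S", "RA"]
        data = [keep.loc[keep["asymmetry_group"] == grp, "li"] for grp in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("temporal tau LI (%)")
        ax.set_xlabel("asymmetry group")
        save(fig, "group_boxplot", keep[["subject_id", "li", "asymmetry_group"]])
    else:
        logger.info("report: grouping stage absent, boxplot skipped")

    if "cross_data" in bundle:
        d = bundle["cross_data"].dropna(subset=["tau_li", "abeta_li"])
        res = bundle["cross_sectional"]
        slope, intercept = np.polyfit(d["abeta_li"], d["tau_li"], 1)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(d["abeta_li"], d["tau_li"], s=8, alpha=0.6)
        xs = np.linspace(d["abeta_li"].min(), d["abeta_li"].max(), 50)
        ax.plot(xs, intercept + slope * xs, color="C3")
        ax.set_xlabel("global Aβ LI (%)")
        ax.set_ylabel("global tau LI (%)")
        ax.set_title(f"standardized β = {res.beta_std:.3f}")
        save(fig, "li_scatter", d[["subject_id", "abeta_li", "tau_li"]])

    if "longitudinal_data" in bundle:
        d = bundle["longitudinal_data"]
        fig, ax = plt.subplots(figsize=(5, 4))
        for _, sub in list(d.groupby("subject_id"))[:60]:
            ax.plot(sub["time_years"], sub["tau_li"], color="grey",
                    alpha=0.4, lw=0.8)
        ax.set_xlabel("years from baseline")
        ax.set_ylabel("global tau LI (%)")
        save(fig, "longitudinal_spaghetti",
             d[["subject_id", "time_years", "tau_li"]])
    else:
        logger.info("report: longitudinal stage absent, section skipped")

    if "group_contrasts" in bundle:
        rows = [dict(contrast=f"{a}-{b}", **r.to_dict())
                for (a, b), r in bundle["group_contrasts"].items()
                if r is not None]
        df = pd.DataFrame(rows)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(df["contrast"], df["beta_std"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("standardized contrast β")
        save(fig, "connectivity_contrasts", df)
    else:
        logger.info("report: connectivity stage absent, section skipped")
    return written
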