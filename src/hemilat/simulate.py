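"""Synthetic cohort generator with planted laterality effect structure.

Every analysis stage in this package can be exercised without access to
restricted cohort data: the generator emits bilateral SUVR tables,
covariates, longitudinal laterality trajectories, cognition scores and
connectivity matrices whose statistical structure matches what the
fitting code assumes, with *known* planted effects so that parameter
recovery is testable.

Key constructions
-----------------
* Group-conditional temporal tau LI values are drawn from truncated
  normal distributions confined to the LA / S / RA classification bands,
  with the location parameter solved numerically so the *truncated* mean
  hits the target group mean.  Group means are therefore exact targets,
  not approximations.
* Regional left/right SUVRs are back-constructed from a planted LI and a
  fixed bilateral mean: ``left = m (1 - LI/100)``,
  ``right = m (1 + LI/100)``, so ``compute_li(left, right)`` returns the
  planted value to machine precision, and hemisphere-mean aggregation of
  equal-mean regions reproduces planted meta-ROI LIs exactly.
* Planted standardized coefficients are achieved analytically from the
  variance decomposition (outcome = beta * z + sqrt(1 - beta^2) * noise
  in standardized coordinates), never by tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import atlas_data
from .core_data import ConnectivityMatrix, RegionAtlas, load_atlas

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "solve_truncated_location",
    "simulate_cross_sectional",
    "simulate_replication_cohort",
    "simulate_longitudinal",
    "simulate_cognition",
    "simulate_connectivity",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All planted effects, noise scales, sample sizes and schedules.

    Defaults reflect the study conditions the analyses are designed for:
    cohort sizes 233 (cross-sectional), 234 (combined replication) and
    289 (longitudinal, 2-5 visits, mean follow-up 2.9 years); asymmetry
    group mix 22 / 68 / 10 percent (LA / S / RA) with group-mean temporal
    tau LIs of -14.4, -0.4 and +14.7 at SDs 3.7, 4.9 and 5.4; planted
    standardized amyloid-to-tau laterality couplings of 0.632
    (cross-sectional), 0.535 (replication) and 0.025 SD/yr/SD
    (longitudinal interaction) on top of a 0.043 SD/yr mean drift; and a
    planted cognition slope effect of -0.157 SD/yr/SD on the late-Braak
    composite.
    """

    seed: int = 0
    # sample sizes
    n_cross: int = 233
    n_combined_replication: int = 234
    n_long: int = 289
    # asymmetry-group mixture (remaining mass, if any, is borderline)
    group_probs: tuple[float, float, float] = (0.22, 0.68, 0.10)
    group_li_params: dict = field(default_factory=lambda: {
        "LA": (-14.4, 3.7), "S": (-0.4, 4.9), "RA": (14.7, 5.4),
    })
    thresholds: tuple[float, float] = (8.78, 9.70)  # (symmetric, asymmetric)
    # planted standardized effects
    cross_effect_std: float = 0.632
    replication_effect_std: float = 0.535
    long_interaction_std: float = 0.025   # SD/yr per SD of baseline Abeta LI
    time_only_slope: float = 0.043        # SD/yr mean drift of tau LI
    cognition_slope_effects: dict = field(default_factory=lambda: {
        "braak_5_6": -0.157,
    })
    # marginal scales (% LI units unless noted)
    abeta_li_sd: float = 4.0
    global_tau_li_sd: float = 7.0
    region_li_noise: float = 2.0
    tau_region_mean: float = 1.8          # SUVR, above the T+ cutoff 1.362
    abeta_region_mean: float = 1.6        # SUVR, above the A+ cutoff 1.033
    age_mean: float = 73.0
    age_sd: float = 7.0
    p_female: float = 0.55
    p_impaired: float = 0.87              # main cohort; replication uses 0.5
    # longitudinal structure
    visit_range: tuple[int, int] = (2, 5)
    followup_mean: float = 2.9
    followup_sd: float = 0.8
    long_baseline_sd: float = 7.0
    long_resid_sd: float = 2.0
    long_slope_sd: float = 1.0            # %/yr random slope SD
    p_baseline_tpos: float = 0.38         # A+T+ share of the longitudinal sample
    p_convert: float = 0.21               # T- to T+ conversion during follow-up
    # cognition structure
    mpacc_baseline_mean: float = -2.6
    mpacc_baseline_sd: float = 1.5
    mpacc_base_slope_std: float = -0.15   # SD/yr mean decline
    mpacc_slope_noise_std: float = 0.10   # SD/yr random slope SD
    roi_li_sd: dict = field(default_factory=lambda: {
        "braak_1_2": 9.0, "braak_3_4": 8.0, "braak_5_6": 7.0,
    })
    cognition_load_pathway: float = 0.0   # optional load-mediated slope share
    # connectivity structure
    n_controls: int = 294
    connectivity_group_sizes: dict = field(default_factory=lambda: {
        "LA": 102, "S": 306, "RA": 44,
    })
    w_homotopic: float = 0.55
    w_interhemi: float = 0.12
    w_intrahemi: float = 0.25
    w_subject_sd: float = 0.03
    w_edge_sd: float = 0.12
    planted_component: tuple | None = None  # (edges, effect, target_group)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedCohort:
    """Bundle of generated tables plus the planted ground truth."""

    biomarkers: pd.DataFrame
    covariates: pd.DataFrame
    truth: pd.DataFrame


def solve_truncated_location(target_mean: float, scale: float,
                             lower: float, upper: float) -> float:
    """Location of a truncated normal whose truncated mean is ``target_mean``.

    The distribution is Normal(loc, scale) truncated to (lower, upper);
    the truncated mean is strictly increasing in loc, so the root is
    unique.  Raises if the target lies outside the open truncation band
    (the truncated mean can never reach it).
    """
    if not (lower < target_mean < upper):
        raise ValueError(
            f"target mean {target_mean} outside truncation band ({lower}, {upper})"
        )

    def trunc_mean(loc):
        a, b = (lower - loc) / scale, (upper - loc) / scale
        return stats.truncnorm.mean(a, b, loc=loc, scale=scale) - target_mean

    span = 20 * scale + (upper - lower)
    return float(optimize.brentq(trunc_mean, lower - span, upper + span,
                                 xtol=1e-10))


def _group_band(group: str, thresholds: tuple[float, float]) -> tuple[float, float]:
    low, high = thresholds
    return {"LA": (-100.0, -high), "S": (-low, low), "RA": (high, 100.0)}[group]


def _draw_group_mixture(rng: np.random.Generator, n: int,
                        config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Group labels and temporal tau LI values from the truncated mixture."""
    probs = np.asarray(config.group_probs, dtype=float)
    if probs.sum() > 1 + 1e-9 or np.any(probs < 0):
        raise ValueError("group probabilities must be non-negative and sum to <= 1")
    names = np.array(["LA", "S", "RA", "borderline"])
    full = np.append(probs, max(0.0, 1.0 - probs.sum()))
    labels = names[rng.choice(4, size=n, p=full / full.sum())]
    li = np.empty(n)
    for group in ("LA", "S", "RA"):
        idx = labels == group
        if not idx.any():
            continue
        mean, sd = config.group_li_params[group]
        lower, upper = _group_band(group, config.thresholds)
        loc = solve_truncated_location(mean, sd, lower, upper)
        a, b = (lower - loc) / sd, (upper - loc) / sd
        li[idx] = stats.truncnorm.rvs(a, b, loc=loc, scale=sd,
                                      size=int(idx.sum()), random_state=rng)
    idx = labels == "borderline"
    if idx.any():
        # borderline band: uniform mix over the two narrow shells
        low, high = config.thresholds
        u = rng.uniform(low, high, size=int(idx.sum()))
        sign = rng.choice([-1.0, 1.0], size=int(idx.sum()))
        li[idx] = sign * u
    return labels, li


def _region_names() -> list[str]:
    return [name for name, _ in atlas_data.ALL_REGIONS]


def _build_biomarker_rows(subject_ids: np.ndarray, region_li: dict[str, np.ndarray],
                          tracer: str, region_mean: float) -> pd.DataFrame:
    """Back-construct left/right SUVRs from planted per-region LIs."""
    frames = []
    for region, li in region_li.items():
        li = np.clip(li, -95.0, 95.0)
        left = region_mean * (1 - li / 100.0)
        right = region_mean * (1 + li / 100.0)
        for hemisphere, suvr in (("left", left), ("right", right)):
            frames.append(pd.DataFrame({
                "subject_id": subject_ids,
                "timepoint_years": 0.0,
                "tracer": tracer,
                "region_name": region,
                "hemisphere": hemisphere,
                "suvr": suvr,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_cross_sectional(config: GeneratorConfig | None = None,
                             n: int | None = None,
                             effect: float | None = None,
                             p_impaired: float | None = None,
                             seed: int | None = None,
                             include_biomarkers: bool = True) -> SimulatedCohort:
    """A+T+ cross-sectional cohort with coupled amyloid/tau laterality.

    The planted structure, per subject:

    * global amyloid LI ~ Normal(0, ``abeta_li_sd``);
    * global tau LI (standardized) = ``effect`` x standardized amyloid LI
      + sqrt(1 - effect^2) x independent noise, so the standardized
      partial coefficient of amyloid LI in the covariate-adjusted OLS
      equals ``effect`` exactly in expectation;
    * temporal tau LI from the truncated-normal group mixture;
    * per-region LIs chosen so that hemisphere-mean aggregation of the
      temporal and global composites reproduces the planted temporal and
      global LIs to machine precision (temporal member regions share the
      temporal LI; the remaining regions absorb the difference plus
      zero-sum regional noise).

    Age and sex are independent of both laterality indices.  With
    ``include_biomarkers=False`` only covariates and planted truth are
    returned (identical draws, empty biomarker table), which is cheap
    for calibration studies that fit on the planted columns directly.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = n or config.n_cross
    effect = config.cross_effect_std if effect is None else effect
    p_imp = config.p_impaired if p_impaired is None else p_impaired
    if not (0 <= abs(effect) <= 1):
        raise ValueError("standardized effect must lie in [-1, 1]")

    sid = np.array([f"sub-{i:05d}" for i in range(n)])
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    status = np.where(rng.random(n) < p_imp, "impaired", "unimpaired")

    z_abeta = rng.normal(size=n)
    abeta_li = z_abeta * config.abeta_li_sd
    eps = rng.normal(size=n)
    global_tau_li = (effect * z_abeta + np.sqrt(1 - effect ** 2) * eps) \
        * config.global_tau_li_sd
    group, temporal_tau_li = _draw_group_mixture(rng, n, config)

    if include_biomarkers:
        regions = _region_names()
        temporal = sorted(atlas_data.BRAAK_1_2 | atlas_data.BRAAK_3_4)
        others = [r for r in regions if r not in set(temporal)]
        n_all, n_temp = len(regions), len(temporal)
        # non-temporal regions absorb the planted global mean exactly
        fill = (n_all * global_tau_li - n_temp * temporal_tau_li) / (n_all - n_temp)
        noise = rng.normal(0, config.region_li_noise, size=(n, len(others)))
        noise -= noise.mean(axis=1, keepdims=True)
        tau_region_li = {r: temporal_tau_li for r in temporal}
        for k, r in enumerate(others):
            tau_region_li[r] = fill + noise[:, k]
        abeta_region_li = {r: abeta_li for r in regions}
        biomarkers = pd.concat([
            _build_biomarker_rows(sid, tau_region_li, "tau", config.tau_region_mean),
            _build_biomarker_rows(sid, abeta_region_li, "abeta", config.abeta_region_mean),
        ], ignore_index=True)
    else:
        biomarkers = pd.DataFrame(columns=[
            "subject_id", "timepoint_years", "tracer", "region_name",
            "hemisphere", "suvr"])
    covariates = pd.DataFrame({
        "subject_id": sid, "timepoint_years": 0.0, "age_years": age,
        "sex": sex, "cognitive_status": status,
    })
    truth = pd.DataFrame({
        "subject_id": sid, "group": group, "abeta_li": abeta_li,
        "z_abeta": z_abeta, "global_tau_li": global_tau_li,
        "temporal_tau_li": temporal_tau_li,
    })
    return SimulatedCohort(biomarkers, covariates, truth)


def simulate_regionwise(couplings: dict[str, float], n: int = 233,
                        config: GeneratorConfig | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Long per-region laterality table with a planted coupling gradient.

    For every region name in ``couplings`` the regional tau LI is
    generated with the given standardized coupling to that region's
    amyloid LI (regions not listed get coupling 0), which is what the
    region-wise association models estimate.  The regional amyloid LIs
    share a common subject-level factor so cross-region associations are
    non-trivial, as in real hemispheric asymmetry data.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 3_000_017)
    sid = np.array([f"sub-{i:05d}" for i in range(n)])
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    shared = rng.normal(size=n)
    frames = []
    for region, beta in couplings.items():
        if not 0 <= abs(beta) <= 1:
            raise ValueError(f"coupling for {region!r} outside [-1, 1]")
        z_a = 0.7 * shared + np.sqrt(1 - 0.49) * rng.normal(size=n)
        z_t = beta * z_a + np.sqrt(1 - beta ** 2) * rng.normal(size=n)
        frames.append(pd.DataFrame({
            "subject_id": sid, "region": region,
            "abeta_li": z_a * config.abeta_li_sd,
            "tau_li": z_t * config.global_tau_li_sd,
            "age_years": age, "sex": sex,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_replication_cohort(config: GeneratorConfig | None = None,
                                seed: int | None = None) -> SimulatedCohort:
    """Combined replication cohort: n = 234, coupling 0.535, mixed status.

    Cognitive status (50% impaired) is independent of both laterality
    indices, matching the replication model that carries it as a
    nuisance covariate.
    """
    config = config or GeneratorConfig()
    return simulate_cross_sectional(
        config, n=config.n_combined_replication,
        effect=config.replication_effect_std, p_impaired=0.5, seed=seed,
    )


def _visit_times(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.visit_range
    nv = int(rng.integers(lo, hi + 1))
    span = max(0.5, rng.normal(config.followup_mean, config.followup_sd))
    t = np.concatenate([[0.0], np.sort(rng.uniform(0, 1, nv - 1)) * span])
    t[-1] = span
    return t


def simulate_longitudinal(config: GeneratorConfig | None = None,
                          n: int | None = None,
                          interaction: float | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Longitudinal global tau LI trajectories with an amyloid interaction.

    Per subject i at visit time t (years from baseline)::

        tau_li(t) = alpha_i + (g0 + g1 * z_i + u_i) * t + e(t)

    with z_i the standardized baseline amyloid LI, g0 the mean drift
    (``time_only_slope`` in baseline-SD units), g1 the planted
    interaction (``long_interaction_std``), u_i a Normal random slope
    and alpha_i a Normal random intercept scaled so the baseline SD
    equals ``long_baseline_sd``.  The table carries one row per visit
    with baseline covariates, A+T- / A+T+ strata and conversion flags.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = n or config.n_long
    g1 = config.long_interaction_std if interaction is None else interaction

    s0, se = config.long_baseline_sd, config.long_resid_sd
    if se >= s0:
        raise ValueError("residual SD must be below the baseline SD")
    sa = np.sqrt(s0 ** 2 - se ** 2)
    g0_raw = config.time_only_slope * s0
    g1_raw = g1 * s0

    rows = []
    for i in range(n):
        z = rng.normal()
        abeta_li = z * config.abeta_li_sd
        age = rng.normal(config.age_mean, config.age_sd)
        sex = "female" if rng.random() < config.p_female else "male"
        tpos = rng.random() < config.p_baseline_tpos
        converts = (not tpos) and (rng.random() < config.p_convert)
        alpha = rng.normal(0, sa)
        u = rng.normal(0, config.long_slope_sd)
        t = _visit_times(rng, config)
        y = alpha + (g0_raw + g1_raw * z + u) * t + rng.normal(0, se, t.size)
        for k in range(t.size):
            rows.append((f"sub-{i:05d}", t[k], y[k], abeta_li, age, sex,
                         "A+T+" if tpos else "A+T-", converts))
    df = pd.DataFrame(rows, columns=[
        "subject_id", "time_years", "tau_li", "abeta_li", "age_years",
        "sex", "stratum", "converts_to_tpos",
    ])
    df["single_timepoint"] = df.groupby("subject_id")["time_years"] \
        .transform("nunique") < 2
    return df


def simulate_cognition(config: GeneratorConfig | None = None,
                       longitudinal: pd.DataFrame | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Append mPACC trajectories and per-ROI baseline laterality columns.

    The planted cognition structure: the annual mPACC slope (in units of
    the baseline mPACC SD) is::

        slope_i = c0 + sum_roi c_roi * z(|tau LI_roi|) + noise

    where z(.) standardizes the absolute ROI laterality by its exact
    half-normal moments, so ``c_roi`` is recovered as the standardized
    time x |LI| interaction.  By default only the late-Braak composite
    carries an effect.  A positive ``cognition_load_pathway`` routes
    part of the slope through the ROI tau load (which co-varies with
    |LI|), for attenuation experiments.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003)
    if longitudinal is None:
        longitudinal = simulate_longitudinal(config, seed=seed)
    df = longitudinal.copy()
    subjects = df["subject_id"].drop_duplicates().to_numpy()
    n = len(subjects)

    per_subject = {"subject_id": subjects}
    z_abs = {}
    for roi, sd in config.roi_li_sd.items():
        li = rng.normal(0, sd, n)
        per_subject[f"tau_li_{roi}"] = li
        mean_abs = sd * np.sqrt(2 / np.pi)
        sd_abs = sd * np.sqrt(1 - 2 / np.pi)
        z_abs[roi] = (np.abs(li) - mean_abs) / sd_abs
        load = 1.8 + 0.15 * z_abs[roi] * config.cognition_load_pathway \
            + rng.normal(0, 0.25, n)
        per_subject[f"tau_load_{roi}"] = load
    per_subject["abeta_load"] = rng.normal(1.6, 0.2, n)

    sm = config.mpacc_baseline_sd
    b0 = rng.normal(config.mpacc_baseline_mean, sm * 0.9, n)
    slope = np.full(n, config.mpacc_base_slope_std, dtype=float)
    for roi, c in config.cognition_slope_effects.items():
        direct = c * (1 - config.cognition_load_pathway)
        slope = slope + direct * z_abs[roi]
        if config.cognition_load_pathway:
            zload = (per_subject[f"tau_load_{roi}"] - 1.8) / 0.25
            slope = slope + c * config.cognition_load_pathway * zload
    slope = slope + rng.normal(0, config.mpacc_slope_noise_std, n)
    slope_raw = slope * sm

    extra = pd.DataFrame(per_subject)
    extra["mpacc_intercept"] = b0
    extra["mpacc_slope"] = slope_raw
    df = df.merge(extra, on="subject_id", how="left")
    resid = rng.normal(0, sm * np.sqrt(1 - 0.81), len(df))
    df["mpacc"] = df["mpacc_intercept"] + df["mpacc_slope"] * df["time_years"] + resid
    return df.drop(columns=["mpacc_intercept", "mpacc_slope"])


def _symmetric_noise(rng: np.random.Generator, n_nodes: int, sd: float) -> np.ndarray:
    noise = rng.normal(0, sd, (n_nodes, n_nodes))
    upper = np.triu(noise, 1)
    return upper + upper.T


def simulate_connectivity(config: GeneratorConfig | None = None,
                          atlas: RegionAtlas | None = None,
                          seed: int | None = None,
                          modality: str = "functional",
                          ) -> tuple[list[ConnectivityMatrix],
                                     list[ConnectivityMatrix], pd.DataFrame]:
    """Control and patient connectivity matrices with homotopic dominance.

    Mean weights are highest on homotopic edges, intermediate within a
    hemisphere and lowest on heterotopic inter-hemispheric edges, so a
    top-fraction inter-hemispheric mask is dominated by homotopic edges
    as in empirical connectomes.  Patient groups share the control
    distribution by default (a true null); an optional planted component
    (edge list, effect size, target group) shifts those edges in the
    target group for sensitivity testing.

    Returns (controls, patients, patient_info) where patient_info holds
    group labels and nuisance covariates aligned with the patient list.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_003)
    if atlas is None:
        atlas, _ = load_atlas("dk84")
    n_nodes = atlas.n_nodes
    hemi = atlas.hemisphere_of
    base = np.full((n_nodes, n_nodes), config.w_intrahemi)
    inter = hemi[:, None] != hemi[None, :]
    base[inter] = config.w_interhemi
    for i, j in atlas.homotopic_pairs:
        base[i, j] = base[j, i] = config.w_homotopic
    np.fill_diagonal(base, 0.0)

    planted = np.zeros((n_nodes, n_nodes))
    target_group = None
    if config.planted_component is not None:
        edges, effect, target_group = config.planted_component
        for i, j in edges:
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"planted edge ({i}, {j}) outside the atlas")
            planted[i, j] = planted[j, i] = effect

    def draw(subject_id: str, shift: np.ndarray | None = None) -> ConnectivityMatrix:
        w = base + rng.normal(0, config.w_subject_sd) \
            + _symmetric_noise(rng, n_nodes, config.w_edge_sd)
        if shift is not None:
            w = w + shift
        np.fill_diagonal(w, 0.0)
        return ConnectivityMatrix(subject_id=subject_id, modality=modality,
                                  node_labels=atlas.node_labels, weights=w)

    controls = [draw(f"ctrl-{i:04d}") for i in range(config.n_controls)]
    patients, info = [], []
    k = 0
    for group, size in config.connectivity_group_sizes.items():
        shift = planted if group == target_group else None
        for _ in range(size):
            sid = f"pat-{k:04d}"
            patients.append(draw(sid, shift))
            info.append({
                "subject_id": sid, "asymmetry_group": group,
                "age_years": rng.normal(config.age_mean, config.age_sd),
                "sex": "female" if rng.random() < config.p_female else "male",
                "tau_load": rng.normal(1.8, 0.3),
                "abs_tau_li": float(np.abs(rng.normal(0, 7.0))),
            })
            k += 1
    return controls, patients, pd.DataFrame(info)
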