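"""Cross-sectional and longitudinal models linking amyloid and tau laterality.

All effect sizes are standardized: continuous variables (outcome and
predictors) are z-scored by their baseline sample SDs before fitting,
binary covariates stay as 0/1 indicators, and time stays in years.  A
longitudinal interaction coefficient therefore reads "outcome SDs per
year per SD of the moderator".

Cross-sectional fits are ordinary least squares; longitudinal fits are
linear mixed-effects models with a random intercept and a random slope
for time per participant, estimated by REML.  If the random-slope model
fails to converge the fit is retried with a random intercept only and
the fallback is recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelResult",
    "standardize_columns",
    "fit_cross_sectional",
    "fit_cross_sectional_replication",
    "regionwise_association",
    "fit_longitudinal_laterality",
    "fit_cognition_models",
    "bonferroni_adjust",
    "bh_fdr",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a single model fit."""

    outcome: str
    predictors: tuple[str, ...]
    focal_predictor: str
    interaction_with_time: bool = False
    grouping: str = "subject_id"
    standardize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.focal_predictor not in self.predictors:
            raise ValueError("focal predictor must be among the predictors")


@dataclass
class ModelResult:
    """Standardized coefficient of the focal term with inference metadata."""

    term: str
    beta_std: float
    ci95: tuple[float, float]
    p: float
    p_adj: float = np.nan
    adjustment: str = "none"
    n_obs: int = 0
    n_subjects: int = 0
    spec: dict = field(default_factory=dict)
    random_effects: str | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        d = {
            "term": self.term, "beta_std": self.beta_std,
            "ci_low": self.ci95[0], "ci_high": self.ci95[1],
            "p": self.p, "p_adj": self.p_adj, "adjustment": self.adjustment,
            "n_obs": self.n_obs, "n_subjects": self.n_subjects,
            "converged": self.converged,
        }
        return d


def _is_binary(series: pd.Series) -> bool:
    return series.dropna().nunique() <= 2


def _encode_binary(series: pd.Series) -> pd.Series:
    """Map a two-level column to 0/1 (levels sorted for determinism)."""
    vals = sorted(series.dropna().unique(), key=str)
    if len(vals) == 1:
        return pd.Series(np.zeros(len(series)), index=series.index)
    return series.map({vals[0]: 0.0, vals[1]: 1.0}).astype(float)


def standardize_columns(df: pd.DataFrame, columns: Sequence[str],
                        baseline: pd.Series | None = None) -> pd.DataFrame:
    """Z-score continuous columns; encode binary columns as 0/1.

    Scaling constants (mean, SD) come from the rows flagged by
    ``baseline`` (all rows if None), so longitudinal outcomes are scaled
    by their baseline cross-sectional SD.
    """
    out = df.copy()
    ref = df if baseline is None else df.loc[baseline]
    for col in columns:
        if _is_binary(df[col]):
            out[col] = _encode_binary(df[col])
            continue
        mu = ref[col].mean()
        sd = ref[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (df[col] - mu) / sd
    return out


def _prepare_cross_sectional(data: pd.DataFrame, spec: ModelSpec):
    cols = [spec.outcome, *spec.predictors]
    df = data.dropna(subset=cols).copy()
    if df[spec.focal_predictor].nunique() <= 1:
        raise ValueError(f"degenerate focal predictor {spec.focal_predictor!r}")
    predictors = list(spec.predictors)
    for col in list(predictors):
        if col != spec.focal_predictor and df[col].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {col!r}", stacklevel=3)
            predictors.remove(col)
    if spec.standardize:
        df = standardize_columns(df, [spec.outcome, *predictors])
    else:
        for col in [spec.outcome, *predictors]:
            if _is_binary(df[col]) and df[col].dtype == object:
                df[col] = _encode_binary(df[col])
    return df, predictors


def fit_cross_sectional(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS fit; returns the standardized coefficient of the focal predictor.

    The canonical use is the laterality coupling model
    ``tau LI ~ age + sex + abeta LI`` with the amyloid LI as focal
    predictor.
    """
    df, predictors = _prepare_cross_sectional(data, spec)
    n, k = len(df), len(predictors)
    if n <= k + 3:
        raise ValueError(f"underdetermined model: n={n} with {k} predictors")
    X = sm.add_constant(df[predictors].astype(float))
    fit = sm.OLS(df[spec.outcome].astype(float), X).fit()
    ci = fit.conf_int().loc[spec.focal_predictor]
    return ModelResult(
        term=spec.focal_predictor,
        beta_std=float(fit.params[spec.focal_predictor]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[spec.focal_predictor]),
        n_obs=n,
        n_subjects=df[spec.grouping].nunique() if spec.grouping in df else n,
        spec={"outcome": spec.outcome, "predictors": predictors,
              "focal": spec.focal_predictor},
    )


def fit_cross_sectional_replication(data: pd.DataFrame,
                                    spec: ModelSpec | None = None,
                                    outcome: str = "tau_li",
                                    focal: str = "abeta_li") -> ModelResult:
    """Replication-cohort variant with a cognitive-status covariate.

    Same OLS machinery as :func:`fit_cross_sectional`, with
    ``cognitive_status`` added as a binary covariate to absorb the mix
    of unimpaired and impaired participants.
    """
    if spec is None:
        spec = ModelSpec(
            outcome=outcome,
            predictors=("age_years", "sex", "cognitive_status", focal),
            focal_predictor=focal,
        )
    if "cognitive_status" not in spec.predictors:
        raise ValueError("replication model requires a cognitive_status covariate")
    return fit_cross_sectional(data, spec)


def regionwise_association(data: pd.DataFrame, spec: ModelSpec,
                           region_col: str = "region",
                           min_cases: int = 10) -> pd.DataFrame:
    """Fit the cross-sectional model once per region; BH-FDR across regions.

    ``data`` is long over regions: one row per (subject, region) with the
    model columns.  Regions with fewer than ``min_cases`` complete cases
    are skipped and reported with NaN results.
    """
    rows = []
    for region, sub in data.groupby(region_col, sort=True):
        complete = sub.dropna(subset=[spec.outcome, *spec.predictors])
        if len(complete) < min_cases:
            rows.append({"region": region, "beta_std": np.nan, "p": np.nan,
                         "n_obs": len(complete), "skipped": True})
            continue
        res = fit_cross_sectional(complete, spec)
        rows.append({"region": region, "beta_std": res.beta_std,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "p": res.p, "n_obs": res.n_obs, "skipped": False})
    out = pd.DataFrame(rows)
    fitted = ~out["p"].isna()
    out["q"] = np.nan
    if fitted.any():
        out.loc[fitted, "q"] = bh_fdr(out.loc[fitted, "p"].to_numpy())
    return out


def _fit_mixed(df: pd.DataFrame, formula: str, groups: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=groups, re_formula="~time")
        try:
            fit = model.fit(reml=True, method="lbfgs")
            if fit.converged:
                return fit, "intercept+slope", True
        except (np.linalg.LinAlgError, ValueError):
            fit = None
        # simplified random structure as fallback
        model = smf.mixedlm(formula, df, groups=groups, re_formula="1")
        fit = model.fit(reml=True, method="lbfgs")
        return fit, "intercept", bool(fit.converged)


def fit_longitudinal_laterality(data: pd.DataFrame,
                                spec: ModelSpec | None = None,
                                outcome: str = "tau_li",
                                focal: str = "abeta_li",
                                time_col: str = "time_years",
                                time_only: bool = False) -> ModelResult:
    """Mixed model for LI change: ``outcome ~ time * (age + sex + focal)``.

    Random intercept and slope for time per participant.  The reported
    term is the ``time x focal`` interaction: the change in the annual
    LI slope (in baseline-SD units) per SD of the baseline moderator.
    With ``time_only=True`` the fixed-effects part reduces to
    ``outcome ~ time`` and the reported term is the mean annual drift.
    """
    if spec is None:
        spec = ModelSpec(
            outcome=outcome,
            predictors=(outcome,) if time_only else ("age_years", "sex", focal),
            focal_predictor=outcome if time_only else focal,
            interaction_with_time=not time_only,
        )
    df = data.dropna(subset=[spec.outcome, time_col, *spec.predictors]).copy()
    df = df.rename(columns={time_col: "time"})
    visits = df.groupby(spec.grouping)["time"].nunique()
    if (visits < 2).all():
        raise ValueError("all subjects have a single timepoint")
    if df[spec.grouping].nunique() < 2:
        raise ValueError("need at least two subjects for a mixed model")
    baseline = df["time"] == df.groupby(spec.grouping)["time"].transform("min")
    if spec.standardize:
        df = standardize_columns(df, [spec.outcome, *spec.predictors],
                                 baseline=baseline)
    if spec.interaction_with_time:
        rhs = " + ".join(spec.predictors)
        formula = f"{spec.outcome} ~ time * ({rhs})"
        term = f"time:{spec.focal_predictor}"
    else:
        formula = f"{spec.outcome} ~ time"
        term = "time"
    fit, re_struct, converged = _fit_mixed(df, formula, df[spec.grouping])
    ci = fit.conf_int().loc[term]
    return ModelResult(
        term=term,
        beta_std=float(fit.params[term]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[term]),
        n_obs=len(df),
        n_subjects=df[spec.grouping].nunique(),
        spec={"formula": formula, "focal": spec.focal_predictor},
        random_effects=re_struct,
        converged=converged,
    )


COGNITION_VARIANTS = ("li_only", "li_plus_load", "abeta_li_adjusted")


def fit_cognition_models(data: pd.DataFrame, variant: str = "li_only",
                         rois: Sequence[str] = ("braak_1_2", "braak_3_4", "braak_5_6"),
                         outcome: str = "mpacc",
                         time_col: str = "time_years") -> dict[str, ModelResult]:
    """Cognition-trajectory mixed models per Braak composite.

    Three specifications of ``mpacc ~ time * (age + sex + ...)``:

    - ``li_only``: moderator is absolute baseline tau LI of the ROI;
    - ``li_plus_load``: additionally adjusts for the ROI's baseline tau
      load (bilateral mean SUVR), isolating asymmetry from burden;
    - ``abeta_li_adjusted``: moderator is absolute baseline amyloid LI,
      adjusted for tau LI, tau load and amyloid load.

    Returns one result per ROI with Bonferroni adjustment over the ROI
    family.
    """
    if variant not in COGNITION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    results: dict[str, ModelResult] = {}
    for roi in rois:
        li_col, load_col = f"tau_li_{roi}", f"tau_load_{roi}"
        df = data.copy()
        df[f"abs_tau_li_{roi}"] = df[li_col].abs()
        if variant == "li_only":
            predictors = ("age_years", "sex", f"abs_tau_li_{roi}")
            focal = f"abs_tau_li_{roi}"
        elif variant == "li_plus_load":
            predictors = ("age_years", "sex", load_col, f"abs_tau_li_{roi}")
            focal = f"abs_tau_li_{roi}"
        else:
            df["abs_abeta_li"] = df["abeta_li"].abs()
            predictors = ("age_years", "sex", f"abs_tau_li_{roi}",
                          load_col, "abeta_load", "abs_abeta_li")
            focal = "abs_abeta_li"
        spec = ModelSpec(outcome=outcome, predictors=predictors,
                         focal_predictor=focal, interaction_with_time=True)
        results[roi] = fit_longitudinal_laterality(df, spec, time_col=time_col)
    m = len(rois)
    for res in results.values():
        res.p_adj = float(min(1.0, m * res.p))
        res.adjustment = "bonferroni"
    return results


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Family-wise adjustment: ``p_adj = min(1, m * p)`` elementwise.

    ``m`` defaults to the number of p-values but may be larger when the
    family includes contrasts not present in the vector.
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be at least 1")
    if m < p.size:
        raise ValueError("family size smaller than the number of p-values")
    return np.minimum(1.0, m * p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
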