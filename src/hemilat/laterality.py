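"""Laterality indices, biomarker positivity, and asymmetry grouping.

The laterality index (LI) quantifies hemispheric asymmetry of tracer
uptake::

    LI (%) = 100 * (right SUVR - left SUVR) / (right SUVR + left SUVR)

Negative LI means left-dominant pathology.  Subjects are stratified into
left-asymmetric (LA), symmetric (S) and right-asymmetric (RA) groups by
comparing the temporal tau LI against +/- 1 SD of the cohort LI
distribution; values within a multiplicative +/-5% band around the SD
threshold are labelled borderline and excluded from group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import IntegrityError, MetaROIDefinition

__all__ = [
    "compute_li",
    "aggregate_meta_roi",
    "laterality_table",
    "classify_status",
    "derive_asymmetry_thresholds",
    "assign_asymmetry_group",
    "burden_ranked_composites",
    "AsymmetryThresholds",
    "TAU_CUTOFF",
    "ABETA_CUTOFF",
]

# Positivity cutoffs (SUVR, strict inequality): tau from the temporal
# meta-ROI of the most affected hemisphere, amyloid from the bilateral
# neocortical composite.
TAU_CUTOFF = 1.362
ABETA_CUTOFF = 1.033

GROUPS = ("LA", "S", "RA", "borderline")


def compute_li(left_suvr, right_suvr):
    """Laterality index in percent, bounded in [-100, 100].

    Antisymmetric under hemisphere swap and invariant to common positive
    scaling of both inputs.  Accepts scalars or arrays.
    """
    left = np.asarray(left_suvr, dtype=float)
    right = np.asarray(right_suvr, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("SUVR values must be strictly positive")
    out = 100.0 * (right - left) / (right + left)
    return float(out) if out.ndim == 0 else out


def aggregate_meta_roi(biomarkers: pd.DataFrame, roi: MetaROIDefinition,
                       weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Mean SUVR of a composite per (subject, timepoint, tracer, hemisphere).

    Unweighted by default; ``weights`` maps region name to a positive
    volume weight for a weighted mean.  Raises if a member region is
    missing for any (subject, timepoint, tracer, hemisphere) cell.
    """
    sub = biomarkers[biomarkers["region_name"].isin(roi.member_regions)]
    keys = ["subject_id", "timepoint_years", "tracer", "hemisphere"]
    n_members = len(roi.member_regions)
    counts = sub.groupby(keys, sort=False)["region_name"].nunique()
    short = counts[counts < n_members]
    if len(short):
        cell = short.index[0]
        present = set(sub.set_index(keys).loc[cell, "region_name"])
        missing = sorted(roi.member_regions - present)
        raise IntegrityError(
            f"meta-ROI {roi.name!r}: cell {cell} is missing regions {missing}"
        )
    if weights is None:
        agg = sub.groupby(keys, sort=False)["suvr"].mean()
    else:
        w = sub["region_name"].map(weights).astype(float)
        agg = (sub["suvr"] * w).groupby([sub[k] for k in keys], sort=False).sum() \
            / w.groupby([sub[k] for k in keys], sort=False).sum()
        agg.name = "suvr"
    return agg.reset_index()


def laterality_table(biomarkers: pd.DataFrame,
                     rois: list[MetaROIDefinition] | None = None) -> pd.DataFrame:
    """Per-target LI table over regions and (optionally) meta-ROIs.

    Returns one row per (subject_id, timepoint_years, tracer, target)
    with columns ``left_suvr``, ``right_suvr``, ``li``, ``abs_li``.
    Meta-ROI LIs are computed from the two hemisphere mean SUVRs, never
    by averaging per-region LIs.
    """
    frames = []
    keys = ["subject_id", "timepoint_years", "tracer"]
    wide = biomarkers.pivot_table(
        index=keys + ["region_name"], columns="hemisphere",
        values="suvr", aggfunc="first",
    ).reset_index().rename(columns={"region_name": "target"})
    frames.append(wide)
    for roi in rois or []:
        agg = aggregate_meta_roi(biomarkers, roi)
        w = agg.pivot_table(index=keys, columns="hemisphere",
                            values="suvr", aggfunc="first").reset_index()
        w["target"] = roi.name
        frames.append(w)
    out = pd.concat(frames, ignore_index=True)
    incomplete = out["left"].isna() | out["right"].isna()
    out = out.loc[~incomplete].copy()
    out = out.rename(columns={"left": "left_suvr", "right": "right_suvr"})
    out["li"] = compute_li(out["left_suvr"].to_numpy(),
                           out["right_suvr"].to_numpy())
    out["abs_li"] = out["li"].abs()
    cols = keys + ["target", "left_suvr", "right_suvr", "li", "abs_li"]
    return out[cols]


def classify_status(biomarkers: pd.DataFrame,
                    temporal_roi: MetaROIDefinition,
                    neocortical_roi: MetaROIDefinition | None = None,
                    tau_cutoff: float = TAU_CUTOFF,
                    abeta_cutoff: float = ABETA_CUTOFF,
                    external_status: pd.DataFrame | None = None) -> pd.DataFrame:
    """A+/T+ status per (subject, timepoint).

    Tau positivity uses the most affected hemisphere: max of the left
    and right temporal meta-ROI SUVR strictly above ``tau_cutoff``.
    Amyloid positivity uses the bilateral (both-hemisphere) neocortical
    composite strictly above ``abeta_cutoff``.  Rows present in
    ``external_status`` (columns subject_id, timepoint_years,
    abeta_positive and/or tau_positive) override the PET rule, e.g. for
    CSF-based amyloid status.
    """
    keys = ["subject_id", "timepoint_years"]
    tau = biomarkers[biomarkers["tracer"] == "tau"]
    parts = []
    if len(tau):
        agg = aggregate_meta_roi(tau, temporal_roi)
        worst = agg.groupby(keys)["suvr"].max().rename("worst_temporal_tau")
        parts.append((worst > tau_cutoff).rename("tau_positive"))
    abeta = biomarkers[biomarkers["tracer"] == "abeta"]
    if neocortical_roi is not None and len(abeta):
        agg = aggregate_meta_roi(abeta, neocortical_roi)
        bilat = agg.groupby(keys)["suvr"].mean()
        parts.append((bilat > abeta_cutoff).rename("abeta_positive"))
    if not parts and external_status is None:
        raise IntegrityError("no PET data and no external status supplied")
    status = pd.concat(parts, axis=1).reset_index() if parts else pd.DataFrame(columns=keys)
    status["basis"] = "pet"
    if external_status is not None:
        ext = external_status.copy()
        ext["basis"] = "external"
        status = status.set_index(keys)
        ext = ext.set_index(keys)
        for col in ("abeta_positive", "tau_positive"):
            if col in ext.columns:
                status.loc[ext.index.intersection(status.index), col] = np.nan
                status = status.combine_first(ext[[col]])
        status.loc[status.index.isin(ext.index), "basis"] = "external"
        status = status.reset_index()
    return status


@dataclass(frozen=True)
class AsymmetryThresholds:
    """Grouping thresholds: the +/-5% borderline band around 1 SD.

    ``threshold_low`` (0.95 sd) bounds the symmetric group,
    ``threshold_high`` (1.05 sd) the asymmetric groups; LIs between the
    two are borderline.
    """

    threshold_low: float
    threshold_high: float
    sd_li: float | None = None

    def __post_init__(self):
        if not (0 < self.threshold_low < self.threshold_high):
            raise ValueError("need 0 < threshold_low < threshold_high")

    @classmethod
    def from_sd(cls, sd_li: float) -> "AsymmetryThresholds":
        return cls(0.95 * sd_li, 1.05 * sd_li, sd_li)

    @classmethod
    def from_bounds(cls, low: float, high: float) -> "AsymmetryThresholds":
        """Explicit (possibly rounded) bounds; ratio must be near 1.05/0.95."""
        if not np.isclose(high / low, 1.05 / 0.95, rtol=1e-2):
            raise ValueError("bounds must be close to the 0.95/1.05 SD ratio")
        return cls(low, high, (low / 0.95 + high / 1.05) / 2)


def derive_asymmetry_thresholds(temporal_tau_li, about: str = "mean") -> AsymmetryThresholds:
    """Grouping thresholds from the cohort temporal tau LI distribution.

    ``sd_li`` is the sample standard deviation (denominator n - 1) about
    the sample mean; ``about="zero"`` instead uses the root mean square
    about perfect symmetry (LI = 0).
    """
    li = np.asarray(temporal_tau_li, dtype=float)
    li = li[np.isfinite(li)]
    if li.size < 2:
        raise ValueError("need at least two finite LI values")
    if about == "mean":
        sd = float(np.std(li, ddof=1))
    elif about == "zero":
        sd = float(np.sqrt(np.sum(li ** 2) / (li.size - 1)))
    else:
        raise ValueError(f"unknown centring {about!r}")
    if sd == 0.0:
        raise ValueError("degenerate cohort: zero LI variance")
    return AsymmetryThresholds.from_sd(sd)


def assign_asymmetry_group(li, thresholds: AsymmetryThresholds):
    """Partition LI values into LA / S / RA / borderline.

    LA: li < -threshold_high; RA: li > threshold_high;
    S: |li| < threshold_low; borderline otherwise.
    """
    arr = np.asarray(li, dtype=float)
    lo, hi = thresholds.threshold_low, thresholds.threshold_high
    out = np.full(arr.shape, "borderline", dtype=object)
    out[arr < -hi] = "LA"
    out[arr > hi] = "RA"
    out[np.abs(arr) < lo] = "S"
    if arr.ndim == 0:
        return str(out[()])
    return pd.Series(out, name="asymmetry_group") if isinstance(li, pd.Series) else out


def burden_ranked_composites(biomarkers: pd.DataFrame,
                             subjects=None) -> dict[str, MetaROIDefinition]:
    """Split regions into high/medium/low tau-burden composites.

    Regions are ranked by cohort-average bilateral tau SUVR; "high" are
    regions strictly above the 75th percentile of the region means,
    "low" strictly below the 25th, "medium" the rest.  Percentiles use
    linear interpolation.
    """
    tau = biomarkers[biomarkers["tracer"] == "tau"]
    if subjects is not None:
        tau = tau[tau["subject_id"].isin(set(map(str, subjects)))]
    if tau.empty:
        raise ValueError("no tau data for the requested cohort")
    region_mean = tau.groupby("region_name")["suvr"].mean()
    if len(region_mean) < 4:
        raise ValueError("need at least 4 regions to rank burden")
    q25, q75 = np.percentile(region_mean.to_numpy(), [25, 75])
    high = frozenset(region_mean.index[region_mean > q75])
    low = frozenset(region_mean.index[region_mean < q25])
    medium = frozenset(region_mean.index) - high - low
    return {
        "high_burden": MetaROIDefinition("high_burden", high),
        "medium_burden": MetaROIDefinition("medium_burden", medium),
        "low_burden": MetaROIDefinition("low_burden", low),
    }
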