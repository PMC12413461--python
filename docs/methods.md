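# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `hemilat`.

## Laterality quantification

The laterality index of a target (region or meta-ROI composite) is
`LI (%) = 100 (R − L)/(R + L)` on strictly positive SUVRs, so it is
bounded in [−100, 100], antisymmetric under hemisphere swap, and
invariant to common positive rescaling (e.g. a change of reference
region that affects both hemispheres equally). Meta-ROI LIs are always
computed from the two hemisphere *mean* SUVRs of the member regions,
never by averaging per-region LIs: the two differ whenever regional
uptake varies, and the hemisphere-mean definition is the one consistent
with treating the composite as a single ROI. Regional means are
unweighted by default; volume weights can be supplied but are not part
of the default because region volumes are not an input of the pipeline.

Positivity is strict (`SUVR > cutoff`): tau from the temporal
(Braak I–IV) composite of the most affected hemisphere against 1.362,
amyloid from the bilateral neocortical composite against 1.033. Both
cutoffs are consumed as constants (they come from external cutpoint
estimation, which is out of scope); an externally supplied status
column (e.g. CSF-based amyloid positivity) overrides the PET rule for
the subjects it covers.

## Asymmetry grouping

Thresholds derive from the cohort SD of the temporal tau LI among A+T+
subjects: sample SD about the sample mean, denominator n − 1. Whether
the dispersion should be taken about the mean or about perfect symmetry
(LI = 0) is genuinely open; the sample-mean convention is the default
and `about="zero"` switches to the RMS-about-zero alternative. The
borderline exclusion band is multiplicative: the symmetric group
requires |LI| < 0.95·sd, the asymmetric groups |LI| > 1.05·sd, and LIs
in between are "borderline" — excluded from group contrasts but kept in
continuous-LI models. The multiplicative reading of the "±5% band"
is adopted because it makes the two thresholds a fixed 1.05/0.95 ratio,
matching how such threshold pairs are reported in cohort studies.
`AsymmetryThresholds.from_bounds` accepts an explicit (possibly
rounded) pair and checks the ratio to 1%, because printed thresholds
are typically rounded to two decimals.

## Connectivity statistics

The control-derived mask ranks inter-hemispheric edges by mean weight
across control subjects and keeps the top `ceil(fraction · E)` (default
fraction 0.10), breaking ties by lexicographic (i, j) node order so
masks are deterministic and invariant to the order of the control
matrices. Homotopic edge-wise models and the per-subject
inter-hemispheric average operate on the masked edge set by default;
the homotopic analysis set is the intersection of homotopic pairs with
the mask (a switch selects all pairs).

**Network-Based Statistic.** Per edge, the group-contrast t-statistic
comes from `weight ~ group + age + sex + tau load`. Edges with
t above the threshold form a graph whose connected components
(extracted with sparse graph routines; size = edge count) are tested by
permutation: p_fwe = (1 + b)/(1 + P) with b the number of permutations
whose maximal component size reaches the observed size — never zero,
by construction. Covariates are handled Freedman–Lane style: edge
weights are residualized on the reduced (covariate-only) model, the
residual rows are permuted, the reduced fits are added back, and the
full model is refit. Plain label permutation is not valid in the
presence of covariates, and Freedman–Lane is the standard remedy in the
permutation-inference literature. Both contrast
directions are thresholded separately and share a single permutation
null of the maximum over both directions, so p_fwe is monotone in
component size within a run and family-wise error is controlled jointly
across directions (slightly conservative per direction). Intensity-based
component sizing is not implemented — inference is on extent only.

## Association models

"Standardized β" means: all continuous variables (outcome and
predictors) z-scored by their sample SDs — baseline-visit SDs in
longitudinal data — binary covariates left as 0/1, time left in years.
A cross-sectional coefficient is then on the partial-correlation scale;
a longitudinal interaction reads "outcome SDs per year per SD of the
moderator". Standardizing time was rejected because the time SD depends
on the visit schedule, which would make coefficients incomparable
across designs; with time in years the planted generator effects are
analytically exact. Interaction terms are products of standardized
variables (standardize first, multiply after).

Cross-sectional fits are OLS with t-based 95% CIs. Constant non-focal
covariates are dropped with a warning (e.g. a single-status cohort); a
constant focal predictor is an error. Mixed models use `statsmodels`
MixedLM with random intercept and slope for time, fitted by REML
(L-BFGS); on convergence failure the fit falls back to a random
intercept only and records the fallback on the result. Multiplicity:
Benjamini–Hochberg step-up across region or edge families, Bonferroni
(m = 3) across pairwise group contrasts and m = number of meta-ROIs for
the longitudinal ROI families.

## The synthetic cohort generator

The generator emulates the *statistical* structure the analyses
consume — laterality distributions, couplings, trajectories — not the
biology of tau spread or the spatial topography of real SUVR maps.

**Group mixture (cross-sectional).** Subjects are assigned LA/S/RA with
probabilities (0.22, 0.68, 0.10); each group's temporal tau LI is a
truncated normal confined to its classification band under thresholds
(8.78, 9.70), with the location solved by root-finding (Brent, tol
1e-10) so the *truncated* mean equals the target group mean (−14.4,
−0.4, +14.7 at scales 3.7, 4.9, 5.4). Group means are therefore exact
targets of the generator rather than approximations, and classification
of the draws returns the planted labels exactly. The scales are treated
as truncated-distribution scale parameters — one of several choices
consistent with post-classification summary statistics.

**Planted couplings.** With z the standardized amyloid LI, the global
tau LI is `(β z + sqrt(1 − β²) ε) · σ_tau` with independent ε ~ N(0,1)
and β = 0.632 (0.535 in the replication configuration, which also mixes
cognitive status 50/50 independently of both LIs). Because age and sex
are independent of both LIs, the standardized covariate-adjusted OLS
coefficient equals β in expectation — the noise scale follows from the
variance decomposition, nothing is tuned.

**SUVR back-construction.** Left/right SUVRs come from a bilateral mean
m and planted LI ℓ: `L = m(1 − ℓ/100)`, `R = m(1 + ℓ/100)`, so
`compute_li(L, R) = ℓ` to machine precision. All tau regions share
m = 1.8 (> 1.362) and all amyloid regions m = 1.6 (> 1.033), making
every simulated subject A+T+. With equal region means, hemisphere-mean
aggregation gives a composite LI equal to the arithmetic mean of member
LIs; temporal member regions carry the temporal mixture draw, and the
non-temporal regions carry `(n_all·g − n_temp·τ)/(n_all − n_temp)` plus
zero-sum regional noise, so the *computed* global and temporal LIs equal
the planted values exactly. A consequence of this exactness-first
construction: per-region tau–amyloid couplings are uniform over
non-temporal regions and ≈0 in temporal regions in the default
configuration. A realistic regional coupling gradient (strongest in
temporal cortex) is provided by the separate `simulate_regionwise`
generator with explicit per-region couplings, which is what the
region-wise association analyses are validated against.

**Longitudinal trajectories.** `tau_li(t) = α_i + (g0 + g1 z_i + u_i) t
+ e(t)` with baseline SD 7% (α and e partitioned so that the baseline
cross-section has exactly that SD), residual SD 2%, random slope SD
1 %/yr, g0 = 0.043·7 %/yr and g1 = 0.025·7 %/yr per SD of baseline
amyloid LI. Visit counts are uniform on 2–5 with follow-up span
~N(2.9, 0.8) years (floor 0.5), first visit at 0, intermediate visits
uniform. The residual and random-slope scales were chosen so the
variance components are well-identified: with a near-zero random-slope
variance the REML fit sits on the boundary of the parameter space,
which is slow and biases the fixed-effect interaction. A+T−/A+T+ strata
and T-conversion flags are emitted with the cohort's approximate
proportions (38% T+ at baseline; 21% of T− convert) for stratified
analyses; the default generative parameters are shared across strata.

**Cognition.** mPACC baseline ~N(−2.6, 1.5); the annual slope (in
baseline-SD units) is `c0 + Σ c_roi · z(|tau LI_roi|) + noise` with
c0 = −0.15 and, by default, a single planted effect c = −0.157 on the
Braak V–VI composite. |LI| of a centred normal is half-normal, so the
standardization uses its exact moments (mean σ√(2/π), SD
σ√(1 − 2/π)) and c is recovered as the standardized time × |LI|
interaction. An optional load-mediated pathway routes a share of the
effect through the ROI tau load for attenuation experiments.

**Connectivity.** Symmetric matrices with mean weights 0.55 (homotopic)
> 0.25 (intra-hemispheric) > 0.12 (heterotopic inter-hemispheric), a
subject-level global offset (SD 0.03) and independent edge noise (SD
0.12). The homotopic dominance makes the top-10% inter-hemispheric mask
homotopic-dominated, as in empirical connectomes. Group differences are
null by default — the relevant empirical finding is a null, so the
default validates specificity — with an optional planted edge component
for sensitivity tests. The global subject offset induces realistic
large-scale edge correlations; note that it inflates the permutation
null of maximal component sizes, which is exactly the behaviour NBS is
designed to absorb (power tests therefore plant components against
independent edge noise).

**What passing tests do not show.** The generator does not reproduce
spatial SUVR topography, tracer-specific off-target binding,
measurement error in region boundaries, informative visit schedules, or
dropout; recovery results certify the estimators under the assumed
models, not robustness to these real-data features.

## Problem sizes and numerical choices

Parameter-recovery checks use 100 replicate cohorts for the
cross-sectional couplings, 200 for the longitudinal interaction, and
10,000 draws for mixture calibration — enough that Monte-Carlo error is
several times smaller than the acceptance tolerances (±0.03, ±0.01,
±0.3 respectively). Matrix symmetry is validated to 1e-8; LI
reconstruction to 1e-9; planted regional LIs are clipped to ±95% to
keep back-constructed SUVRs strictly positive (relevant only in the
extreme tails). Percentile-based burden composites use linear
interpolation with strict inequalities, so equal-burden regions all
land in the medium stratum. NBS p-values use the add-one estimator and
are bounded below by 1/(P + 1).

## Known limitations

- MixedLM occasionally converges to the boundary for small random-slope
  variances; the intercept-only fallback is recorded but changes the
  interaction SE slightly.
- The NBS engine tests a two-group contrast; F-type multi-group NBS is
  not implemented (run pairwise contrasts instead).
- The builtin atlas follows the standard 84-node cortical + subcortical
  assignment; site-specific variants should be supplied as YAML.
- External (file-based) longitudinal inputs are supported through the
  model-fitting functions directly; the orchestrated pipeline generates
  its longitudinal stage synthetically.
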