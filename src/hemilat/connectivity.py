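"""Inter-hemispheric connectivity statistics and the Network-Based Statistic.

The analysis chain mirrors a connectome group study: a biologically
plausible edge mask is derived from healthy controls (top fraction of
inter-hemispheric edges by mean weight), per-subject summaries average
the masked edges, homotopic (same-region left-right) edges get
edge-wise regressions against tau asymmetry, and whole-network group
contrasts use cluster-based inference on supra-threshold edge
components with family-wise-error control by permutation (NBS).

Permutation inference uses the Freedman-Lane scheme: edge weights are
residualized on the nuisance covariates under the reduced model, the
residuals are permuted across subjects, refitted under the full model,
and the maximal supra-threshold component size forms the null
distribution.  Both contrast directions (target > reference and
reference > target) are thresholded separately; their p-values share a
single null of the permutation-wise maximum over both directions, so
family-wise error is controlled jointly across directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .core_data import ConnectivityMatrix, IntegrityError, RegionAtlas
from .models import ModelSpec, ModelResult, bh_fdr, fit_cross_sectional

__all__ = [
    "EdgeMask",
    "NBSComponent",
    "NBSResult",
    "build_control_mask",
    "average_interhemispheric",
    "homotopic_edge_models",
    "nbs",
    "group_outcome_models",
]


@dataclass(frozen=True)
class EdgeMask:
    """Retained inter-hemispheric edges with provenance."""

    modality: str
    retained_edges: tuple[tuple[int, int], ...]  # (i, j) with i < j
    fraction: float
    n_controls: int

    def __len__(self) -> int:
        return len(self.retained_edges)


def _stack_weights(matrices: list[ConnectivityMatrix],
                   edges: list[tuple[int, int]]) -> np.ndarray:
    """Subjects x edges weight array for the given edge list."""
    ii = np.array([e[0] for e in edges])
    jj = np.array([e[1] for e in edges])
    return np.stack([m.weights[ii, jj] for m in matrices])


def build_control_mask(control_matrices: list[ConnectivityMatrix],
                       atlas: RegionAtlas,
                       fraction: float = 0.10) -> EdgeMask:
    """Rank inter-hemispheric edges by mean control weight; keep the top.

    Retains ``ceil(fraction * E)`` edges of the E inter-hemispheric
    pairs; ties broken by lexicographic (i, j) node order so the mask is
    deterministic and invariant to the order of the control matrices.
    """
    if not control_matrices:
        raise ValueError("need at least one control matrix")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    edges = atlas.interhemispheric_edges()
    if not edges:
        raise ValueError("atlas has no inter-hemispheric edges")
    mean_w = _stack_weights(control_matrices, edges).mean(axis=0)
    n_keep = ceil(fraction * len(edges))
    order = sorted(range(len(edges)), key=lambda k: (-mean_w[k], edges[k]))
    kept = sorted(edges[k] for k in order[:n_keep])
    return EdgeMask(modality=control_matrices[0].modality,
                    retained_edges=tuple(kept), fraction=fraction,
                    n_controls=len(control_matrices))


def average_interhemispheric(matrix: ConnectivityMatrix, mask: EdgeMask) -> float:
    """Unweighted mean weight over the masked inter-hemispheric edges."""
    if len(mask) == 0:
        raise ValueError("empty edge mask")
    ii = np.array([e[0] for e in mask.retained_edges])
    jj = np.array([e[1] for e in mask.retained_edges])
    w = matrix.weights[ii, jj]
    if not np.all(np.isfinite(w)):
        raise IntegrityError(
            f"non-finite weight on a masked edge for subject {matrix.subject_id!r}"
        )
    return float(w.mean())


def homotopic_edge_models(matrices: list[ConnectivityMatrix],
                          atlas: RegionAtlas,
                          covariates: pd.DataFrame,
                          mask: EdgeMask | None = None,
                          focal: str = "abs_tau_li",
                          extra_covariates: tuple[str, ...] = ("age_years", "sex", "tau_load"),
                          ) -> pd.DataFrame:
    """Edge-wise regressions of homotopic connectivity on tau asymmetry.

    For every homotopic pair (restricted to the mask when given) fits
    ``edge weight ~ age + sex + tau load + |tau LI|`` across subjects
    and applies BH-FDR across the pair set.  ``covariates`` must carry
    one row per subject_id in the order-independent sense; matrices are
    matched on ``subject_id``.
    """
    pairs = atlas.homotopic_pairs
    if mask is not None:
        kept = set(mask.retained_edges)
        pairs = [p for p in pairs if tuple(sorted(p)) in kept]
    if not pairs:
        raise ValueError("no homotopic pairs in the analysis set")
    cov = covariates.set_index("subject_id")
    matrices = [m for m in matrices if m.subject_id in cov.index]
    weights = _stack_weights(matrices, [tuple(sorted(p)) for p in pairs])
    cov = cov.loc[[m.subject_id for m in matrices]].reset_index()
    labels = atlas.node_labels
    rows = []
    spec = ModelSpec(outcome="edge_weight",
                     predictors=(*extra_covariates, focal),
                     focal_predictor=focal)
    for k, (i, j) in enumerate(pairs):
        df = cov.copy()
        df["edge_weight"] = weights[:, k]
        res = fit_cross_sectional(df, spec)
        region = labels[i].split("-", 1)[1]
        rows.append({"region": region, "node_left": i, "node_right": j,
                     "beta_std": res.beta_std, "ci_low": res.ci95[0],
                     "ci_high": res.ci95[1], "p": res.p, "n_obs": res.n_obs})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Network-Based Statistic


@dataclass(frozen=True)
class NBSComponent:
    direction: str  # "target>reference" | "reference>target"
    edges: tuple[tuple[int, int], ...]
    nodes: tuple[int, ...]
    size: int  # edge count (extent)
    p_fwe: float


@dataclass
class NBSResult:
    edge_threshold: float
    n_permutations: int
    seed: int | None
    components: list[NBSComponent] = field(default_factory=list)
    null_max_size: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_fwe < 0.05]


def _edge_t_stats(Y: np.ndarray, X: np.ndarray, coef_index: int) -> np.ndarray:
    """t-statistic of one design column for every edge (column of Y)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T
    B = P @ Y
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[coef_index, coef_index], 1e-300))
    return B[coef_index] / se


def _components_from_edges(edge_array: np.ndarray, supra: np.ndarray,
                           n_nodes: int):
    """Connected components of the supra-threshold subgraph.

    Returns (component label per supra edge, edge count per label).
    """
    sel = edge_array[supra]
    if len(sel) == 0:
        return None, np.array([], dtype=int)
    adj = sp.coo_matrix(
        (np.ones(len(sel)), (sel[:, 0], sel[:, 1])), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    edge_labels = labels[sel[:, 0]]
    sizes = np.bincount(edge_labels)
    return edge_labels, sizes


def _max_component_size(edge_array, supra, n_nodes) -> int:
    _, sizes = _components_from_edges(edge_array, supra, n_nodes)
    return int(sizes.max()) if sizes.size else 0


def nbs(matrices: list[ConnectivityMatrix], groups: pd.Series,
        covariates: pd.DataFrame, atlas: RegionAtlas,
        edge_threshold: float = 3.0, n_permutations: int = 5000,
        seed: int | None = None, mask: EdgeMask | None = None,
        covariate_columns: tuple[str, ...] = ("age_years", "sex", "tau_load"),
        ) -> NBSResult:
    """Network-Based Statistic contrast between two subject groups.

    Per edge, the group contrast t-statistic comes from the linear model
    ``weight ~ group + covariates``.  Edges with ``t > edge_threshold``
    (each direction separately) form a graph whose connected components
    are tested by permutation: component p_fwe = (1 + b) / (1 + P) where
    b counts permutations whose maximal component size (over both
    directions) reaches the observed size.

    ``groups`` is aligned with ``matrices`` and must contain exactly two
    levels; the lexicographically larger level is the "target" group.
    """
    if edge_threshold <= 0:
        raise ValueError("edge threshold must be positive")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    levels = sorted(pd.Series(groups).unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g = (pd.Series(groups).reset_index(drop=True) == levels[1]).astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("each group needs at least two subjects")

    n_nodes = atlas.n_nodes
    if mask is not None:
        edges = list(mask.retained_edges)
    else:
        edges = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    edge_array = np.array(edges)
    Y = _stack_weights(matrices, edges)
    n = Y.shape[0]

    cov = covariates.reset_index(drop=True)
    Z = np.column_stack([np.ones(n)] +
                        [pd.to_numeric(cov[c], errors="coerce").to_numpy()
                         if cov[c].dtype != object else
                         (cov[c] == sorted(cov[c].unique(), key=str)[-1]).astype(float).to_numpy()
                         for c in covariate_columns])
    X_full = np.column_stack([Z[:, :1], g.to_numpy(), Z[:, 1:]])
    coef_index = 1

    t_obs = _edge_t_stats(Y, X_full, coef_index)

    # Freedman-Lane: residualize on the reduced (covariate-only) model,
    # permute residuals, add back reduced fits, refit the full model.
    Pz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    fitted_r = Pz @ Y
    resid_r = Y - fitted_r
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        t_perm = _edge_t_stats(fitted_r + resid_r[perm], X_full, coef_index)
        null_max[b] = max(
            _max_component_size(edge_array, t_perm > edge_threshold, n_nodes),
            _max_component_size(edge_array, -t_perm > edge_threshold, n_nodes),
        )

    result = NBSResult(edge_threshold=edge_threshold,
                       n_permutations=n_permutations, seed=seed,
                       null_max_size=null_max)
    for direction, supra in ((f"{levels[1]}>{levels[0]}", t_obs > edge_threshold),
                             (f"{levels[0]}>{levels[1]}", -t_obs > edge_threshold)):
        edge_labels, sizes = _components_from_edges(edge_array, supra, n_nodes)
        if edge_labels is None:
            continue
        sel = edge_array[supra]
        for label in np.unique(edge_labels):
            comp_edges = sel[edge_labels == label]
            size = int(len(comp_edges))
            p_fwe = (1 + int((null_max >= size).sum())) / (1 + n_permutations)
            result.components.append(NBSComponent(
                direction=direction,
                edges=tuple(map(tuple, comp_edges.tolist())),
                nodes=tuple(sorted(set(comp_edges.ravel().tolist()))),
                size=size, p_fwe=p_fwe,
            ))
    result.components.sort(key=lambda c: (-c.size, c.p_fwe, c.direction))
    return result


def group_outcome_models(data: pd.DataFrame, outcome: str,
                         group_col: str = "asymmetry_group",
                         groups: tuple[str, ...] = ("LA", "S", "RA"),
                         covariate_columns: tuple[str, ...] = ("age_years", "sex", "tau_load"),
                         ) -> dict[tuple[str, str], ModelResult | None]:
    """Pairwise group contrasts of a per-subject outcome.

    One standardized OLS per contrast (LA-S, RA-S, LA-RA):
    ``outcome ~ covariates + group indicator``; Bonferroni adjustment
    over the three comparisons.  Empty groups yield None with a warning.
    """
    contrasts = [(groups[0], groups[1]), (groups[2], groups[1]),
                 (groups[0], groups[2])]
    out: dict[tuple[str, str], ModelResult | None] = {}
    for a, b in contrasts:
        sub = data[data[group_col].isin((a, b))].copy()
        if sub[group_col].nunique() < 2:
            warnings.warn(f"contrast {a}-{b} skipped: empty group")
            out[(a, b)] = None
            continue
        sub["group_ind"] = (sub[group_col] == a).astype(float)
        spec = ModelSpec(outcome=outcome,
                         predictors=(*covariate_columns, "group_ind"),
                         focal_predictor="group_ind")
        res = fit_cross_sectional(sub, spec)
        res.p_adj = float(min(1.0, 3 * res.p))
        res.adjustment = "bonferroni"
        out[(a, b)] = res
    return out
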