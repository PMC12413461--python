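"""Data model and I/O for region-level PET tables and connectivity matrices.

All tabular inputs are delimited text (comma or tab, auto-detected).
Biomarker tables are long-format: one row per (subject, timepoint,
tracer, region, hemisphere) SUVR measurement.  Connectivity matrices are
square labelled matrices over the atlas nodes; node order is normalised
to atlas order on read so downstream code can index positionally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas_data

__all__ = [
    "FormatError",
    "IntegrityError",
    "Region",
    "RegionAtlas",
    "MetaROIDefinition",
    "ConnectivityMatrix",
    "load_atlas",
    "read_biomarker_table",
    "write_biomarker_table",
    "read_covariate_table",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "BIOMARKER_COLUMNS",
]


class FormatError(ValueError):
    """Structurally malformed input (missing columns, bad labels)."""


class IntegrityError(ValueError):
    """Well-formed input that violates a data invariant."""


BIOMARKER_COLUMNS = [
    "subject_id", "timepoint_years", "tracer",
    "region_name", "hemisphere", "suvr",
]

HEMISPHERES = ("left", "right")
TRACERS = ("tau", "abeta")


@dataclass(frozen=True)
class Region:
    name: str
    hemisphere: str  # "left" | "right"
    lobe: str
    node_index: int

    @property
    def label(self) -> str:
        prefix = "lh" if self.hemisphere == "left" else "rh"
        return f"{prefix}-{self.name}"


@dataclass(frozen=True)
class MetaROIDefinition:
    """Named composite of atlas regions, hemisphere-agnostic."""

    name: str
    member_regions: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "member_regions", frozenset(self.member_regions))


@dataclass
class RegionAtlas:
    """Parcellation with explicit hemisphere labels and homotopic pairing.

    Homotopic pairs are inferred from shared ``region_name`` across the
    two hemispheres; every bilateral region yields exactly one pair.
    """

    regions: list[Region]

    def __post_init__(self):
        idx = [r.node_index for r in self.regions]
        if sorted(idx) != list(range(len(self.regions))):
            raise FormatError("node_index values must be unique and contiguous")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate (region, hemisphere) in atlas")

    @property
    def n_nodes(self) -> int:
        return len(self.regions)

    @property
    def node_labels(self) -> list[str]:
        return [r.label for r in sorted(self.regions, key=lambda r: r.node_index)]

    @property
    def region_names(self) -> set[str]:
        return {r.name for r in self.regions}

    @property
    def hemisphere_of(self) -> np.ndarray:
        """Array over node index: 0 for left, 1 for right."""
        out = np.empty(self.n_nodes, dtype=int)
        for r in self.regions:
            out[r.node_index] = 0 if r.hemisphere == "left" else 1
        return out

    @property
    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """(left_node, right_node) pairs sharing a region name."""
        by_name: dict[str, dict[str, int]] = {}
        for r in self.regions:
            by_name.setdefault(r.name, {})[r.hemisphere] = r.node_index
        pairs = []
        for name in sorted(by_name):
            sides = by_name[name]
            if "left" in sides and "right" in sides:
                pairs.append((sides["left"], sides["right"]))
        return pairs

    def interhemispheric_edges(self) -> list[tuple[int, int]]:
        """All (i, j), i < j, joining nodes of opposite hemispheres."""
        hemi = self.hemisphere_of
        n = self.n_nodes
        return [(i, j) for i in range(n) for j in range(i + 1, n)
                if hemi[i] != hemi[j]]


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted matrix over atlas nodes; diagonal is unused."""

    subject_id: str
    modality: str  # "functional" | "structural"
    node_labels: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError("connectivity matrix must be square")
        if w.shape[0] != len(self.node_labels):
            raise FormatError("matrix dimension does not match node labels")
        if not np.allclose(w, w.T, atol=1e-8, equal_nan=True):
            raise IntegrityError(
                f"matrix for subject {self.subject_id!r} is asymmetric"
            )
        self.weights = w


def _builtin_atlas() -> tuple[RegionAtlas, list[MetaROIDefinition]]:
    regions = []
    idx = 0
    for hemisphere in HEMISPHERES:
        for name, lobe in atlas_data.ALL_REGIONS:
            regions.append(Region(name, hemisphere, lobe, idx))
            idx += 1
    rois = [MetaROIDefinition(name, frozenset(members))
            for name, members in atlas_data.default_meta_rois().items()]
    return RegionAtlas(regions), rois


def load_atlas(source: str | Path = "dk84") -> tuple[RegionAtlas, list[MetaROIDefinition]]:
    """Load an atlas and its meta-ROI composites.

    Parameters
    ----------
    source
        Builtin name ``"dk84"`` (84-node Desikan-Killiany + subcortical)
        or path to a YAML file with keys ``regions`` (list of mappings
        with ``name``, ``hemisphere`` and optionally ``lobe``) and
        ``meta_rois`` (mapping of composite name to member-region list).
        Node order follows the file's region order.
    """
    if isinstance(source, str) and source == "dk84":
        return _builtin_atlas()
    path = Path(source)
    spec = yaml.safe_load(path.read_text())
    if not isinstance(spec, dict) or "regions" not in spec:
        raise FormatError(f"atlas file {path} lacks a 'regions' section")
    regions = []
    for i, entry in enumerate(spec["regions"]):
        hemisphere = entry.get("hemisphere")
        if hemisphere not in HEMISPHERES:
            raise FormatError(
                f"region {entry.get('name')!r} has no valid hemisphere"
            )
        regions.append(Region(entry["name"], hemisphere,
                              entry.get("lobe", "unknown"), i))
    atlas = RegionAtlas(regions)
    rois = []
    for name, members in (spec.get("meta_rois") or {}).items():
        unknown = set(members) - atlas.region_names
        if unknown:
            raise FormatError(f"meta-ROI {name!r} references unknown regions {sorted(unknown)}")
        rois.append(MetaROIDefinition(name, frozenset(members)))
    return atlas, rois


def _read_delimited(path: str | Path | io.IOBase, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kw)


def validate_biomarker_table(df: pd.DataFrame,
                             atlas: RegionAtlas | None = None) -> pd.DataFrame:
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"biomarker table lacks columns {missing}")
    df = df[BIOMARKER_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    try:
        df["suvr"] = pd.to_numeric(df["suvr"])
        df["timepoint_years"] = pd.to_numeric(df["timepoint_years"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric SUVR or timepoint: {exc}") from exc
    if (df["suvr"] <= 0).any():
        bad = df.loc[df["suvr"] <= 0]
        raise IntegrityError(
            f"{len(bad)} rows with non-positive SUVR (first: "
            f"{bad.iloc[0][['subject_id', 'region_name']].to_dict()})"
        )
    if not df["tracer"].isin(TRACERS).all():
        raise FormatError("tracer must be 'tau' or 'abeta'")
    if not df["hemisphere"].isin(HEMISPHERES).all():
        raise FormatError("hemisphere must be 'left' or 'right'")
    key = ["subject_id", "timepoint_years", "tracer", "region_name", "hemisphere"]
    dup = df.duplicated(key)
    if dup.any():
        raise IntegrityError(
            f"{int(dup.sum())} duplicate measurement keys, e.g. "
            f"{df.loc[dup, key].iloc[0].to_dict()}"
        )
    if atlas is not None:
        unknown = set(df["region_name"]) - atlas.region_names
        if unknown:
            raise FormatError(f"unknown region names: {sorted(unknown)[:5]}")
    return df.reset_index(drop=True)


def read_biomarker_table(path: str | Path, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Read and validate a long-format biomarker SUVR table."""
    return validate_biomarker_table(_read_delimited(path), atlas)


def write_biomarker_table(df: pd.DataFrame, path: str | Path) -> None:
    df[BIOMARKER_COLUMNS].to_csv(path, index=False)


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    for col in ("subject_id", "age_years", "sex"):
        if col not in df.columns:
            raise FormatError(f"covariate table lacks column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    if (df["age_years"] <= 0).any():
        raise IntegrityError("non-positive age")
    return df


def read_connectivity_matrix(path: str | Path, atlas: RegionAtlas,
                             modality: str,
                             subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a labelled square matrix and align node order to the atlas."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    labels = [str(c) for c in df.columns]
    if set(labels) != set(atlas.node_labels):
        extra = set(labels) - set(atlas.node_labels)
        raise FormatError(
            f"matrix node labels do not match atlas (unexpected: {sorted(extra)[:5]})"
        )
    if list(df.index.astype(str)) != labels:
        raise FormatError("matrix row and column labels differ")
    df = df.loc[atlas.node_labels, atlas.node_labels]
    return ConnectivityMatrix(
        subject_id=subject_id or Path(path).stem,
        modality=modality,
        node_labels=atlas.node_labels,
        weights=df.to_numpy(dtype=float),
    )


def write_connectivity_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.weights, index=matrix.node_labels,
                 columns=matrix.node_labels).to_csv(path)
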