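"""Core in-memory containers shared by all pipeline stages.

The pipeline moves four kinds of data around: a segmented CT volume per
patient, gene-by-sample omics matrices (protein or transcript), a per-patient
table of radiologist-scored imaging traits with reader provenance, and the
run configuration.  Each container validates its own invariants on
construction so downstream math can assume them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMaskError, MaskFormatError, ParameterError, SchemaError, ShapeMismatchError

READERS = ("reader1", "reader2", "consolidated")

TRAIT_KINDS = ("binary", "ordinal", "count", "quantitative")

#: trait kinds whose reader disagreements are arbitrated rather than averaged
CATEGORICAL_KINDS = ("binary", "ordinal", "count")


@dataclass
class SegmentedVolume:
    """A 3D CT intensity grid with a multi-site integer segmentation mask.

    Attributes
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Attenuation values in Hounsfield units.
    spacing : tuple of float
        Voxel size (x, y, z) in mm; all components positive.
    mask : ndarray of int, same shape
        Site labels; 0 is background and the nonzero labels are 1..S.
    patient_id : str
        Opaque identifier carried into per-patient outputs.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.intensities.shape != self.mask.shape:
            raise ShapeMismatchError(
                f"intensity shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        if self.intensities.ndim != 3:
            raise ShapeMismatchError(f"expected 3D grids, got {self.intensities.ndim}D")
        if not np.issubdtype(self.mask.dtype, np.integer):
            if not np.allclose(self.mask, np.round(self.mask)):
                raise MaskFormatError("mask contains non-integer labels")
            self.mask = np.round(self.mask).astype(np.int32)
        if np.any(self.mask < 0):
            raise MaskFormatError("mask labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive components, got {self.spacing}")
        labels = np.unique(self.mask[self.mask > 0])
        if labels.size == 0:
            raise EmptyMaskError("mask has no foreground voxels")
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise MaskFormatError(
                f"site labels must be contiguous 1..S, got {labels.tolist()}; "
                "use io.read_segmented_volume / relabel_sites to compact them"
            )

    @property
    def n_sites(self) -> int:
        return int(self.mask.max())

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def site_volumes_ml(self) -> np.ndarray:
        """Volume of each site 1..S in mL."""
        counts = np.bincount(self.mask.ravel(), minlength=self.n_sites + 1)[1:]
        return counts * self.voxel_volume_ml


@dataclass
class OmicsMatrix:
    """A genes x samples abundance matrix with explicit missing values.

    ``values`` is a DataFrame indexed by gene id with sample-id columns; NaN
    marks a missing measurement (never silently zero).  ``kind`` records
    whether the measurements are protein log-ratios or transcript expression.
    """

    values: pd.DataFrame
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "transcript"):
            raise ParameterError(f"kind must be 'protein' or 'transcript', got {self.kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParameterError(f"duplicate gene ids after consolidation: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ParameterError("duplicate sample ids")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class TraitSpec:
    """Declared type of one imaging trait.

    kind is one of binary / ordinal / count / quantitative; ordinal traits
    carry an explicit level ordering (index 0 = first listed level).
    """

    kind: str
    levels: tuple = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ParameterError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and len(self.levels) < 2:
            raise ParameterError("ordinal trait needs an explicit level ordering")


class TraitTable:
    """Per-patient imaging traits with reader-1/reader-2/consolidated columns.

    ``data`` is a DataFrame indexed by patient id whose columns are a
    MultiIndex of (trait, reader) with reader in ``READERS``.  ``schema`` maps
    trait name to its :class:`TraitSpec`.  Ordinal traits are stored as level
    indices (0-based into ``TraitSpec.levels``).
    """

    def __init__(self, data: pd.DataFrame, schema: Mapping[str, TraitSpec]):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ParameterError("TraitTable data needs (trait, reader) MultiIndex columns")
        self.schema = dict(schema)
        for trait in data.columns.get_level_values(0).unique():
            if trait not in self.schema:
                raise SchemaError(trait)
        self.data = data.sort_index(axis=1)

    @property
    def traits(self) -> list[str]:
        return [t for t in self.schema if (t, READERS[0]) in self.data.columns or (t, "consolidated") in self.data.columns]

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    def reader(self, reader: str) -> pd.DataFrame:
        """Patients x traits frame for one reader column."""
        if reader not in READERS:
            raise ParameterError(f"unknown reader {reader!r}")
        sub = self.data.xs(reader, axis=1, level=1)
        return sub

    def has_consolidated(self) -> bool:
        cols = self.data.columns
        return all((t, "consolidated") in cols for t in self.traits)


def _freeze(obj):
    if isinstance(obj, dict):
        return {k: _freeze(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_freeze(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class PipelineConfig:
    """Run configuration: the fixed constants of every pipeline stage.

    The defaults are the values the pipeline runs with throughout: 32 gray
    levels with an in-plane radius-2 window and the four axial unit offsets
    for texture; K=4 texture sub-regions from 5 restarts of RBF kernel
    K-means; a p < 0.1 tail threshold for the prioritization funnel; and
    alpha = 0.05 with exact rank tests up to n = 25 for the association layer.
    """

    texture: dict = field(default_factory=lambda: {
        "n_levels": 32,
        "window_radius": 2,
        "offsets": [[0, 1], [1, 0], [1, 1], [1, -1]],
        "planar": True,
        "symmetric": True,
    })
    clustering: dict = field(default_factory=lambda: {
        "n_clusters": 4,
        "kernel": "rbf",
        "restarts": 5,
        "bandwidth_subsample": 1000,
    })
    prioritization: dict = field(default_factory=lambda: {
        "p_threshold": 0.1,
        "cv_side": "lower",
        "rho_side": "upper",
        "shift_epsilon": 1e-6,
    })
    association: dict = field(default_factory=lambda: {
        "alpha": 0.05,
        "exact_max_n": 25,
        "bh_family": "per_feature",
    })
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (
            ("prioritization.p_threshold", self.prioritization.get("p_threshold")),
            ("association.alpha", self.association.get("alpha")),
        ):
            if not (0 < float(value) < 1):
                raise ParameterError(f"{name} must lie in (0, 1), got {value}")

    def to_dict(self) -> dict:
        return _freeze({
            "texture": self.texture,
            "clustering": self.clustering,
            "prioritization": self.prioritization,
            "association": self.association,
            "seed": self.seed,
        })

    def config_hash(self) -> str:
        """Short stable digest of the configuration, embedded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
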