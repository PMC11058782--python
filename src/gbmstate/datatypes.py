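"""Core containers shared across the pipeline.

Orientation convention: expression grids are genes x cells (rows x columns),
matching the triplet MTX layout the loaders read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The four transcriptional meta-module states, in tie-break priority order.
STATES: tuple[str, ...] = ("NPC", "OPC", "AC", "MES")

#: Label for the intermediate/hybrid state spread between AC-like and MES-like.
HYBRID: str = "HYBRID"

LAYERS = ("counts", "lognorm", "relative")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression grid with a layer tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are cell (or spot) ids.
    layer
        One of ``counts``, ``lognorm`` or ``relative``.
    total_umi
        Per-cell total UMI counts (counts layer bookkeeping; carried through).
    mito_fraction
        Per-cell fraction of counts from mitochondrial genes.
    """

    values: pd.DataFrame
    layer: str = "counts"
    total_umi: pd.Series | None = None
    mito_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        if self.layer == "counts":
            vals = self.values.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts layer contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_counts(
        cls, values: pd.DataFrame, mito_prefix: str = "MT-"
    ) -> "ExpressionMatrix":
        """Wrap a raw count grid, computing per-cell totals and mito fractions.

        The mitochondrial gene set is identified by an id prefix (default
        ``MT-``); no curated list is assumed.
        """
        totals = values.sum(axis=0)
        is_mito = values.index.str.startswith(mito_prefix)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito = values.loc[is_mito].sum(axis=0) / totals
        mito = mito.fillna(0.0)
        return cls(values=values, layer="counts", total_umi=totals, mito_fraction=mito)

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(cell_ids)
        return ExpressionMatrix(
            values=self.values[ids],
            layer=self.layer,
            total_umi=None if self.total_umi is None else self.total_umi[ids],
            mito_fraction=None
            if self.mito_fraction is None
            else self.mito_fraction[ids],
        )


@dataclass
class GeneSetCatalog:
    """Named gene sets (state meta-modules, derived signatures, user sets)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate ids")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    def add(self, name: str, genes: Iterable[str]) -> None:
        genes = list(genes)
        if name in self.sets:
            raise ValueError(f"set {name!r} already present")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} contains duplicate ids")
        self.sets[name] = genes


@dataclass
class EnrichmentResult:
    """Pre-ranked enrichment outcome for one gene set."""

    set_name: str
    es: float
    nes: float
    p: float
    q: float
    n_perm: int
    seed: int
    n_hits: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValueError(f"ES out of [-1, 1]: {self.es}")


@dataclass
class PairedEnrichmentCall:
    """Per-patient enrichment call on paired (longitudinal) profiles."""

    patient: str
    call: str  # enriched_up | enriched_down | no_change
    nes: float
    q: float


@dataclass
class KinaseActivityResult:
    """Kinase-substrate enrichment z-score for one kinase."""

    kinase: str
    z: float
    m: int
    p: float
    significant: bool


@dataclass
class SpatialSample:
    """Spot table with coordinates, region labels and score (or gene) grids.

    ``spots`` holds columns spot_id, row, col, region; ``scores`` is a
    spot x signature frame indexed by spot_id; ``expr`` optionally holds a
    genes x spots matrix still to be scored.
    """

    spots: pd.DataFrame
    scores: pd.DataFrame | None = None
    expr: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        required = {"spot_id", "row", "col", "region"}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        coords = list(zip(self.spots["row"], self.spots["col"]))
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate spot coordinates")

    @property
    def spot_ids(self) -> pd.Index:
        return pd.Index(self.spots["spot_id"])


@dataclass
class SpatialCorrelationArray:
    """Per-sample c x c spatially weighted correlation matrices plus mean."""

    signatures: list[str]
    stack: np.ndarray  # (n_samples, c, c)
    reduced: pd.DataFrame  # c x c
    region: str


@dataclass
class VesselScene:
    """Cells and vessel polylines in a 2-D field.

    ``cells`` columns: cell_id, x, y, cell_class (NesHI | NesLO),
    region (invasive_front | core). ``segments`` maps a segment id to an
    (n_vertices, 2) array of polyline coordinates.
    """

    cells: pd.DataFrame
    segments: dict[str, np.ndarray]
    contact_radius: float = 5.0

    def __post_init__(self) -> None:
        required = {"cell_id", "x", "y", "cell_class", "region"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if not self.segments:
            raise ValueError("scene has no vessel segments")
        for sid, verts in self.segments.items():
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 2:
                raise ValueError(f"segment {sid!r} is not an (n>=2, 2) polyline")
            if not np.isfinite(verts).all():
                raise ValueError(f"segment {sid!r} has non-finite vertices")
        if not np.isfinite(self.cells[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite cell positions")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    Generators fill the fields they plant; the rest stay None.
    """

    cell_states: pd.Series | None = None  # cell_id -> true state
    reprogrammed: pd.Series | None = None  # cell_id -> bool
    original_states: pd.Series | None = None  # pre-reprogramming labels
    gene_marker_of: pd.Series | None = None  # gene_id -> state (markers only)
    active_kinases: dict[str, float] | None = None  # kinase -> planted effect
    division_counts: pd.Series | None = None  # record_id -> X_true
    vessel_attached: pd.Series | None = None  # cell_id -> bool
    colocalization: float | None = None
    params: dict | None = None  # generator parameters (JSON-serializable)
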