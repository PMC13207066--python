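"""Core domain types shared across the pipeline.

Conventions
-----------
* Expression matrices are oriented **genes x units** (units = cells, bulk
  samples or spatial spots). Readers transpose as needed so downstream code
  never has to guess.
* Gene and unit identifiers are matched case-sensitively as plain strings;
  no symbol aliasing is performed.
* Missing clinical values are encoded as NaN, never as 0.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Layer",
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSetCollection",
    "ClinicalCohort",
    "Network",
    "SpatialSection",
    "RegionLabel",
    "LoadReport",
]


class Layer(str, enum.Enum):
    """Processing state of an expression matrix."""

    counts = "counts"
    lognorm = "lognorm"


class RegionLabel(str, enum.Enum):
    """Anatomical origin of a spatial section."""

    tumor_core = "tumor_core"
    interface = "interface"


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x units non-negative expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with unit ids as columns.
    layer
        ``counts`` for raw (integer-like, >= 0) data, ``lognorm`` for
        log-normalized data.
    """

    values: pd.DataFrame
    layer: Layer = Layer.counts

    def __post_init__(self) -> None:
        if isinstance(self.layer, str):
            self.layer = Layer(self.layer)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "unit")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"unit {self.values.columns[bad[1]]!r}"
            )
        if self.layer == Layer.counts and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.values.index[bad[0]]!r}, "
                f"unit {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], layer=self.layer)

    def subset_units(self, units: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(units)], layer=self.layer)


@dataclass
class CellAnnotation:
    """Per-cell labels: subpopulation, originating sample, optional region."""

    table: pd.DataFrame  # index = cell ids; columns: subpopulation, sample_id, [region]

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "cell")
        if "subpopulation" not in self.table.columns:
            raise ValueError("annotation table requires a 'subpopulation' column")
        if self.table["subpopulation"].isna().any():
            missing = self.table.index[self.table["subpopulation"].isna()][0]
            raise ValueError(f"cell {missing!r} has no subpopulation label")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def subpopulations(self) -> list[str]:
        return sorted(self.table["subpopulation"].unique())

    def cells_of(self, subpopulation: str) -> list[str]:
        mask = self.table["subpopulation"] == subpopulation
        return list(self.table.index[mask])


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (e.g. one per cell subpopulation)."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                dup = next(g for g in genes if genes.count(g) > 1)
                raise ValueError(f"gene set {name!r} contains duplicate gene {dup!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


# Canonical stage axes and their admissible ordinal codes.
STAGE_RANGES: Mapping[str, tuple[int, int]] = {
    "t_stage": (1, 4),
    "n_stage": (0, 1),
    "m_stage": (0, 1),
    "tnm_stage": (1, 4),
}


@dataclass
class ClinicalCohort:
    """Per-sample survival and ordinal TNM staging annotations.

    ``os_time`` is carried in the unit declared at load time (``time_unit``)
    and never converted. Stage columns hold ordinal codes (float with NaN
    for missing).
    """

    table: pd.DataFrame  # index = sample ids; columns: os_time, os_event, t/n/m/tnm_stage
    time_unit: str = "days"

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in ("os_time", "os_event"):
            if col not in self.table.columns:
                raise ValueError(f"clinical table requires column {col!r}")
        t = self.table["os_time"]
        if (t.dropna() <= 0).any():
            bad = self.table.index[t <= 0][0]
            raise ValueError(f"non-positive os_time for sample {bad!r}")
        ev = self.table["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("os_event must be binary 0/1")
        for col, (lo, hi) in STAGE_RANGES.items():
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if ((vals < lo) | (vals > hi)).any():
                    raise ValueError(f"{col} codes outside [{lo}, {hi}]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def stage(self, axis: str) -> pd.Series:
        """Ordinal codes for axis in {'T','N','M','TNM'} (NaN = missing)."""
        col = {"T": "t_stage", "N": "n_stage", "M": "m_stage", "TNM": "tnm_stage"}[axis]
        if col not in self.table.columns:
            return pd.Series(np.nan, index=self.table.index, name=col)
        return self.table[col]


@dataclass
class Network:
    """A gene regulatory network as a (possibly weighted) edge list.

    Self-loops are dropped at construction and counted in
    ``n_self_loops_dropped``; duplicate edges are collapsed with weights
    summed.
    """

    edges: list[tuple[str, str, float]]
    directed: bool = True
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        cleaned: dict[tuple[str, str], float] = {}
        dropped = 0
        for edge in self.edges:
            if len(edge) == 2:
                s, t, w = edge[0], edge[1], 1.0
            else:
                s, t, w = edge
            if s == t:
                dropped += 1
                continue
            key = (s, t) if self.directed else tuple(sorted((s, t)))  # type: ignore[assignment]
            cleaned[key] = cleaned.get(key, 0.0) + float(w)
        self.edges = [(s, t, w) for (s, t), w in cleaned.items()]
        self.n_self_loops_dropped += dropped

    @property
    def nodes(self) -> list[str]:
        out: set[str] = set()
        for s, t, _ in self.edges:
            out.add(s)
            out.add(t)
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SpatialSection:
    """One spatial-transcriptomics tissue section.

    ``coordinates`` rows align one-to-one with ``spots.unit_ids``.
    """

    section_id: str
    spots: ExpressionMatrix
    coordinates: pd.DataFrame  # index = spot ids; columns x, y
    region_label: RegionLabel = RegionLabel.tumor_core

    def __post_init__(self) -> None:
        if isinstance(self.region_label, str):
            self.region_label = RegionLabel(self.region_label)
        spot_ids = set(self.spots.unit_ids)
        coord_ids = set(self.coordinates.index)
        missing = spot_ids - coord_ids
        if missing:
            raise ValueError(
                f"spot {sorted(missing)[0]!r} has counts but no coordinates"
            )
        extra = coord_ids - spot_ids
        if extra:
            raise ValueError(
                f"spot {sorted(extra)[0]!r} has coordinates but no counts"
            )
        if not np.all(np.isfinite(self.coordinates[["x", "y"]].to_numpy())):
            raise ValueError("non-finite spot coordinates")
        # align coordinate row order with the count matrix
        self.coordinates = self.coordinates.loc[self.spots.unit_ids]

    @property
    def n_spots(self) -> int:
        return self.spots.shape[1]


@dataclass
class LoadReport:
    """Row accounting for a reader: kept + rejected + coerced == total."""

    total: int = 0
    kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    coerced: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
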