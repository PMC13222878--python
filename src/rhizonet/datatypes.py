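"""Domain types shared by every analysis stage.

The central container is :class:`AbundanceTable` — a samples × taxa count
matrix with per-sample metadata describing the factorial design of a
rhizobox experiment (site × root compartment × amendment treatment).
Trait tables, zymogram images and compartment masks carry the soil
chemistry / root morphology / enzyme-imaging side of the study, and
:class:`CooccurrenceNetwork` carries the per-condition correlation graphs.

All types validate their invariants at construction time and raise
:class:`ValidationError` with a message naming the offending entry.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Site",
    "Compartment",
    "Treatment",
    "Condition",
    "METADATA_COLUMNS",
    "AbundanceTable",
    "TraitTable",
    "Zymogram",
    "CompartmentMasks",
    "CooccurrenceNetwork",
]


class ValidationError(ValueError):
    """An input violated a documented type invariant."""


class Site(str, enum.Enum):
    NON_URBAN = "non_urban"
    PERI_URBAN = "peri_urban"


class Compartment(str, enum.Enum):
    RHIZOSPHERE = "rhizosphere"
    RHIZOPLANE = "rhizoplane"


class Treatment(str, enum.Enum):
    UNTREATED = "untreated"
    BIOCHAR = "biochar"


#: metadata columns required for every sample, beside the sample_id index
METADATA_COLUMNS = ("site", "compartment", "treatment", "rhizobox_id")

_ENUM_COLUMNS = {"site": Site, "compartment": Compartment, "treatment": Treatment}


@dataclass(frozen=True)
class Condition:
    """One cell of the experimental design: site × compartment × treatment."""

    site: str
    compartment: str
    treatment: str

    def __post_init__(self) -> None:
        Site(self.site)
        Compartment(self.compartment)
        Treatment(self.treatment)

    def label(self) -> str:
        return f"{self.site}.{self.compartment}.{self.treatment}"


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    if metadata.index.name != "sample_id":
        metadata = metadata.copy()
        metadata.index.name = "sample_id"
    if metadata.index.duplicated().any():
        dup = metadata.index[metadata.index.duplicated()][0]
        raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValidationError(f"metadata lacks required columns {missing_cols}")
    for col, enum_cls in _ENUM_COLUMNS.items():
        levels = {e.value for e in enum_cls}
        bad = set(metadata[col].astype(str)) - levels
        if bad:
            raise ValidationError(
                f"unknown {col} level(s) {sorted(bad)}; expected one of {sorted(levels)}"
            )
        if metadata[col].isna().any():
            raise ValidationError(f"missing value in metadata column {col!r}")
    return metadata


@dataclass
class AbundanceTable:
    """Samples × taxa abundance matrix with aligned sample metadata.

    Parameters
    ----------
    counts
        Non-negative numeric matrix; rows are samples (index = sample_id),
        columns are taxon labels. Either raw counts or relative abundances
        are accepted downstream.
    metadata
        One row per sample, indexed by sample_id, with columns
        ``site``, ``compartment``, ``treatment``, ``rhizobox_id``.
    taxonomy
        Optional taxon → rank annotation table (index = taxon label,
        columns may include ``phylum`` and ``genus``); required only for
        rank aggregation.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon label {dup!r}")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r} in counts")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size and (np.isnan(values.astype(float)).any()):
            raise ValidationError("counts contain missing values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count {values[i, j]} for sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        metadata = _validate_metadata(self.metadata)
        missing = counts.index.difference(metadata.index)
        if len(missing):
            raise ValidationError(
                f"sample(s) missing from metadata: {list(map(str, missing))}"
            )
        # align metadata row order to the count matrix; extra metadata rows
        # (samples without counts) are dropped silently
        object.__setattr__(self, "metadata", metadata.loc[counts.index])
        if self.taxonomy is not None:
            extra = pd.Index(counts.columns).difference(self.taxonomy.index)
            if len(extra):
                raise ValidationError(
                    f"taxa missing from taxonomy: {list(map(str, extra))[:5]}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances (each sample sums to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0][0]
            raise ValidationError(f"sample {empty!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def subset(
        self,
        site: str | None = None,
        compartment: str | None = None,
        treatment: str | None = None,
    ) -> "AbundanceTable":
        """Return the sub-table of samples matching the given factor levels."""
        keep = pd.Series(True, index=self.metadata.index)
        for col, value in (
            ("site", site),
            ("compartment", compartment),
            ("treatment", treatment),
        ):
            if value is not None:
                keep &= self.metadata[col].astype(str) == str(value)
        idx = self.metadata.index[keep]
        return AbundanceTable(
            counts=self.counts.loc[idx].copy(),
            metadata=self.metadata.loc[idx].copy(),
            taxonomy=self.taxonomy,
        )

    def condition_of(self, sample_id: str) -> Condition:
        row = self.metadata.loc[sample_id]
        return Condition(str(row["site"]), str(row["compartment"]), str(row["treatment"]))


@dataclass
class TraitTable:
    """Per-unit trait measurements (soil chemistry, root morphology, enzymes).

    ``values`` is units × traits; missing measurements are permitted (NaN)
    and propagate as pairwise-complete deletion in downstream correlations.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate trait name {dup!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate unit id {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("trait values must be numeric")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def units(self) -> list[str]:
        return list(self.values.index)


@dataclass
class Zymogram:
    """A greyscale enzyme-activity membrane image.

    ``image`` holds the grey values exactly as acquired (8/16-bit integer
    or float); ``pixel_size`` is the physical edge length of one pixel in
    centimetres.
    """

    image: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValidationError(f"zymogram image must be 2-D, got shape {img.shape}")
        if not np.all(np.isfinite(img.astype(float))):
            raise ValidationError("zymogram image contains non-finite grey values")
        if not (self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        self.image = img


@dataclass
class CompartmentMasks:
    """Disjoint rhizoplane / rhizosphere / background partition of a ROI."""

    rhizoplane: np.ndarray
    rhizosphere: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.rhizoplane.shape,
            self.rhizosphere.shape,
            self.background.shape,
        }
        if len(shapes) != 1:
            raise ValidationError(f"mask shapes differ: {shapes}")
        for name in ("rhizoplane", "rhizosphere", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        overlap = (
            (self.rhizoplane & self.rhizosphere)
            | (self.rhizoplane & self.background)
            | (self.rhizosphere & self.background)
        )
        if overlap.any():
            raise ValidationError("compartment masks are not pairwise disjoint")

    def union(self) -> np.ndarray:
        return self.rhizoplane | self.rhizosphere | self.background

    def check_covers(self, roi: np.ndarray) -> None:
        if not np.array_equal(self.union(), np.asarray(roi, dtype=bool)):
            raise ValidationError("compartment masks do not exactly cover the ROI")

    def items(self) -> Iterable[tuple[str, np.ndarray]]:
        yield "rhizoplane", self.rhizoplane
        yield "rhizosphere", self.rhizosphere
        yield "background", self.background


@dataclass
class CooccurrenceNetwork:
    """Per-condition undirected genus co-occurrence graph.

    Edges carry ``rho`` (correlation coefficient), ``p`` (two-sided
    p-value of the screen) and ``sign`` (+1/−1). Every edge satisfies
    ``p < edge_alpha`` as used at construction.
    """

    graph: nx.Graph
    edge_alpha: float
    condition: Condition | None = None
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not (0 < self.edge_alpha <= 1):
            raise ValidationError(f"edge_alpha must be in (0, 1], got {self.edge_alpha}")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if "p" in data and not (data["p"] < self.edge_alpha):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) has p={data['p']} ≥ edge_alpha={self.edge_alpha}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho", np.nan),
                "p": d.get("p", np.nan),
                "sign": d.get("sign", 0),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])
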