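"""Core containers shared by every stage of the patch-seq pipeline.

A patch-seq experiment yields, for each cell, a transcriptome (raw gene
counts) and a set of whole-cell electrophysiology measurements recorded on
the same cell before harvesting.  The containers here keep the two
modalities aligned by cell identifier and carry donor-level metadata
(condition, glucose, demographics) used for stratification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight electrophysiology features used by the fingerprinting model,
#: in canonical column order.  Units follow raw patch-clamp exports:
#: membrane capacitance in pF; exocytosis (depolarization-evoked capacitance
#: increase) normalized to cell size in fF/pF; Ca2+/Na+ current densities in
#: pA/pF; cumulative Ca2+ charge entry in pC/pF.
EPHYS_FEATURES: tuple[str, ...] = (
    "cell_size",
    "total_exo",
    "first_exo",
    "late_exo",
    "early_ca_peak",
    "late_ca_peak",
    "ca_integral",
    "na_peak",
)

EPHYS_UNITS: dict[str, str] = {
    "cell_size": "pF",
    "total_exo": "fF/pF",
    "first_exo": "fF/pF",
    "late_exo": "fF/pF",
    "early_ca_peak": "pA/pF",
    "late_ca_peak": "pA/pF",
    "ca_integral": "pC/pF",
    "na_peak": "pA/pF",
}

#: Islet cell types recognised by the default marker scheme.
CELL_TYPES: tuple[str, ...] = ("alpha", "beta", "delta", "gamma", "acinar")

UNASSIGNED = "unassigned"

#: Marker transcripts used to call cell types: glucagon marks alpha cells,
#: insulin and islet amyloid polypeptide beta, somatostatin delta,
#: pancreatic polypeptide gamma, serine proteases acinar, ghrelin epsilon.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "alpha": ("GCG",),
    "beta": ("INS", "IAPP"),
    "delta": ("SST",),
    "gamma": ("PPY",),
    "acinar": ("PRSS1", "PRSS2"),
    "epsilon": ("GHRL",),
}

META_COLUMNS = ("donor", "condition", "glucose", "sex", "age", "bmi", "cit")

CONDITIONS = ("ND", "T1D")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class MarkerScheme:
    """Mapping of cell-type label to marker gene set.

    ``unassigned_label`` is used for cells whose best marker score is zero.
    """

    markers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    unassigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        for label, genes in self.markers.items():
            if len(genes) == 0:
                raise DatasetError(f"marker set for {label!r} is empty")


@dataclass
class PatchSeqDataset:
    """Joint container of counts, cell metadata and electrophysiology.

    Parameters
    ----------
    counts
        Gene x cell matrix of non-negative integer counts.
    gene_ids, cell_ids
        Ordered, unique row / column labels for ``counts``.
    cell_meta
        One row per cell (indexed by cell id) with the columns in
        :data:`META_COLUMNS`.
    ephys
        One row per cell carrying the eight :data:`EPHYS_FEATURES`.
        May be ``None`` or cover only a subset of cells; cells without
        electrophysiology are excluded from fingerprinting and correlation
        but retained for differential expression.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    ephys: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DatasetError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise DatasetError(
                f"counts has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        for name, labels in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = pd.Index(labels)[pd.Index(labels).duplicated()]
            if len(dup):
                raise DatasetError(f"duplicate {name} ids: {sorted(set(dup))[:5]}")
        if np.any(self.counts < 0):
            g, c = np.argwhere(self.counts < 0)[0]
            raise DatasetError(
                f"negative count at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DatasetError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        cells = set(self.cell_ids)
        unknown = [c for c in self.cell_meta.index if c not in cells]
        if unknown:
            raise DatasetError(f"metadata rows for unknown cells: {unknown[:5]}")
        missing_meta = [c for c in self.cell_ids if c not in set(self.cell_meta.index)]
        if missing_meta:
            raise DatasetError(f"cells missing metadata: {missing_meta[:5]}")
        # keep metadata aligned with the count matrix column order
        self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.ephys is not None:
            unknown = [c for c in self.ephys.index if c not in cells]
            if unknown:
                raise DatasetError(f"ephys rows for unknown cells: {unknown[:5]}")
            missing_cols = [f for f in EPHYS_FEATURES if f not in self.ephys.columns]
            if missing_cols:
                raise DatasetError(f"ephys table missing features: {missing_cols}")
            self.ephys = self.ephys[list(EPHYS_FEATURES)]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Integer row positions for the given gene labels."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise DatasetError(f"unknown genes: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cells_with_ephys(self) -> list[str]:
        if self.ephys is None:
            return []
        complete = self.ephys.dropna(axis=0, how="any")
        return [c for c in self.cell_ids if c in set(complete.index)]

    def summary(self) -> dict:
        by_cond = self.cell_meta["condition"].value_counts().to_dict()
        return {
            "n_genes": self.n_genes,
            "n_cells": self.n_cells,
            "n_donors": int(self.cell_meta["donor"].nunique()),
            "cells_by_condition": {k: int(v) for k, v in by_cond.items()},
            "n_cells_with_ephys": len(self.cells_with_ephys()),
            "total_counts": int(self.counts.sum()),
        }
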