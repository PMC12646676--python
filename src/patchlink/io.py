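"""Readers and writers for the on-disk dataset layout.

Counts are stored as MatrixMarket coordinate files (genes x cells) with
sidecar ``genes.tsv`` / ``barcodes.tsv`` label files, the layout emitted by
most single-cell quantification tools; dense TSV is accepted as a
convenience.  Metadata, electrophysiology and truth tables are
tab-separated with a header row.  Gene sets use the GMT convention
(set name, description, then member genes, tab-separated).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import EPHYS_FEATURES, DatasetError, PatchSeqDataset

FLOAT_FORMAT = "%.6g"


def _read_labels(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(counts_path, genes_path=None, cells_path=None):
    """Read a counts matrix from MTX (+ label files) or dense TSV.

    Returns ``(counts, gene_ids, cell_ids)`` with genes as rows.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise DatasetError("MTX counts require genes and cells label files")
        mat = scipy.io.mmread(os.fspath(counts_path))
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        gene_ids = _read_labels(genes_path)
        cell_ids = _read_labels(cells_path)
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise DatasetError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        return counts, gene_ids, cell_ids
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    return df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns]


def read_dataset(counts_path, genes_path=None, cells_path=None,
                 meta_path=None, ephys_path=None) -> PatchSeqDataset:
    """Assemble a :class:`PatchSeqDataset` from its on-disk pieces.

    Cells present in the metadata but absent from the electrophysiology
    table simply carry missing electrophysiology.
    """
    counts, gene_ids, cell_ids = read_counts(counts_path, genes_path, cells_path)
    if meta_path is None:
        raise DatasetError("cell metadata table is required")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    ephys = None
    if ephys_path is not None and Path(ephys_path).exists():
        ephys = pd.read_csv(ephys_path, sep="\t", index_col=0)
        ephys.index = ephys.index.astype(str)
    return PatchSeqDataset(counts, gene_ids, cell_ids, meta, ephys)


def write_counts(counts, gene_ids, cell_ids, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.mtx",
        "genes": directory / "genes.tsv",
        "cells": directory / "barcodes.tsv",
    }
    sparse = scipy.sparse.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(os.fspath(paths["counts"]), sparse, field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in gene_ids))
    paths["cells"].write_text("".join(f"{c}\n" for c in cell_ids))
    return paths


def write_table(df: pd.DataFrame, path, index_label="cell_id") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)
    return path


def write_dataset(dataset: PatchSeqDataset, directory) -> dict[str, Path]:
    """Write a dataset to ``directory`` in the standard layout."""
    directory = Path(directory)
    paths = write_counts(dataset.counts, dataset.gene_ids, dataset.cell_ids, directory)
    paths["meta"] = write_table(dataset.cell_meta, directory / "cell_meta.tsv")
    if dataset.ephys is not None:
        paths["ephys"] = write_table(dataset.ephys, directory / "ephys.tsv")
    return paths


def read_dataset_dir(directory) -> PatchSeqDataset:
    directory = Path(directory)
    return read_dataset(
        directory / "counts.mtx",
        directory / "genes.tsv",
        directory / "barcodes.tsv",
        directory / "cell_meta.tsv",
        directory / "ephys.tsv",
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into ``{set name: [genes]}``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DatasetError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = fields[0]
            if name in sets:
                raise DatasetError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise DatasetError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one symbol per line (# comments allowed)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes
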