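"""Normalization, marker-based cell typing and outlier exclusion.

Two library-size normalizations are used at different stages: counts per
10,000 with a log transform (CP10K-log) for cell typing, and counts per
million (CPM) for differential expression and correlation.  Cell types are
called directly from marker-gene scores; electrophysiology outliers are
removed per feature within (cell type, condition, glucose) strata at
|z| > 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DatasetError, MarkerScheme, PatchSeqDataset


def _normalize(counts: np.ndarray, cell_ids, target: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cell_ids[i] for i in zero[:10]]
        raise DatasetError(f"cells with zero total counts: {names}")
    return counts * (target / totals)


def normalize_cp10k_log(dataset: PatchSeqDataset) -> np.ndarray:
    """Scale each cell to 10,000 total counts, then apply ln(1 + x)."""
    scaled = _normalize(dataset.counts, dataset.cell_ids, 10_000.0)
    return np.log1p(scaled)


def normalize_cpm(dataset: PatchSeqDataset) -> np.ndarray:
    """Scale each cell to 1,000,000 total counts (no log transform)."""
    return _normalize(dataset.counts, dataset.cell_ids, 1_000_000.0)


def annotate_cell_types(
    norm_matrix: np.ndarray,
    gene_ids,
    cell_ids,
    scheme: MarkerScheme | None = None,
) -> pd.Series:
    """Label each cell with the type whose mean marker expression is maximal.

    ``norm_matrix`` should be CP10K-log normalized expression (genes x
    cells).  Cells whose best marker score is zero receive the scheme's
    unassigned label.  Ties between nonzero scores break by scheme order.
    """
    scheme = scheme or MarkerScheme()
    lookup = {g: i for i, g in enumerate(gene_ids)}
    scores = {}
    for label, markers in scheme.markers.items():
        rows = [lookup[m] for m in markers if m in lookup]
        if rows:
            scores[label] = np.asarray(norm_matrix)[rows, :].mean(axis=0)
    if not scores:
        raise DatasetError("no marker genes present in the dataset")
    score_mat = np.vstack(list(scores.values()))
    labels = list(scores.keys())
    best = np.argmax(score_mat, axis=0)
    out = np.array([labels[i] for i in best], dtype=object)
    out[score_mat.max(axis=0) == 0] = scheme.unassigned_label
    return pd.Series(out, index=list(cell_ids), name="cell_type")


def exclude_outliers(
    ephys: pd.DataFrame,
    strata: pd.DataFrame,
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask per-feature outliers within (cell type, condition, glucose) strata.

    Parameters
    ----------
    ephys
        Cells x features table; may contain missing values.
    strata
        Cells x (cell_type, condition, glucose) table aligned to ``ephys``
        by index.
    z_threshold
        Values with ``|value - group mean| / group sd > z_threshold`` are
        masked (set to NaN) for that feature only; the cell's other
        features are untouched.

    Returns the masked copy of ``ephys`` and a tidy report of removals.
    Groups with fewer than two observed values, or zero standard
    deviation, are passed through unchanged.
    """
    masked = ephys.copy().astype(float)
    strata = strata.loc[ephys.index]
    keys = ["cell_type", "condition", "glucose"]
    removed = []
    for group, idx in strata.groupby(keys, sort=True, observed=True).groups.items():
        block = masked.loc[idx]
        for feature in ephys.columns:
            vals = block[feature].dropna()
            if len(vals) < 2:
                continue
            sd = vals.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                continue
            z = (vals - vals.mean()) / sd
            bad = z.index[np.abs(z) > z_threshold]
            for cell in bad:
                masked.loc[cell, feature] = np.nan
                removed.append(
                    {"cell_id": cell, "feature": feature, "z": float(z.loc[cell]),
                     **dict(zip(keys, group))}
                )
    report = pd.DataFrame(removed, columns=["cell_id", "feature", "z", *keys])
    return masked, report
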