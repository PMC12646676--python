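"""Per-gene Wilcoxon rank-sum differential expression (T1D vs ND).

The statistic is the tie-corrected, continuity-corrected normal
approximation of the two-sample rank-sum test computed on CPM-normalized
expression (ranks are invariant to the log transform, so the statistic is
identical on log CPM).  Fold changes are ``log2((mean CPM_T1D + 1) /
(mean CPM_ND + 1))`` and FDR is Benjamini-Hochberg across all tested
genes.  Genes detected in fewer than ``min_cells`` cells overall are
dropped before testing (their p-value would be dominated by ties at
zero) and reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class DEError(ValueError):
    pass


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DEError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Signed z for ranks of x (group of interest) vs y, with tie and
    continuity corrections.  Positive z means x tends to be larger."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    return float((diff - cc) / np.sqrt(var))


def wilcoxon_de(
    cpm: np.ndarray,
    gene_ids,
    is_t1d: np.ndarray,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Rank-sum DE of T1D vs ND cells on a CPM matrix (genes x cells).

    Returns a table indexed by gene with columns ``z``, ``p``, ``q``,
    ``log2fc``, ``pct_nd``, ``pct_t1d`` and a boolean ``tested`` column
    (genes below the detection floor carry NaN statistics).
    """
    cpm = np.asarray(cpm, dtype=float)
    is_t1d = np.asarray(is_t1d, dtype=bool)
    if cpm.shape[1] != is_t1d.size:
        raise DEError("label vector length does not match cell count")
    n_t1d, n_nd = int(is_t1d.sum()), int((~is_t1d).sum())
    if n_t1d == 0 or n_nd == 0:
        raise DEError("both conditions must be represented")

    detected = (cpm > 0).sum(axis=1)
    tested = detected >= min_cells

    t1d = cpm[:, is_t1d]
    nd = cpm[:, ~is_t1d]
    z = np.full(cpm.shape[0], np.nan)
    for i in np.flatnonzero(tested):
        z[i] = _ranksum_z(t1d[i], nd[i])
    p = np.where(np.isnan(z), np.nan, 2.0 * stats.norm.sf(np.abs(z)))
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_fdr(p[tested])

    log2fc = np.log2((t1d.mean(axis=1) + 1.0) / (nd.mean(axis=1) + 1.0))
    table = pd.DataFrame(
        {
            "z": z,
            "p": p,
            "q": q,
            "log2fc": log2fc,
            "pct_nd": (nd > 0).mean(axis=1),
            "pct_t1d": (t1d > 0).mean(axis=1),
            "tested": tested,
        },
        index=pd.Index(list(gene_ids), name="gene"),
    )
    table.attrs["n_nd"] = n_nd
    table.attrs["n_t1d"] = n_t1d
    table.attrs["min_cells"] = min_cells
    table.attrs["pseudocount"] = 1.0
    return table
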