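"""Detection-filtered, zero-excluded, bootstrapped Spearman correlation.

The linkage statistic between a transcript and an electrophysiological
property: transcripts detected in at least half the cells are considered
(populational relevance); for each gene, cells with zero counts are
excluded from that gene's correlation to limit the influence of tied
ranks and zero inflation; Spearman's rho is computed on average ranks,
with a two-sided p from the t approximation on ``n_used - 2`` degrees of
freedom; bootstrapping over cells (B = 1,000, resample indices shared
across genes within an iteration) yields the mean coefficient used to
rank genes for enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class CorrelationError(ValueError):
    pass


def detection_filter(counts: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of genes detected (count > 0) in >= ``threshold`` of cells."""
    counts = np.asarray(counts)
    if counts.shape[1] == 0:
        raise CorrelationError("cell group is empty")
    return (counts > 0).mean(axis=1) >= threshold


def _spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_zero_excluded(expr, prop) -> tuple[float, int, float]:
    """Spearman rho of expression vs property after dropping zero-count cells.

    Cells with zero expression (and cells where either value is missing)
    are removed pairwise.  Returns ``(rho, n_used, p)``; rho and p are NaN
    when fewer than three cells remain or either margin is constant.
    """
    expr = np.asarray(expr, dtype=float)
    prop = np.asarray(prop, dtype=float)
    if expr.shape != prop.shape:
        raise CorrelationError(
            f"length mismatch: {expr.shape} expression vs {prop.shape} property"
        )
    mask = (expr != 0) & np.isfinite(expr) & np.isfinite(prop)
    n_used = int(mask.sum())
    if n_used < 3:
        return float("nan"), n_used, float("nan")
    rx = stats.rankdata(expr[mask])
    ry = stats.rankdata(prop[mask])
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan"), n_used, float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, n_used, _spearman_p(rho, n_used)


def _masked_rank_corr(E: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Row-wise zero-excluded Spearman for matrices of resamples.

    ``E`` and ``P`` are (B, n) matrices; entries where ``E`` is zero or
    either value is non-finite are excluded per row.  Rows with fewer than
    3 usable values or a constant margin give NaN.
    """
    E = np.asarray(E, dtype=float)
    P = np.asarray(P, dtype=float)
    bad = (E == 0) | ~np.isfinite(E) | ~np.isfinite(P)
    E = np.where(bad, np.nan, E)
    P = np.where(bad, np.nan, P)
    rE = stats.rankdata(E, axis=1, nan_policy="omit")
    rP = stats.rankdata(P, axis=1, nan_policy="omit")
    n = (~bad).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mE = np.nansum(rE, axis=1) / n
        mP = np.nansum(rP, axis=1) / n
        dE = rE - mE[:, None]
        dP = rP - mP[:, None]
        cov = np.nansum(dE * dP, axis=1)
        var_e = np.nansum(dE * dE, axis=1)
        var_p = np.nansum(dP * dP, axis=1)
        rho = cov / np.sqrt(var_e * var_p)
    rho[(n < 3) | (var_e == 0) | (var_p == 0)] = np.nan
    return rho


def bootstrap_correlations(
    matrix: np.ndarray,
    gene_ids,
    prop: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Zero-excluded Spearman per gene with a cell bootstrap.

    ``matrix`` is genes x cells expression (CPM; ranks are invariant to
    any monotone rescaling).  One resample of cells (with replacement) is
    drawn per iteration and shared across genes, preserving cross-gene
    dependence.  ``rho_original`` and its p come from the unresampled
    data; the bootstrap supplies ``rho_boot_mean`` and ``rho_boot_sd``
    over defined resamples.
    """
    if B < 1:
        raise CorrelationError("B must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    prop = np.asarray(prop, dtype=float)
    n_genes, n_cells = matrix.shape
    if prop.size != n_cells:
        raise CorrelationError("property vector length does not match cell count")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cells, size=(B, n_cells))

    rows = []
    boot_mean = np.full(n_genes, np.nan)
    boot_sd = np.full(n_genes, np.nan)
    for g in range(n_genes):
        rho, n_used, p = spearman_zero_excluded(matrix[g], prop)
        rows.append((rho, n_used, p))
        rhos = _masked_rank_corr(matrix[g][idx], prop[idx])
        ok = np.isfinite(rhos)
        if ok.any():
            boot_mean[g] = rhos[ok].mean()
            boot_sd[g] = rhos[ok].std(ddof=1) if ok.sum() > 1 else 0.0
    table = pd.DataFrame(
        rows, columns=["rho_original", "n_used", "p"],
        index=pd.Index(list(gene_ids), name="gene"),
    )
    table["rho_boot_mean"] = boot_mean
    table["rho_boot_sd"] = boot_sd
    table["significant"] = table["p"] < p_threshold
    table = table[
        ["rho_original", "rho_boot_mean", "rho_boot_sd", "n_used", "p", "significant"]
    ]
    table.attrs["B"] = B
    table.attrs["seed"] = seed
    table.attrs["p_threshold"] = p_threshold
    return table


def multi_property_consistency(
    tables: dict[str, pd.DataFrame],
    min_properties: int = 3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Genes significantly correlated, with one sign, across >= 3 properties.

    A gene qualifies when it is significant (p < threshold) in at least
    ``min_properties`` property tables and all of its significant
    ``rho_original`` values share one sign.  Genes meeting the count but
    mixing signs are reported in the table's ``attrs['mixed_sign']``.
    """
    if not tables:
        return pd.DataFrame(columns=["n_significant", "direction", "properties"])
    universes = [set(t.index) for t in tables.values()]
    universe = universes[0]
    for u in universes[1:]:
        if u != universe:
            raise CorrelationError("correlation tables must share a gene universe")

    records, mixed = [], []
    for gene in sorted(universe):
        sig_props, signs = [], []
        for prop_name, table in tables.items():
            row = table.loc[gene]
            if np.isfinite(row["p"]) and row["p"] < p_threshold:
                sig_props.append(prop_name)
                signs.append(np.sign(row["rho_original"]))
        if len(sig_props) < min_properties:
            continue
        if len(set(signs)) > 1:
            mixed.append(gene)
            continue
        records.append(
            {
                "gene": gene,
                "n_significant": len(sig_props),
                "direction": "+" if signs[0] > 0 else "-",
                "properties": ",".join(sig_props),
            }
        )
    out = pd.DataFrame(records, columns=["gene", "n_significant", "direction",
                                         "properties"]).set_index("gene")
    out.attrs["mixed_sign"] = mixed
    out.attrs["min_properties"] = min_properties
    out.attrs["p_threshold"] = p_threshold
    return out
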