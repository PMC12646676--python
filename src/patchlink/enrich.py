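"""Gene-set enrichment: preranked GSEA, weighted set cover, ORA, and
Fisher's-exact genetic-risk enrichment.

Preranked GSEA uses the classic weighted running-sum enrichment score
(hit increments proportional to |score|^w, miss decrements 1/(N - N_hit)),
a gene-permutation null for nominal p and NES, and the standard
NES-pooling FDR.  Weighted set cover greedily reduces redundancy among
significant sets.  Over-representation uses the hypergeometric upper
tail; genetic-risk enrichment uses the two-sided Fisher exact test with a
Haldane-Anscombe-corrected odds ratio and Woolf 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(order_scores: np.ndarray, hit_mask: np.ndarray,
                weight: float) -> tuple[float, int]:
    """Enrichment score and extremum position for one ordered hit mask."""
    n = order_scores.size
    n_hit = int(hit_mask.sum())
    steps = np.empty(n)
    w = np.abs(order_scores[hit_mask]) ** weight
    total = w.sum()
    if total == 0:
        # all hit scores are exactly zero: fall back to unweighted increments
        w = np.ones(n_hit)
        total = float(n_hit)
    steps[hit_mask] = w / total
    steps[~hit_mask] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list[str]


def gsea_preranked(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a gene -> score series.

    Genes are ranked by decreasing score.  Sets are intersected with the
    ranked universe; sets outside [min_size, max_size] after intersection,
    or equal to the whole universe, are skipped.  The null permutes set
    membership over genes (``n_perm`` draws per set size, shared across
    sets of equal size); p and NES are sign-matched, FDR follows the
    pooled-NES procedure.
    """
    scores = scores.astype(float)
    if scores.index.has_duplicates:
        raise EnrichmentError("duplicate genes in ranked list")
    if not np.all(np.isfinite(scores.to_numpy())):
        raise EnrichmentError("scores must be finite")
    order = scores.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    vals = order.to_numpy()
    n = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}

    kept: list[tuple[str, np.ndarray]] = []
    skipped: list[str] = []
    for name, members in sets.items():
        idx = np.array(sorted({pos_of[g] for g in members if g in pos_of}), dtype=int)
        if not (min_size <= idx.size <= max_size) or idx.size == n:
            skipped.append(name)
            continue
        kept.append((name, idx))

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({idx.size for _, idx in kept}):
        es_null = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[perm_idx] = True
            es_null[b], _ = _running_es(vals, mask, weight)
        null_by_size[size] = es_null

    rows = []
    obs_nes, null_nes_pool = [], []
    for name, idx in kept:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, pos = _running_es(vals, mask, weight)
        null = null_by_size[idx.size]
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        if same_sign.size == 0:
            p = 1.0 / n_perm
            nes = np.sign(es)
        else:
            p = float(np.mean(same_sign >= abs(es)))
            p = max(p, 1.0 / n_perm)
            denom = same_sign.mean()
            nes = es / denom if es >= 0 else -abs(es) / denom
        if es > 0:
            le = [g for g in genes[: pos + 1] if mask[pos_of[g]]]
        else:
            le = [g for g in genes[pos:] if mask[pos_of[g]]]
        rows.append({"set": name, "size": int(idx.size), "es": es, "nes": float(nes),
                     "p": p, "leading_edge": ",".join(le)})
        obs_nes.append(float(nes))
        # normalized null NES for the pooled FDR
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        norm = np.concatenate([
            pos_null / pos_null.mean() if pos_null.size else np.empty(0),
            neg_null / abs(neg_null).mean() if neg_null.size else np.empty(0),
        ])
        null_nes_pool.append(norm)

    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p",
                                        "leading_edge"])
    if len(table):
        pool = np.concatenate(null_nes_pool)
        obs = np.asarray(obs_nes)
        q = np.empty(len(obs))
        for i, nes in enumerate(obs):
            if nes >= 0:
                num = np.mean(pool >= nes) / max(np.mean(pool >= 0), 1e-12)
                den = np.mean(obs >= nes) / max(np.mean(obs >= 0), 1e-12)
            else:
                num = np.mean(pool <= nes) / max(np.mean(pool < 0), 1e-12)
                den = np.mean(obs <= nes) / max(np.mean(obs < 0), 1e-12)
            q[i] = min(1.0, num / max(den, 1e-12))
        table["q"] = q
    else:
        table["q"] = []
    table = table.set_index("set")
    table.attrs["skipped_sets"] = skipped
    table.attrs["n_perm"] = n_perm
    table.attrs["weight"] = weight
    return table


# ---------------------------------------------------------------------------
# weighted set cover


def weighted_set_cover(
    sets: dict[str, list[str]],
    weights: dict[str, float],
    universe: set[str] | None = None,
) -> list[str]:
    """Greedy redundancy reduction over significant gene sets.

    Repeatedly selects the set maximizing (newly covered genes x weight)
    until the universe (default: union of the sets) is covered or no set
    adds coverage.  Every selected set contributes at least one previously
    uncovered gene.  Ties break by set name for determinism.
    """
    members = {name: set(genes) for name, genes in sets.items()}
    if universe is None:
        universe = set().union(*members.values()) if members else set()
    uncovered = set(universe)
    selected: list[str] = []
    remaining = dict(members)
    while uncovered and remaining:
        best_name, best_gain = None, 0.0
        for name in sorted(remaining):
            new = len(remaining[name] & uncovered)
            if new == 0:
                continue
            gain = new * weights.get(name, 1.0)
            if gain > best_gain:
                best_name, best_gain = name, gain
        if best_name is None:
            break
        selected.append(best_name)
        uncovered -= remaining.pop(best_name)
    return selected


def set_cover_weights(q_values: pd.Series, cap: float = 16.0) -> dict[str, float]:
    """-log10(FDR q) weights, clipped at ``cap`` (q floored at 10**-cap)."""
    q = q_values.astype(float).clip(lower=10.0 ** (-cap))
    return (-np.log10(q)).clip(upper=cap).to_dict()


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_hypergeometric(
    hits, background, sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a hit list.

    Returns per set the overlap ``k``, expected overlap under the null,
    one-sided p for overlap >= k, and BH q across sets.
    """
    background = set(background)
    if not background:
        raise EnrichmentError("background is empty")
    hits = set(hits)
    if not hits <= background:
        raise EnrichmentError("hits must be a subset of the background")
    M, n_hits = len(background), len(hits)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & background
        K = len(members)
        k = len(members & hits)
        expected = n_hits * K / M
        p = float(stats.hypergeom.sf(k - 1, M, K, n_hits)) if K else 1.0
        rows.append({"set": name, "set_size": K, "k": k,
                     "expected": expected, "p": p})
    table = pd.DataFrame(rows, columns=["set", "set_size", "k", "expected", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table.set_index("set")


# ---------------------------------------------------------------------------
# genetic-risk enrichment


@dataclass
class RiskEnrichment:
    """2x2 Fisher-exact enrichment of a query list against a risk list."""

    table: np.ndarray  # [[query&risk, query&~risk], [~query&risk, ~query&~risk]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    list_name: str = ""

    def to_dict(self) -> dict:
        return {
            "list": self.list_name,
            "a": int(self.table[0, 0]),
            "b": int(self.table[0, 1]),
            "c": int(self.table[1, 0]),
            "d": int(self.table[1, 1]),
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
        }


def fisher_from_table(table: np.ndarray, list_name: str = "") -> RiskEnrichment:
    """Two-sided Fisher exact test with Haldane-Anscombe OR and Woolf CI."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise EnrichmentError("need a 2x2 table of non-negative integers")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if np.any(t == 0):
        t = t + 0.5  # Haldane-Anscombe correction
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    log_or = np.log(odds)
    return RiskEnrichment(
        table=table,
        odds_ratio=float(odds),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        p=float(p),
        list_name=list_name,
    )


def risk_enrichment_fisher(
    query, risk, background, list_name: str = ""
) -> RiskEnrichment:
    """Enrichment of ``risk`` genes within ``query``, against ``background``.

    Both lists must be subsets of the background (the universe of all
    tested genes).  The caller is responsible for how the risk list was
    built (e.g. human-genetic-evidence score >= 3, or eQTL significance at
    2e-6 strict / 5e-3 permissive); record it in ``list_name``.
    """
    background = set(background)
    query = set(query)
    risk = set(risk)
    if not (query | risk) <= background:
        extra = sorted((query | risk) - background)[:5]
        raise EnrichmentError(
            f"background must contain query and risk genes; missing {extra}"
        )
    a = len(query & risk)
    b = len(query - risk)
    c = len(risk - query)
    d = len(background) - a - b - c
    return fisher_from_table(np.array([[a, b], [c, d]]), list_name=list_name)
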