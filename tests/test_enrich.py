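"""GSEA, weighted set cover, ORA, and Fisher risk enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from patchlink.enrich import (
    EnrichmentError,
    fisher_from_table,
    gsea_preranked,
    ora_hypergeometric,
    risk_enrichment_fisher,
    set_cover_weights,
    weighted_set_cover,
)


def brute_force_es(scores: pd.Series, members, weight):
    """Independent O(N*m) running-sum oracle for the enrichment score."""
    order = scores.sort_values(ascending=False, kind="mergesort")
    members = set(members)
    nr = sum(abs(order[g]) ** weight for g in order.index if g in members)
    n_miss = len(order) - len(members & set(order.index))
    best, running = 0.0, 0.0
    for g in order.index:
        if g in members:
            running += (abs(order[g]) ** weight) / nr
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def fisher_two_sided_enumeration(table):
    """Exact two-sided Fisher p by full hypergeometric enumeration over all
    tables with the observed margins (point-probability rule)."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestGsea:
    def test_singleton_top_gene_unweighted_es_is_one(self):
        scores = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        table = gsea_preranked(
            scores, {"s": ["a"]}, n_perm=10, seed=0, weight=0.0, min_size=1
        )
        assert table.loc["s", "es"] == pytest.approx(1.0)

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_es_matches_brute_force_oracle(self, weight):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            genes = [f"g{i}" for i in range(n)]
            scores = pd.Series(rng.normal(size=n), index=genes)
            size = int(rng.integers(3, max(4, n // 3)))
            members = list(rng.choice(genes, size=size, replace=False))
            table = gsea_preranked(
                scores, {"s": members}, n_perm=5, seed=0,
                weight=weight, min_size=1,
            )
            expected = brute_force_es(scores, members, weight)
            assert table.loc["s", "es"] == pytest.approx(expected, abs=1e-12)

    def test_es_invariant_under_monotone_rescaling_when_unweighted(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        scores = pd.Series(rng.normal(size=40), index=genes)
        members = genes[::5]
        kw = dict(n_perm=5, seed=0, weight=0.0, min_size=1)
        a = gsea_preranked(scores, {"s": members}, **kw)
        b = gsea_preranked(3.0 * scores + np.sign(scores) * 0.0, {"s": members}, **kw)
        c = gsea_preranked(scores.apply(np.cbrt), {"s": members}, **kw)
        assert a.loc["s", "es"] == b.loc["s", "es"] == c.loc["s", "es"]

    def test_whole_universe_set_is_skipped(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        table = gsea_preranked(scores, {"all": list("abc")}, n_perm=5, seed=0,
                               min_size=1)
        assert len(table) == 0
        assert table.attrs["skipped_sets"] == ["all"]

    def test_nes_sign_matches_es(self, small_cohort):
        dataset, truth = small_cohort
        rng = np.random.default_rng(0)
        genes = dataset.gene_ids[:200]
        scores = pd.Series(rng.normal(size=200), index=genes)
        sets = {f"s{i}": list(rng.choice(genes, 15, replace=False))
                for i in range(5)}
        table = gsea_preranked(scores, sets, n_perm=100, seed=1)
        assert (np.sign(table["nes"]) == np.sign(table["es"])).all()
        for name in table.index:
            le = table.loc[name, "leading_edge"].split(",")
            assert set(le) <= set(sets[name])

    def test_permutation_p_is_stable(self):
        """Nominal p from 200 permutations agrees with a 2,000-permutation
        run within 3 binomial standard errors."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(150)]
        scores = pd.Series(rng.normal(size=150), index=genes)
        # moderately enriched set: top-quartile biased membership
        members = list(scores.nlargest(40).index[rng.choice(40, 12, replace=False)])
        p_small = gsea_preranked(scores, {"s": members}, n_perm=200, seed=1)
        p_big = gsea_preranked(scores, {"s": members}, n_perm=2000, seed=2)
        p1, p2 = p_small.loc["s", "p"], p_big.loc["s", "p"]
        se = np.sqrt(p2 * (1 - p2) / 200) + 1e-3
        assert abs(p1 - p2) <= 3 * se

    def test_planted_set_detected(self, small_cohort):
        """The planted DE set is the top enrichment on the DE z ranking."""
        import patchlink as pl
        from patchlink.synthetic import build_gene_sets

        dataset, truth = small_cohort
        cpm = pl.normalize_cpm(dataset)
        alpha = (truth.cell_type_of == "alpha").to_numpy()
        t1d = (dataset.cell_meta["condition"] == "T1D").to_numpy()
        de = pl.wilcoxon_de(cpm[:, alpha], dataset.gene_ids, t1d[alpha])
        sets = build_gene_sets(dataset, truth, seed=0)
        table = gsea_preranked(de["z"].dropna(), sets, n_perm=200, seed=3)
        assert table.loc["PLANTED_DE", "q"] < 0.1
        assert table["nes"].idxmax() == "PLANTED_DE"


class TestSetCover:
    def test_disjoint_sets_all_selected(self):
        sets = {"a": ["g1", "g2"], "b": ["g3"], "c": ["g4", "g5"]}
        selected = weighted_set_cover(sets, {k: 1.0 for k in sets})
        assert sorted(selected) == ["a", "b", "c"]

    def test_superset_dominates_at_equal_weight(self):
        sets = {"A": ["g1", "g2", "g3"], "B": ["g1", "g2"]}
        assert weighted_set_cover(sets, {"A": 1.0, "B": 1.0}) == ["A"]

    def test_every_selected_set_adds_coverage(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"s{i}": list(rng.choice(genes, rng.integers(2, 10), replace=False))
            for i in range(12)
        }
        weights = {k: float(rng.uniform(0.5, 3)) for k in sets}
        selected = weighted_set_cover(sets, weights)
        covered = set()
        for name in selected:
            new = set(sets[name]) - covered
            assert new
            covered |= new
        assert covered == set().union(*map(set, sets.values()))

    def test_greedy_matches_exhaustive_on_six_set_instance(self):
        """On a 6-set instance the greedy selection covers the union and is
        minimal: no selected set is redundant, and no strictly smaller
        subset of the sets achieves full coverage with >= the same total
        weighted coverage."""
        sets = {
            "a": ["1", "2", "3"],
            "b": ["3", "4"],
            "c": ["5", "6", "7", "8"],
            "d": ["1", "5"],
            "e": ["8", "9"],
            "f": ["2", "9"],
        }
        weights = {k: 1.0 for k in sets}
        universe = set().union(*map(set, sets.values()))
        selected = weighted_set_cover(sets, weights)
        assert set().union(*(set(sets[s]) for s in selected)) == universe
        # exhaustive search for the minimum cover size
        best = None
        for r in range(1, 7):
            for combo in itertools.combinations(sets, r):
                if set().union(*(set(sets[s]) for s in combo)) == universe:
                    best = r
                    break
            if best:
                break
        assert len(selected) == best

    def test_weights_from_q_values(self):
        w = set_cover_weights(pd.Series({"a": 0.01, "b": 1e-30}))
        assert w["a"] == pytest.approx(2.0)
        assert w["b"] == pytest.approx(16.0)


class TestOra:
    def test_degenerate_universe_gives_p_one(self):
        out = ora_hypergeometric(["a", "b"], ["a", "b"], {"s": ["a", "b"]})
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_tail_summation(self):
        """Background 20, set 5, hits 5, overlap 3: p equals the direct
        hypergeometric tail sum."""
        background = [f"g{i}" for i in range(20)]
        hits = background[:3] + background[10:12]
        members = background[:5]
        out = ora_hypergeometric(hits, background, {"s": members})
        expected = sum(
            comb(5, k, exact=True) * comb(15, 5 - k, exact=True)
            for k in range(3, 6)
        ) / comb(20, 5, exact=True)
        assert out.loc["s", "p"] == pytest.approx(expected, rel=1e-12)
        assert out.loc["s", "k"] == 3
        assert out.loc["s", "expected"] == pytest.approx(5 * 5 / 20)

    def test_equals_one_sided_fisher(self):
        """ORA's hypergeometric upper tail equals the one-sided Fisher p on
        the equivalent 2x2 table."""
        rng = np.random.default_rng(6)
        background = [f"g{i}" for i in range(60)]
        for _ in range(20):
            hits = list(rng.choice(background, 15, replace=False))
            members = list(rng.choice(background, 12, replace=False))
            out = ora_hypergeometric(hits, background, {"s": members})
            a = len(set(hits) & set(members))
            tab = [
                [a, len(hits) - a],
                [len(members) - a, 60 - len(hits) - len(members) + a],
            ]
            _, p = stats.fisher_exact(tab, alternative="greater")
            assert out.loc["s", "p"] == pytest.approx(p, rel=1e-9)

    def test_hits_outside_background_rejected(self):
        with pytest.raises(EnrichmentError):
            ora_hypergeometric(["x"], ["a"], {"s": ["a"]})

    def test_empty_background_rejected(self):
        with pytest.raises(EnrichmentError):
            ora_hypergeometric([], [], {"s": ["a"]})


class TestFisher:
    def test_independence_table(self):
        res = fisher_from_table(np.array([[5, 5], [5, 5]]))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_documented_example(self):
        res = fisher_from_table(np.array([[10, 90], [20, 880]]))
        assert res.odds_ratio == pytest.approx(4.888, abs=1e-3)
        expected = fisher_two_sided_enumeration([[10, 90], [20, 880]])
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_two_sided_p_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            table = rng.integers(0, 31, size=(2, 2))
            res = fisher_from_table(table)
            expected = fisher_two_sided_enumeration(table.tolist())
            assert res.p == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            t = rng.integers(0, 20, size=(2, 2))
            a = fisher_from_table(t)
            b = fisher_from_table(t[::-1, ::-1])
            assert a.p == pytest.approx(b.p, rel=1e-12)
            assert a.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-12)

    def test_zero_cell_uses_haldane_correction(self):
        res = fisher_from_table(np.array([[0, 10], [5, 5]]))
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            t = rng.integers(1, 40, size=(2, 2))
            res = fisher_from_table(t)
            assert res.ci_low < res.odds_ratio < res.ci_high

    def test_risk_list_outside_background_rejected(self):
        with pytest.raises(EnrichmentError):
            risk_enrichment_fisher(["a"], ["zzz"], ["a", "b"])

    def test_risk_enrichment_builds_correct_table(self):
        background = [f"g{i}" for i in range(100)]
        query = background[:20]
        risk = background[10:40]
        res = risk_enrichment_fisher(query, risk, background, list_name="huge")
        assert res.table.tolist() == [[10, 10], [20, 60]]
        assert res.list_name == "huge"
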