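import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathassoc import (
    NullPoolCache,
    PathwayDB,
    PhenotypeGeneSet,
    compute_dp,
    empirical_pvalue,
    exact_pooled_tail,
    run_enrichment,
    sample_null_pool,
)
from tests.conftest import make_db


def gene_set(label, genes, db, n_snps=None):
    return PhenotypeGeneSet.from_genes(
        label, genes, db, n_snps=n_snps or len(genes), sample_size=1000
    )


# ---------------------------------------------------------------------------
# observed counts


def test_compute_dp_counts_intersections(toy_db):
    gs = gene_set("p", {"g1", "g2"}, toy_db)
    dp = compute_dp(gs, toy_db)
    assert dp == {"P1": 2, "P2": 0}


def test_compute_dp_reports_every_pathway_including_zeros(disjoint_db):
    dp = compute_dp({"g0", "g1"}, disjoint_db)  # both in P1
    assert set(dp) == set(disjoint_db.pathway_ids)
    assert dp["P1"] == 2 and all(dp[p] == 0 for p in dp if p != "P1")


def test_compute_dp_rejects_genes_outside_universe(toy_db):
    with pytest.raises(ValueError, match="outside the pathway universe"):
        compute_dp({"g1", "nope"}, toy_db)


# ---------------------------------------------------------------------------
# exact pooled tail (closed form vs enumeration)


def test_exact_tail_at_zero_is_one(toy_db):
    assert exact_pooled_tail(0, 3, toy_db) == 1.0


def test_exact_tail_toy_value_matches_enumeration(toy_db):
    # enumerate all C(8,2)=28 gene pairs and count, per pathway, pairs fully
    # inside it; the pooled tail is the average over pathways
    genes = sorted(toy_db.universe)
    hits = {pid: 0 for pid in toy_db.pathway_ids}
    n_pairs = 0
    for pair in itertools.combinations(genes, 2):
        n_pairs += 1
        for pid in toy_db.pathway_ids:
            if set(pair) <= toy_db.genes_of(pid):
                hits[pid] += 1
    expected = sum(h / n_pairs for h in hits.values()) / toy_db.P
    assert expected == pytest.approx(21 / 56)
    assert exact_pooled_tail(2, 2, toy_db) == pytest.approx(expected)


def test_exact_tail_forced_cases():
    whole = PathwayDB({"P1": ("all", {f"g{i}" for i in range(6)})})
    assert exact_pooled_tail(4, 4, whole) == pytest.approx(1.0)
    assert exact_pooled_tail(5, 4, whole) == 0.0  # k > G convention


@given(
    sizes=st.lists(st.integers(2, 8), min_size=2, max_size=5),
    G=st.integers(1, 6),
)
@settings(max_examples=100, deadline=None)
def test_exact_tail_monotone_in_dp_and_g(sizes, G):
    db = make_db(sizes)
    G = min(G, db.N)
    tails = [exact_pooled_tail(k, G, db) for k in range(0, G + 1)]
    assert all(a >= b for a, b in zip(tails, tails[1:]))
    if G + 1 <= db.N:
        for k in range(1, G + 1):
            assert exact_pooled_tail(k, G + 1, db) >= exact_pooled_tail(k, G, db)


# ---------------------------------------------------------------------------
# null pool sampling


def test_pool_forced_scores_single_pathway_universe():
    whole = PathwayDB({"P1": ("all", {f"g{i}" for i in range(7)})})
    pool = sample_null_pool(3, whole, reps=50, seed=0)
    assert (pool.scores == 3).all()
    pool_full = sample_null_pool(7, whole, reps=10, seed=0)
    assert (pool_full.scores == 7).all()


def test_pool_invariants_and_reproducibility(toy_db):
    pool = sample_null_pool(2, toy_db, reps=500, seed=3)
    assert pool.size == 500 * toy_db.P
    assert pool.scores.min() >= 0 and pool.scores.max() <= 2
    again = sample_null_pool(2, toy_db, reps=500, seed=3)
    assert np.array_equal(pool.counts, again.counts)
    other = sample_null_pool(2, toy_db, reps=500, seed=4)
    assert not np.array_equal(pool.counts, other.counts)


def test_pool_rejects_bad_draw_size(toy_db):
    with pytest.raises(ValueError):
        sample_null_pool(0, toy_db, reps=10, seed=0)
    with pytest.raises(ValueError):
        sample_null_pool(toy_db.N + 1, toy_db, reps=10, seed=0)


def test_sampler_matches_exact_tail_on_random_toy_db():
    db = make_db([3, 5, 4])
    G = 3
    pool = sample_null_pool(G, db, reps=30000, seed=11)
    for k in range(0, G + 1):
        p = exact_pooled_tail(k, G, db)
        phat = (pool.scores >= k).mean()
        se = np.sqrt(max(p * (1 - p), 1e-12) / pool.size)
        assert abs(phat - p) <= max(4 * se, 1e-9), (k, p, phat)


# ---------------------------------------------------------------------------
# empirical p-values


def test_empirical_pvalue_examples(toy_db):
    from pathassoc import NullScorePool

    pool = sample_null_pool(2, toy_db, reps=100, seed=0)
    assert empirical_pvalue(0, pool) == 1.0

    fixed = NullScorePool(
        G=2, reps=5, seed=0, counts=np.array([[0], [0], [0], [1], [2]])
    )  # pooled scores [0, 0, 0, 1, 2]
    assert empirical_pvalue(2, fixed) == pytest.approx(0.2)
    assert empirical_pvalue(3, fixed) == 0.0
    assert empirical_pvalue(3, fixed, smoothed=True) > 0.0


def test_pvalue_monotone_in_dp(toy_db):
    pool = sample_null_pool(2, toy_db, reps=2000, seed=5)
    ps = [empirical_pvalue(k, pool) for k in range(0, 4)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# run_enrichment


def test_min_dp_blocks_single_gene_hits(disjoint_db):
    gs = gene_set("p", {"g0", "g4"}, disjoint_db)  # one gene in P1, one in P2
    results = run_enrichment([gs], disjoint_db, reps=200, seed=0, min_dp=2)
    assert all(not r.significant for r in results)
    assert all(r.dp <= 1 for r in results)


def test_phenotype_filling_small_pathway_is_significant():
    # one tiny pathway inside a large sparse database
    db = make_db([3] + [30] * 6)
    gs = gene_set("p", {"g0", "g1", "g2"}, db)
    assert exact_pooled_tail(3, 3, db) < 0.05  # detectable by the oracle
    results = run_enrichment([gs], db, reps=2000, seed=1)
    by_path = {r.pathway_id: r for r in results}
    assert by_path["P1"].significant


def test_identical_g_and_dp_share_pvalue(disjoint_db):
    # pooled null is pathway-agnostic: same (G, dp) -> same p, any pathway
    a = gene_set("a", {"g0", "g1", "g2"}, disjoint_db)  # 3 genes in P1
    b = gene_set("b", {"g10", "g11", "g12"}, disjoint_db)  # 3 genes in P3
    cache = NullPoolCache(disjoint_db, reps=1000, seed=7)
    results = run_enrichment([a, b], disjoint_db, cache=cache, seed=7)
    p_by = {(r.phenotype_label, r.pathway_id): r.p_emp for r in results}
    assert p_by[("a", "P1")] == p_by[("b", "P3")]


def test_run_enrichment_deterministic(disjoint_db):
    gs = gene_set("p", {"g0", "g1", "g4", "g5"}, disjoint_db)
    r1 = run_enrichment([gs], disjoint_db, reps=500, seed=9)
    r2 = run_enrichment([gs], disjoint_db, reps=500, seed=9)
    assert r1 == r2


def test_untestable_gene_sets_skipped(disjoint_db):
    small = gene_set("tiny", {"g0"}, disjoint_db)
    results = run_enrichment([small], disjoint_db, reps=100, seed=0)
    assert results == []


def test_per_pathway_variant_runs(disjoint_db):
    gs = gene_set("p", {"g0", "g1", "g2"}, disjoint_db)
    pooled = run_enrichment([gs], disjoint_db, reps=1000, seed=2)
    conditional = run_enrichment([gs], disjoint_db, reps=1000, seed=2, per_pathway=True)
    # same observed counts, possibly different p-values
    assert [r.dp for r in pooled] == [r.dp for r in conditional]
    assert all(0.0 <= r.p_emp <= 1.0 for r in conditional)


def test_null_calibration_of_pair_pvalues(disjoint_db):
    # uniform random gene sets: fraction of pairs with p <= alpha stays at or
    # below alpha (discreteness makes the pooled test conservative)
    rng = np.random.default_rng(21)
    genes = sorted(disjoint_db.universe)
    sets = [
        gene_set(f"n{i}", rng.choice(genes, size=5, replace=False), disjoint_db)
        for i in range(60)
    ]
    cache = NullPoolCache(disjoint_db, reps=1000, seed=22)
    results = run_enrichment(sets, disjoint_db, cache=cache, seed=22, alpha=0.05)
    frac = np.mean([r.p_emp <= 0.05 for r in results])
    n = len(results)
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
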