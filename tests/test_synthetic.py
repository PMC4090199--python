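import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from pathassoc import (
    GeneAnnotation,
    SyntheticSpec,
    associations_from_frame,
    build_phenotype_gene_sets,
    exact_pooled_tail,
    expected_pairwise_intersection,
    generate_catalog,
    generate_pathway_db,
)


def test_zero_overlap_makes_disjoint_pathways():
    spec = SyntheticSpec(n_pathways=6, pathway_size_range=(5, 9), overlap_fraction=0.0, seed=1)
    db, _ = generate_pathway_db(spec)
    assert db.N == int(db.sizes.sum())
    all_genes = [g for pid in db.pathway_ids for g in db.genes_of(pid)]
    assert len(all_genes) == len(set(all_genes))


def test_single_pathway_universe():
    spec = SyntheticSpec(n_pathways=1, pathway_size_range=(8, 8), overlap_fraction=0.0, seed=2)
    db, _ = generate_pathway_db(spec)
    assert db.universe == db.genes_of(db.pathway_ids[0])


def test_intervals_cover_universe_and_do_not_overlap():
    spec = SyntheticSpec(seed=3)
    db, ivs = generate_pathway_db(spec)
    assert {iv.symbol for iv in ivs} == set(db.universe)
    by_chrom = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def test_pairwise_overlap_matches_hypergeometric_expectation():
    # with fixed sizes the intersection of two pathways is exactly
    # Hypergeom(pool, k, k); compare the realized mean Jaccard to the
    # closed-form expectation E[ |A∩B| / (2s - |A∩B|) ]
    spec = SyntheticSpec(
        n_pathways=12, pathway_size_range=(20, 20), overlap_fraction=0.5, seed=4
    )
    pool = spec.shared_pool_size
    k = round(0.5 * 20)
    xs = np.arange(0, k + 1)
    pmf = hypergeom.pmf(xs, pool, k, k)
    expected_jaccard = float(np.sum(pmf * xs / (40 - xs)))
    assert expected_pairwise_intersection(spec, 20, 20) == pytest.approx(
        float(np.sum(pmf * xs))
    )
    jaccards = []
    for rep in range(30):
        db, _ = generate_pathway_db(
            SyntheticSpec(
                n_pathways=12, pathway_size_range=(20, 20),
                overlap_fraction=0.5, seed=100 + rep,
            )
        )
        sets = [db.genes_of(pid) for pid in db.pathway_ids]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                jaccards.append(inter / (len(sets[i] | sets[j])))
    jaccards = np.array(jaccards)
    se = jaccards.std(ddof=1) / math.sqrt(len(jaccards))
    # pairs within one database share the pool, so they are correlated;
    # widen the naive band accordingly
    assert abs(jaccards.mean() - expected_jaccard) <= 6 * se


def test_infeasible_overlap_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(overlap_fraction=1.5)


def test_generation_is_deterministic():
    spec = SyntheticSpec(seed=5)
    db1, ivs1 = generate_pathway_db(spec)
    db2, ivs2 = generate_pathway_db(spec)
    assert db1 == db2 and ivs1 == ivs2
    c1 = generate_catalog(spec, db1, ivs1)
    c2 = generate_catalog(spec, db2, ivs2)
    for a, b in zip(c1, c2):
        assert a.to_csv(index=False) == b.to_csv(index=False)


def test_coordinate_mapping_recovers_generated_genes_exactly():
    # intervals are non-overlapping and SNPs intragenic, so coordinate-mode
    # mapping must return exactly the genes the generator chose
    spec = SyntheticSpec(n_phenotypes_null=10, n_phenotypes_planted=5, seed=6)
    db, ivs = generate_pathway_db(spec)
    catalog, truth, _ = generate_catalog(spec, db, ivs)
    gene_sets = build_phenotype_gene_sets(
        associations_from_frame(catalog), GeneAnnotation(ivs), db, mode="coordinate"
    )
    chosen = catalog.groupby("phenotype")["reported_genes"].agg(set)
    for gs in gene_sets:
        assert gs.all_genes == frozenset(chosen[gs.phenotype_label])
    # reported mode agrees, since the generator fills the gene column
    reported = build_phenotype_gene_sets(
        associations_from_frame(catalog), None, db, mode="reported"
    )
    assert reported == gene_sets


def test_full_signal_phenotype_draws_only_causal_genes():
    spec = SyntheticSpec(
        n_phenotypes_null=0, n_phenotypes_planted=3, signal_fraction=1.0, seed=7
    )
    db, ivs = generate_pathway_db(spec)
    catalog, truth, _ = generate_catalog(spec, db, ivs)
    for phen, causal in zip(truth.phenotype, truth.causal_pathway):
        genes = set(catalog.loc[catalog.phenotype == phen, "reported_genes"])
        assert genes <= set(db.genes_of(causal))


def test_ground_truth_marks_null_phenotypes():
    spec = SyntheticSpec(n_phenotypes_null=4, n_phenotypes_planted=2, seed=8)
    db, ivs = generate_pathway_db(spec)
    _, truth, cats = generate_catalog(spec, db, ivs)
    nulls = truth[truth.phenotype.str.startswith("null")]
    assert (nulls.causal_pathway == "").all()
    planted = truth[truth.phenotype.str.startswith("planted")]
    assert (planted.causal_pathway != "").all()
    assert set(cats.category) == {"background", "planted"}


def test_planted_signal_is_detectable_by_the_oracle():
    # detectability precondition for recovery: at the default study
    # condition the expected causal count has a pooled tail below alpha
    spec = SyntheticSpec(seed=9)
    db, _ = generate_pathway_db(spec)
    G = int(np.mean(spec.genes_per_phenotype_range))
    expected_dp = int(spec.signal_fraction * G)  # ~8 causal genes
    assert exact_pooled_tail(expected_dp, G, db) < 0.05


def test_messy_mode_adds_intergenic_snps():
    spec = SyntheticSpec(n_phenotypes_null=3, n_phenotypes_planted=0, messy=True, seed=10)
    db, ivs = generate_pathway_db(spec)
    catalog, _, _ = generate_catalog(spec, db, ivs)
    blanks = catalog[catalog.reported_genes == ""]
    assert len(blanks) == 3
    # intergenic SNPs sit outside every gene interval
    ann = GeneAnnotation(ivs)
    for row in blanks.itertuples(index=False):
        assert ann.genes_containing(row.chrom, row.pos) == set()


def test_all_catalog_pvalues_below_threshold():
    spec = SyntheticSpec(n_phenotypes_null=5, n_phenotypes_planted=0, seed=11)
    db, ivs = generate_pathway_db(spec)
    catalog, _, _ = generate_catalog(spec, db, ivs)
    assert (catalog.pvalue <= 1e-5).all()
    assert (catalog.pvalue >= 1e-12).all()
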