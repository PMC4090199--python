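"""Synthetic pathway databases, gene annotations and GWAS-style catalogs.

Every pipeline stage is exercisable without external downloads: the
generator builds a pathway database of configurable size and overlap, lays
each gene on a synthetic chromosome as a non-overlapping interval, and emits
a catalog of phenotype-SNP rows whose phenotypes are either null (genes
scattered uniformly over the universe) or planted (genes drawn
preferentially from one designated causal pathway).  A ground-truth sidecar
records each phenotype's causal pathway, so recovery can be scored exactly.

Overlap model
-------------
With ``overlap_fraction`` o > 0 a shared gene pool of size
``S = round(2 * o * max_size)`` is created; a pathway of size s takes
``round(o * s)`` members from the pool (uniformly, without replacement) and
the rest as private genes.  Pathway pairs therefore intersect only through
the pool, and for fixed sizes the intersection is exactly hypergeometric:
|A ∩ B| ~ Hypergeom(S, k_a, k_b) with k = round(o * s) — which gives a
closed-form check on the realized overlap.  o = 0 yields disjoint pathways.

SNPs are placed inside their gene's interval and association p-values are
sampled log-uniformly in [1e-12, 1e-5]; the pipeline only thresholds these,
never models them.  Study sizes follow a linear link from the phenotype's
gene count plus Gaussian noise, so the subjects~genes correlation has a
known expectation.

The default configuration is the package's reference study condition: a
20-pathway database of sizes 10-15 with 20% overlap (~200 genes), 50 null
and 20 planted phenotypes of 8-12 genes each, and planted phenotypes drawing
each gene from their causal pathway with probability 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneInterval, PathwayDB

# Interval layout on synthetic chromosomes: fixed-length genes with gaps so
# intragenic SNPs map back unambiguously and intergenic ones exercise the
# window logic.
_GENES_PER_CHROM = 500
_GENE_LEN = 1000
_GENE_PITCH = 3000

_DB_STREAM = 11
_CATALOG_STREAM = 13


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study."""

    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 15)
    overlap_fraction: float = 0.2
    n_phenotypes_null: int = 50
    n_phenotypes_planted: int = 20
    genes_per_phenotype_range: tuple[int, int] = (8, 12)
    signal_fraction: float = 0.8
    snps_per_gene: int = 1
    sample_size_intercept: float = 2000.0
    sample_size_slope: float = 300.0
    sample_size_sigma: float = 500.0
    planted_categories: tuple[str, ...] = ("planted",)
    null_category: str = "background"
    messy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid pathway size range {self.pathway_size_range}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must be in [0, 1]")
        glo, ghi = self.genes_per_phenotype_range
        if not (1 <= glo <= ghi):
            raise ValueError(
                f"invalid genes-per-phenotype range {self.genes_per_phenotype_range}"
            )
        if self.n_phenotypes_null < 0 or self.n_phenotypes_planted < 0:
            raise ValueError("phenotype counts must be non-negative")
        if self.snps_per_gene < 1:
            raise ValueError("snps_per_gene must be >= 1")
        if self.overlap_fraction > 0:
            smax = self.pathway_size_range[1]
            pool = int(round(2 * self.overlap_fraction * smax))
            kmax = int(round(self.overlap_fraction * smax))
            if kmax > max(pool, 0):
                raise ValueError(
                    "infeasible overlap/size combination: shared draw exceeds pool"
                )

    @property
    def shared_pool_size(self) -> int:
        if self.overlap_fraction == 0:
            return 0
        return max(1, int(round(2 * self.overlap_fraction * self.pathway_size_range[1])))


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _interval_for(index: int) -> GeneInterval:
    chrom = f"chr{1 + index // _GENES_PER_CHROM}"
    start = (index % _GENES_PER_CHROM) * _GENE_PITCH
    return GeneInterval(_gene_name(index), chrom, start, start + _GENE_LEN, "+")


def generate_pathway_db(spec: SyntheticSpec) -> tuple[PathwayDB, list[GeneInterval]]:
    """Build the pathway database and a non-overlapping gene annotation.

    Pathway sizes are sampled uniformly from ``pathway_size_range``; the
    overlap model is described in the module docstring.  Every universe gene
    gets one interval on a synthetic chromosome.  Deterministic for a fixed
    spec (seeded by ``spec.seed``).
    """
    rng = np.random.default_rng([spec.seed, _DB_STREAM])
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    pool_size = spec.shared_pool_size
    counter = pool_size  # shared-pool genes occupy indices [0, pool_size)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for p, s in enumerate(sizes):
        s = int(s)
        k = int(round(spec.overlap_fraction * s)) if pool_size else 0
        k = min(k, s, pool_size)
        shared = rng.choice(pool_size, size=k, replace=False) if k else np.array([], int)
        members = {_gene_name(int(i)) for i in shared}
        for _ in range(s - k):
            members.add(_gene_name(counter))
            counter += 1
        pid = f"SP{p + 1:03d}"
        pathways[pid] = (f"synthetic pathway {p + 1}", frozenset(members))
    db = PathwayDB(pathways)
    # Pool genes never drawn by any pathway stay out of the universe and get
    # no interval; index only genes the universe contains.
    name_to_index = {}
    for idx in range(counter):
        name = _gene_name(idx)
        if name in db.universe:
            name_to_index[name] = idx
    intervals = [_interval_for(name_to_index[g]) for g in sorted(db.universe)]
    return db, intervals


def expected_pairwise_intersection(spec: SyntheticSpec, size_a: int, size_b: int) -> float:
    """Closed-form expected |A ∩ B| for two pathways of the given sizes."""
    if spec.overlap_fraction == 0:
        return 0.0
    s = spec.shared_pool_size
    ka = min(int(round(spec.overlap_fraction * size_a)), size_a, s)
    kb = min(int(round(spec.overlap_fraction * size_b)), size_b, s)
    return ka * kb / s


def generate_catalog(
    spec: SyntheticSpec,
    db: PathwayDB,
    annotation: Sequence[GeneInterval],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (catalog, ground truth, categories) for the spec's phenotypes.

    Null phenotypes draw their genes uniformly without replacement from the
    universe.  Planted phenotypes draw each gene from their causal pathway
    with probability ``signal_fraction`` (deduplicated), the remainder
    uniformly from the rest of the universe; the causal pathway is chosen
    uniformly among the largest pathways in the database.  Each chosen gene
    emits ``snps_per_gene`` SNPs inside its interval; ``messy=True`` adds one
    intergenic SNP per phenotype to exercise nearest-gene mapping.

    Returns plain DataFrames with the canonical catalog column names; the
    ground truth has one row per phenotype (causal pathway empty for nulls).
    """
    rng = np.random.default_rng([spec.seed, _CATALOG_STREAM])
    by_symbol = {iv.symbol: iv for iv in annotation}
    universe = sorted(db.universe)
    max_size = int(db.sizes.max())
    causal_candidates = [
        pid for pid in db.pathway_ids if len(db.genes_of(pid)) == max_size
    ]
    glo, ghi = spec.genes_per_phenotype_range

    catalog_rows: list[dict] = []
    truth_rows: list[dict] = []
    category_rows: list[dict] = []
    snp_counter = 0

    def emit_snp(label: str, gene: str, pvalue: float, sample_size: int, study: str):
        nonlocal snp_counter
        iv = by_symbol[gene]
        pos = int(rng.integers(iv.start, iv.end))
        snp_counter += 1
        catalog_rows.append(
            {
                "phenotype": label,
                "snp": f"rs{snp_counter:06d}",
                "chrom": iv.chrom,
                "pos": pos,
                "pvalue": pvalue,
                "reported_genes": gene,
                "sample_size": sample_size,
                "study": study,
            }
        )

    def phenotype_block(label: str, planted: bool, category: str) -> None:
        nonlocal snp_counter
        n = int(rng.integers(glo, ghi + 1))
        causal = ""
        if planted:
            causal = str(rng.choice(causal_candidates))
            members = sorted(db.genes_of(causal))
            n_causal = min(int(rng.binomial(n, spec.signal_fraction)), len(members), n)
            chosen = list(rng.choice(members, size=n_causal, replace=False))
            rest_pool = sorted(set(universe) - set(chosen))
            chosen += list(rng.choice(rest_pool, size=n - n_causal, replace=False))
        else:
            chosen = list(rng.choice(universe, size=n, replace=False))
        sample_size = max(
            50,
            int(round(
                spec.sample_size_intercept
                + spec.sample_size_slope * n
                + rng.normal(0.0, spec.sample_size_sigma)
            )),
        )
        study = f"study_{label}"
        for gene in chosen:
            for _ in range(spec.snps_per_gene):
                pvalue = float(10.0 ** rng.uniform(-12.0, -5.0))
                emit_snp(label, gene, pvalue, sample_size, study)
        if spec.messy:
            # one intergenic SNP in the gap downstream of the first gene
            iv = by_symbol[chosen[0]]
            snp_counter += 1
            catalog_rows.append(
                {
                    "phenotype": label,
                    "snp": f"rs{snp_counter:06d}",
                    "chrom": iv.chrom,
                    "pos": iv.end + int(rng.integers(1, _GENE_PITCH - _GENE_LEN)),
                    "pvalue": float(10.0 ** rng.uniform(-12.0, -5.0)),
                    "reported_genes": "",
                    "sample_size": sample_size,
                    "study": study,
                }
            )
        truth_rows.append(
            {
                "phenotype": label,
                "causal_pathway": causal,
                "n_genes": n,
                "sample_size": sample_size,
            }
        )
        category_rows.append({"phenotype": label, "category": category})

    for i in range(spec.n_phenotypes_null):
        phenotype_block(f"null_{i + 1:03d}", planted=False, category=spec.null_category)
    for i in range(spec.n_phenotypes_planted):
        cat = spec.planted_categories[i % len(spec.planted_categories)]
        phenotype_block(f"planted_{i + 1:03d}", planted=True, category=cat)

    catalog = pd.DataFrame(
        catalog_rows,
        columns=["phenotype", "snp", "chrom", "pos", "pvalue",
                 "reported_genes", "sample_size", "study"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["phenotype", "causal_pathway", "n_genes", "sample_size"]
    )
    cats = pd.DataFrame(category_rows, columns=["phenotype", "category"])
    return catalog, truth, cats
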