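"""Aggregate views over enrichment results.

Three summaries mirror the standard questions asked of a phenotype-pathway
screen: which categories of phenotypes cluster into pathways (and how that
depends on how many SNPs a phenotype has), whether categories reuse the same
pathways or each hit their own, and how study size, gene count and pathway
count correlate across phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .enrichment import EnrichmentResult
from .io import CategoryMap
from .mapping import PhenotypeGeneSet

#: Default SNP-count bin edges -> bins [2-4], [5-9], [10-19], [>=20].
DEFAULT_SNP_BINS = (2, 5, 10, 20)


@dataclass(frozen=True)
class CategorySummary:
    category: str
    n_phenotypes: int
    n_with_any_significant: int
    fraction: float
    n_associations: int
    n_unique_pathways: int


@dataclass(frozen=True)
class BinSummary:
    bin_label: str
    lo: int
    hi: int | None  # None = open-ended top bin
    n_phenotypes: int
    n_with_any_significant: int
    fraction: float


@dataclass(frozen=True)
class CorrelationReport:
    pair: str
    pearson_r: float | None
    p_value: float | None
    n: int
    note: str = ""


def _sig_by_phenotype(results: Sequence[EnrichmentResult]) -> dict[str, set[str]]:
    sig: dict[str, set[str]] = {}
    for r in results:
        if r.significant:
            sig.setdefault(r.phenotype_label, set()).add(r.pathway_id)
    return sig


def category_fractions(
    results: Sequence[EnrichmentResult],
    gene_sets: Sequence[PhenotypeGeneSet],
    categories: CategoryMap,
    snp_bins: Sequence[int] = DEFAULT_SNP_BINS,
) -> tuple[list[CategorySummary], list[BinSummary]]:
    """Per-category and per-SNP-count-bin clustering tendencies.

    For each category: how many phenotypes, how many with at least one
    significant pathway, the total number of associations, and the number of
    unique pathways behind them (a category re-hitting the same pathways has
    far fewer unique pathways than associations).  For each SNP-count bin:
    the fraction of phenotypes with any significant pathway.

    ``snp_bins`` are left edges; the last bin is open-ended.  Bins must
    cover the observed SNP-count range of the phenotypes passed in.
    """
    edges = list(snp_bins)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("snp_bins must be strictly increasing")
    sig = _sig_by_phenotype(results)
    n_assoc: dict[str, int] = {}
    uniq: dict[str, set[str]] = {}
    for r in results:
        if r.significant:
            cat = categories.category_of(r.phenotype_label)
            n_assoc[cat] = n_assoc.get(cat, 0) + 1
            uniq.setdefault(cat, set()).add(r.pathway_id)

    by_cat: dict[str, list[PhenotypeGeneSet]] = {}
    for gs in gene_sets:
        by_cat.setdefault(categories.category_of(gs.phenotype_label), []).append(gs)
    cat_out = []
    for cat in sorted(set(by_cat) | set(n_assoc)):
        members = by_cat.get(cat, [])
        hits = sum(1 for gs in members if sig.get(gs.phenotype_label))
        cat_out.append(
            CategorySummary(
                category=cat,
                n_phenotypes=len(members),
                n_with_any_significant=hits,
                fraction=hits / len(members) if members else 0.0,
                n_associations=n_assoc.get(cat, 0),
                n_unique_pathways=len(uniq.get(cat, set())),
            )
        )

    bin_out = []
    counts = [gs.n_snps for gs in gene_sets]
    if counts and min(counts) < edges[0]:
        raise ValueError(
            f"snp_bins start at {edges[0]} but a phenotype has {min(counts)} SNPs"
        )
    for b, lo in enumerate(edges):
        hi = edges[b + 1] - 1 if b + 1 < len(edges) else None
        members = [
            gs for gs in gene_sets
            if gs.n_snps >= lo and (hi is None or gs.n_snps <= hi)
        ]
        hits = sum(1 for gs in members if sig.get(gs.phenotype_label))
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        bin_out.append(
            BinSummary(
                bin_label=label, lo=lo, hi=hi,
                n_phenotypes=len(members),
                n_with_any_significant=hits,
                fraction=hits / len(members) if members else 0.0,
            )
        )
    return cat_out, bin_out


def correlation_table(
    gene_sets: Sequence[PhenotypeGeneSet],
    results: Sequence[EnrichmentResult],
    log_transform: bool = False,
) -> list[CorrelationReport]:
    """Pearson correlations across phenotypes between study size (subjects),
    gene count G, and number of significantly associated pathways.

    Raw counts by default; ``log_transform`` applies log10 to strictly
    positive variables (counts get +1) for exploration.  Phenotypes without
    a defined sample size are dropped; fewer than 3 remaining is an error.
    Zero variance in a variable makes r undefined — reported as missing with
    the reason rather than silently skipped.
    """
    sig = _sig_by_phenotype(results)
    rows = [gs for gs in gene_sets if gs.sample_size is not None]
    if len(rows) < 3:
        raise ValueError(f"need >= 3 phenotypes with sample sizes, got {len(rows)}")
    subjects = np.array([gs.sample_size for gs in rows], dtype=float)
    genes = np.array([gs.G for gs in rows], dtype=float)
    pathways = np.array(
        [len(sig.get(gs.phenotype_label, ())) for gs in rows], dtype=float
    )
    if log_transform:
        subjects = np.log10(subjects)
        genes = np.log10(genes + 1.0)
        pathways = np.log10(pathways + 1.0)
    out = []
    for name, x, y in (
        ("subjects~pathways", subjects, pathways),
        ("subjects~genes", subjects, genes),
        ("genes~pathways", genes, pathways),
    ):
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            which = "x" if np.std(x) == 0.0 else "y"
            out.append(
                CorrelationReport(
                    pair=name, pearson_r=None, p_value=None, n=len(rows),
                    note=f"zero variance in {name.split('~')[0 if which == 'x' else 1]}",
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = pearsonr(x, y)
        out.append(
            CorrelationReport(pair=name, pearson_r=float(r), p_value=float(p), n=len(rows))
        )
    return out
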