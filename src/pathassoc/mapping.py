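"""SNP-to-gene mapping and per-phenotype gene sets.

A phenotype gene is the gene in which, or near which, a phenotype-associated
SNP falls.  Two mapping modes are supported:

``reported``
    Trust the catalog's curated gene column.  Intergenic placeholders of the
    form ``"GENE1 - GENE2"`` are split and both flanking genes kept (or
    dropped, configurable); tokens like ``NR``/``intergenic`` are discarded.

``coordinate``
    Locate the SNP in a gene annotation: all genes whose interval contains
    the position, else the single nearest gene within ``window`` base pairs,
    else nothing.  Equidistant flanks are resolved deterministically to the
    lexicographically smaller symbol.

Distances are gap sizes under 0-based half-open coordinates: a SNP at
position p left of an interval [s, e) is s - p away, right of it p - e.

The per-phenotype gene set deduplicates genes across SNPs (several SNPs in
one gene count once) and restricts to the pathway universe; the size of the
restricted set, G, is the draw size of the resampling null.  A phenotype is
testable only if at least two distinct genes were mapped — clustering of a
single gene into a pathway is not evidence of anything.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GeneInterval, PathwayDB, SnpAssociation

_PLACEHOLDER_SPLIT = re.compile(r"\s+-\s+")
_NULL_TOKENS = {"", "nr", "intergenic", "none", "na"}


class GeneAnnotation:
    """Chromosome-indexed view of a gene annotation for point queries."""

    def __init__(self, intervals: Iterable[GeneInterval]):
        self.intervals = list(intervals)
        seen: set[str] = set()
        for iv in self.intervals:
            if iv.symbol in seen:
                raise ValueError(f"duplicate gene symbol {iv.symbol!r} in annotation")
            seen.add(iv.symbol)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end, iv.symbol))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            symbols = np.array([iv.symbol for iv in ivs], dtype=object)
            self._by_chrom[chrom] = (starts, ends, symbols)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def by_symbol(self) -> dict[str, GeneInterval]:
        return {iv.symbol: iv for iv in self.intervals}

    def _distances(self, chrom: str, pos: int):
        starts, ends, symbols = self._by_chrom[chrom]
        d = np.where(pos < starts, starts - pos, np.where(pos >= ends, pos - ends, 0))
        return d, symbols

    def genes_containing(self, chrom: str, pos: int) -> set[str]:
        if chrom not in self._by_chrom:
            return set()
        starts, ends, symbols = self._by_chrom[chrom]
        # strict containment: a SNP at an interval's (exclusive) end is
        # adjacent (distance 0), not inside
        return set(symbols[(starts <= pos) & (pos < ends)])

    def nearest_gene(self, chrom: str, pos: int, window: int) -> str | None:
        """Nearest gene within ``window`` bp (ties -> lexicographically
        smallest symbol); ``None`` if nothing is that close."""
        if chrom not in self._by_chrom:
            return None
        d, symbols = self._distances(chrom, pos)
        dmin = int(d.min())
        if dmin > window:
            return None
        return min(symbols[d == dmin])


def map_snp_to_genes(
    snp: SnpAssociation,
    annotation: GeneAnnotation | None = None,
    window: int = 20000,
    mode: str = "coordinate",
    split_placeholders: bool = True,
) -> set[str]:
    """Genes assigned to one SNP under the chosen mapping mode.

    Coordinate mode returns every gene whose interval contains the SNP; if
    none does, the single nearest gene within ``window`` bp; else the empty
    set (the SNP contributes no phenotype gene).  An unknown chromosome
    yields the empty set with a warning.
    """
    if mode == "reported":
        out: set[str] = set()
        for token in snp.reported_genes:
            token = token.strip()
            if _PLACEHOLDER_SPLIT.search(token):
                if split_placeholders:
                    out.update(
                        t for t in _PLACEHOLDER_SPLIT.split(token)
                        if t.strip().casefold() not in _NULL_TOKENS
                    )
                continue
            if token.casefold() in _NULL_TOKENS:
                continue
            out.add(token)
        return out
    if mode != "coordinate":
        raise ValueError(f"unknown mapping mode {mode!r}")
    if annotation is None:
        raise ValueError("coordinate mode requires a gene annotation")
    if window < 0:
        raise ValueError(f"negative window {window}")
    if snp.chrom not in annotation.chromosomes:
        warnings.warn(
            f"chromosome {snp.chrom!r} absent from annotation (SNP {snp.snp_id})",
            stacklevel=2,
        )
        return set()
    contained = annotation.genes_containing(snp.chrom, snp.pos)
    if contained:
        return contained
    nearest = annotation.nearest_gene(snp.chrom, snp.pos, window)
    return {nearest} if nearest is not None else set()


@dataclass(frozen=True)
class PhenotypeGeneSet:
    """A phenotype's deduplicated mapped genes and their pathway-universe
    restriction.  ``G`` (= ``len(universe_genes)``) is the resampling draw
    size for the null."""

    phenotype_label: str
    all_genes: frozenset[str]
    universe_genes: frozenset[str]
    G: int
    n_snps: int
    sample_size: int | None
    testable: bool

    def __post_init__(self) -> None:
        if not self.universe_genes <= self.all_genes:
            raise ValueError("universe_genes must be a subset of all_genes")
        if self.G != len(self.universe_genes):
            raise ValueError("G must equal |universe_genes|")

    @classmethod
    def from_genes(
        cls,
        phenotype_label: str,
        all_genes: Iterable[str],
        db: PathwayDB,
        n_snps: int,
        sample_size: int | None = None,
        min_genes: int = 2,
    ) -> "PhenotypeGeneSet":
        all_set = frozenset(all_genes)
        uni = frozenset(all_set & db.universe)
        return cls(
            phenotype_label=phenotype_label,
            all_genes=all_set,
            universe_genes=uni,
            G=len(uni),
            n_snps=n_snps,
            sample_size=sample_size,
            testable=len(all_set) >= min_genes,
        )


def gene_sets_to_frame(gene_sets: Sequence[PhenotypeGeneSet]):
    import pandas as pd

    return pd.DataFrame(
        {
            "phenotype": [gs.phenotype_label for gs in gene_sets],
            "n_snps": [gs.n_snps for gs in gene_sets],
            "sample_size": [
                -1 if gs.sample_size is None else gs.sample_size for gs in gene_sets
            ],
            "n_genes": [len(gs.all_genes) for gs in gene_sets],
            "G": [gs.G for gs in gene_sets],
            "testable": [gs.testable for gs in gene_sets],
            "all_genes": [";".join(sorted(gs.all_genes)) for gs in gene_sets],
            "universe_genes": [";".join(sorted(gs.universe_genes)) for gs in gene_sets],
        }
    )


def gene_sets_from_frame(df) -> list[PhenotypeGeneSet]:
    out = []
    for row in df.itertuples(index=False):
        all_genes = frozenset(
            g for g in str(row.all_genes).split(";") if g and g != "nan"
        )
        uni = frozenset(
            g for g in str(row.universe_genes).split(";") if g and g != "nan"
        )
        out.append(
            PhenotypeGeneSet(
                phenotype_label=str(row.phenotype),
                all_genes=all_genes,
                universe_genes=uni,
                G=len(uni),
                n_snps=int(row.n_snps),
                sample_size=None if int(row.sample_size) < 0 else int(row.sample_size),
                testable=bool(row.testable),
            )
        )
    return out


def write_gene_sets(gene_sets: Sequence[PhenotypeGeneSet], path, params=None) -> None:
    from .io import write_tsv

    write_tsv(gene_sets_to_frame(gene_sets), path, params=params)


def read_gene_sets(path) -> list[PhenotypeGeneSet]:
    import pandas as pd

    return gene_sets_from_frame(pd.read_csv(path, sep="\t", comment="#"))


def build_phenotype_gene_sets(
    associations: Sequence[SnpAssociation],
    annotation: GeneAnnotation | None,
    db: PathwayDB,
    window: int = 20000,
    mode: str = "coordinate",
    sample_size_agg: str = "sum",
    min_genes: int = 2,
    split_placeholders: bool = True,
) -> list[PhenotypeGeneSet]:
    """Aggregate threshold-filtered, label-normalized associations into one
    gene set per phenotype (first-appearance order).

    A phenotype's sample size is aggregated over its distinct source studies
    (``sum`` over all studies, or ``max``); rows without a study identifier
    are grouped by their reported size, so repeated SNP rows from one study
    are not double-counted.  Phenotypes with fewer than ``min_genes`` mapped
    genes are flagged untestable but retained, so reports can account for
    every phenotype seen.
    """
    if sample_size_agg not in ("sum", "max"):
        raise ValueError(f"sample_size_agg must be 'sum' or 'max', got {sample_size_agg!r}")
    order: list[str] = []
    genes_by_phen: dict[str, set[str]] = {}
    snps_by_phen: dict[str, set[str]] = {}
    studies_by_phen: dict[str, dict[str, int]] = {}
    for snp in associations:
        label = snp.phenotype_label
        if label not in genes_by_phen:
            order.append(label)
            genes_by_phen[label] = set()
            snps_by_phen[label] = set()
            studies_by_phen[label] = {}
        genes_by_phen[label] |= map_snp_to_genes(
            snp, annotation, window=window, mode=mode,
            split_placeholders=split_placeholders,
        )
        snps_by_phen[label].add(snp.snp_id)
        if snp.sample_size is not None:
            key = snp.study if snp.study is not None else f"size:{snp.sample_size}"
            studies_by_phen[label].setdefault(key, snp.sample_size)
    out: list[PhenotypeGeneSet] = []
    for label in order:
        sizes = studies_by_phen[label]
        if sizes:
            total = sum(sizes.values()) if sample_size_agg == "sum" else max(sizes.values())
        else:
            total = None
        out.append(
            PhenotypeGeneSet.from_genes(
                label,
                genes_by_phen[label],
                db,
                n_snps=len(snps_by_phen[label]),
                sample_size=total,
                min_genes=min_genes,
            )
        )
    return out
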