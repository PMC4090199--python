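"""Readers and writers for the catalog-level formats the pipeline touches.

The pipeline consumes four external inputs: a GWAS-catalog-style association
table (TSV), gene intervals (BED, 0-based half-open), pathway gene sets (GMT)
and a phenotype -> category map (TSV).  Everything is parsed into small typed
containers; writers emit TSV with a ``#``-prefixed provenance header (tool
version plus the parameters of the run) so results can be traced without a
side channel.

Phenotype labels are normalized on read (trim, case-fold, collapse internal
whitespace) so that differently-spelled catalog entries of the same trait
merge into one phenotype; an optional synonym map can merge labels further.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

#: Catalog inclusion threshold: entries associate with their phenotype at
#: p < 1e-5, and rows above this are dropped on read.
CATALOG_PVALUE_THRESHOLD = 1e-5

#: Logical field -> default column name in the association table.  A config
#: may remap any of these to match a particular catalog dialect.
DEFAULT_COLUMNS = {
    "phenotype": "phenotype",
    "snp": "snp",
    "chrom": "chrom",
    "pos": "pos",
    "pvalue": "pvalue",
    "genes": "reported_genes",
    "sample_size": "sample_size",
    "study": "study",
}

_MANDATORY = ("phenotype", "snp", "chrom", "pos", "pvalue")
_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """An input file violates its format contract."""


def normalize_label(label: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonical form of a phenotype label: trimmed, case-folded, internal
    whitespace collapsed, then optionally mapped through a synonym table.

    Idempotent: normalizing an already-normalized label is the identity
    (synonym maps are expected to map normalized aliases to normalized
    canonical labels; this is enforced by applying normalization to the
    synonym lookup result as well).
    """
    s = _WS.sub(" ", str(label).strip()).casefold()
    if synonyms:
        s = _WS.sub(" ", synonyms.get(s, s).strip()).casefold()
    return s


@dataclass(frozen=True)
class SnpAssociation:
    """One catalog row: a SNP associated with a phenotype in some study."""

    phenotype_label: str
    snp_id: str
    chrom: str
    pos: int
    assoc_pvalue: float
    reported_genes: tuple[str, ...] = ()
    sample_size: int | None = None
    study: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative SNP position {self.pos}")
        if not (0.0 < self.assoc_pvalue <= 1.0):
            raise ValueError(f"association p-value {self.assoc_pvalue} outside (0, 1]")
        if not self.phenotype_label:
            raise ValueError("empty phenotype label")


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic footprint, 0-based half-open."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.symbol}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


class PathwayDB:
    """Named gene sets plus their gene universe.

    The universe is the exact union of all member sets; ``N`` is its size and
    ``P`` the number of pathways.  Pathway order follows insertion (file
    order for GMT input); genes are indexed in sorted order so the membership
    matrix is reproducible.
    """

    def __init__(self, pathways: Mapping[str, tuple[str, Iterable[str]]]):
        self._pathways: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (name, genes) in pathways.items():
            gset = frozenset(genes)
            if not gset:
                raise FormatError(f"pathway {pid!r} is empty")
            self._pathways[pid] = (name, gset)
        if not self._pathways:
            raise FormatError("pathway database contains no pathways")
        self.universe: frozenset[str] = frozenset().union(
            *(g for _, g in self._pathways.values())
        )
        self.pathway_ids: list[str] = list(self._pathways)
        self._genes: list[str] = sorted(self.universe)
        self._gene_index: dict[str, int] = {g: i for i, g in enumerate(self._genes)}
        self._membership: np.ndarray | None = None

    @property
    def P(self) -> int:
        return len(self._pathways)

    @property
    def N(self) -> int:
        return len(self.universe)

    @property
    def sizes(self) -> np.ndarray:
        """Pathway sizes, aligned with ``pathway_ids``."""
        return np.array([len(self._pathways[p][1]) for p in self.pathway_ids])

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self._pathways[pathway_id][1]

    def name_of(self, pathway_id: str) -> str:
        return self._pathways[pathway_id][0]

    def membership(self) -> np.ndarray:
        """(N, P) uint8 gene-by-pathway incidence matrix, cached."""
        if self._membership is None:
            m = np.zeros((self.N, self.P), dtype=np.uint8)
            for j, pid in enumerate(self.pathway_ids):
                for g in self._pathways[pid][1]:
                    m[self._gene_index[g], j] = 1
            self._membership = m
        return self._membership

    @property
    def gene_list(self) -> list[str]:
        """Universe genes in index (sorted) order."""
        return list(self._genes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PathwayDB) and self._pathways == other._pathways

    def __repr__(self) -> str:
        return f"PathwayDB(P={self.P}, N={self.N})"

    @classmethod
    def from_gmt(cls, path) -> "PathwayDB":
        """Parse a GMT file: ``id<TAB>description<TAB>gene1<TAB>gene2...``.

        Duplicate genes within one line are deduplicated; a line with fewer
        than three fields or a repeated pathway id is a format error.
        """
        pathways: dict[str, tuple[str, frozenset[str]]] = {}
        for lineno, line in _iter_data_lines(path):
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line has fewer than 3 fields"
                )
            pid, desc = fields[0], fields[1]
            if pid in pathways:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: line {lineno}: pathway {pid!r} has no genes")
            pathways[pid] = (desc, genes)
        return cls(pathways)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in self.pathway_ids:
                name, genes = self._pathways[pid]
                fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


@dataclass
class CategoryMap:
    """Total phenotype -> category mapping with an explicit default.

    Phenotypes absent from the file are assigned the default category (with a
    warning), mirroring the catch-all group for unclassifiable traits.
    """

    mapping: dict[str, str]
    default: str = "other"

    def category_of(self, label: str) -> str:
        key = normalize_label(label)
        if key not in self.mapping:
            warnings.warn(
                f"phenotype {label!r} missing from category map; "
                f"assigned {self.default!r}",
                stacklevel=2,
            )
            return self.default
        return self.mapping[key]


def _iter_data_lines(path):
    """Yield (1-based line number, stripped line) skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_table(
    path,
    pvalue_threshold: float = CATALOG_PVALUE_THRESHOLD,
    columns: Mapping[str, str] | None = None,
    on_bad_rows: str = "fail",
    synonyms: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read a tab-separated association table into :class:`SnpAssociation` rows.

    Rows with ``assoc_pvalue > pvalue_threshold`` are dropped (the catalog
    inclusion rule).  Phenotype labels are normalized so spelling variants of
    one trait merge.  Rows are returned in file order.

    Parameters
    ----------
    columns:
        Overrides for :data:`DEFAULT_COLUMNS` (logical field -> header name).
    on_bad_rows:
        ``"fail"`` (default) raises :class:`FormatError` naming the offending
        line; ``"skip"`` drops the row with a warning.
    """
    if on_bad_rows not in ("fail", "skip"):
        raise ValueError(f"on_bad_rows must be 'fail' or 'skip', got {on_bad_rows!r}")
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    lines = _iter_data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise FormatError(f"{path}: empty file (no header)") from None
    index = {name: i for i, name in enumerate(header.split("\t"))}
    for key in _MANDATORY:
        if cols[key] not in index:
            raise FormatError(
                f"{path}: missing mandatory column {cols[key]!r} (field {key!r})"
            )

    out: list[SnpAssociation] = []
    for lineno, line in lines:
        fields = line.split("\t")

        def get(key: str) -> str | None:
            name = cols.get(key)
            if name is None or name not in index:
                return None
            i = index[name]
            return fields[i] if i < len(fields) else None

        try:
            pos = int(get("pos"))  # type: ignore[arg-type]
            pval = float(get("pvalue"))  # type: ignore[arg-type]
            if pos < 0:
                raise ValueError(f"negative position {pos}")
            if not (0.0 < pval <= 1.0):
                raise ValueError(f"p-value {pval} outside (0, 1]")
            label = normalize_label(get("phenotype") or "", synonyms)
            if not label:
                raise ValueError("empty phenotype label")
        except (TypeError, ValueError) as exc:
            msg = f"{path}: line {lineno}: unparseable row ({exc})"
            if on_bad_rows == "fail":
                raise FormatError(msg) from None
            warnings.warn(msg, stacklevel=2)
            continue
        if pval > pvalue_threshold:
            continue
        genes_raw = get("genes") or ""
        genes = tuple(t.strip() for t in re.split(r"[;,]", genes_raw) if t.strip())
        ss_raw = get("sample_size")
        try:
            sample_size = int(float(ss_raw)) if ss_raw not in (None, "", "NR") else None
        except ValueError:
            sample_size = None
        out.append(
            SnpAssociation(
                phenotype_label=label,
                snp_id=get("snp") or "",
                chrom=get("chrom") or "",
                pos=pos,
                assoc_pvalue=pval,
                reported_genes=genes,
                sample_size=sample_size,
                study=get("study") or None,
            )
        )
    return out


def associations_from_frame(
    df: pd.DataFrame,
    pvalue_threshold: float = CATALOG_PVALUE_THRESHOLD,
    synonyms: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Convert an in-memory catalog DataFrame (canonical column names) to rows.

    Applies the same threshold filter and label normalization as
    :func:`read_association_table`; useful when the catalog was generated
    programmatically rather than read from disk.
    """
    out = []
    for row in df.itertuples(index=False):
        pval = float(row.pvalue)
        if pval > pvalue_threshold:
            continue
        genes_raw = str(getattr(row, "reported_genes", "") or "")
        genes = tuple(t.strip() for t in re.split(r"[;,]", genes_raw) if t.strip())
        ss = getattr(row, "sample_size", None)
        out.append(
            SnpAssociation(
                phenotype_label=normalize_label(row.phenotype, synonyms),
                snp_id=str(row.snp),
                chrom=str(row.chrom),
                pos=int(row.pos),
                assoc_pvalue=pval,
                reported_genes=genes,
                sample_size=None if ss is None or pd.isna(ss) else int(ss),
                study=str(getattr(row, "study", "") or "") or None,
            )
        )
    return out


def read_gene_intervals(path, one_based: bool = False) -> list[GeneInterval]:
    """Read gene intervals from BED (chrom, start, end, name[, score, strand]).

    ``one_based=True`` converts 1-based inclusive starts to the internal
    0-based half-open convention on read.  Duplicate gene symbols are an
    error: the annotation must identify each gene once.
    """
    intervals: list[GeneInterval] = []
    seen: set[str] = set()
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}: line {lineno}: BED line has fewer than 4 fields")
        chrom, start_s, end_s, name = fields[:4]
        strand = fields[5] if len(fields) > 5 else "."
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
        if one_based:
            start -= 1
        if name in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate gene symbol {name!r}")
        seen.add(name)
        try:
            intervals.append(GeneInterval(name, chrom, start, end, strand))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_gene_intervals(intervals: Sequence[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.symbol}\t0\t{iv.strand}\n")


def read_category_map(path, default: str = "other") -> CategoryMap:
    """Read a two-column TSV ``phenotype<TAB>category`` (optional header)."""
    mapping: dict[str, str] = {}
    first = True
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        if first and fields[1].strip().casefold() == "category":
            first = False
            continue  # header
        first = False
        mapping[normalize_label(fields[0])] = fields[1].strip()
    return CategoryMap(mapping, default=default)


def write_category_map(categories: CategoryMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("phenotype\tcategory\n")
        for label in sorted(categories.mapping):
            fh.write(f"{label}\t{categories.mapping[label]}\n")


def read_synonym_map(path) -> dict[str, str]:
    """Two-column TSV ``alias<TAB>canonical``; both sides are normalized."""
    mapping: dict[str, str] = {}
    first = True
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        if first and fields[1].strip().casefold() == "canonical":
            first = False
            continue
        first = False
        mapping[normalize_label(fields[0])] = normalize_label(fields[1])
    return mapping


# ---------------------------------------------------------------------------
# Generic TSV writing with provenance header


def write_tsv(df: pd.DataFrame, path, params: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with a ``#`` provenance header (version +
    sorted key=value parameters).  Contains no timestamps so identical runs
    produce byte-identical files."""
    with open(path, "w") as fh:
        fh.write(f"# pathassoc {__version__}\n")
        for key in sorted(params or {}):
            fh.write(f"# {key}={params[key]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
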