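"""Phenotype-phenotype networks from shared significant pathways.

Two phenotypes are linked when at least one pathway is significantly
associated with both; the link weight is the number of shared pathways.
The unipartite network can be thresholded on weight (threshold 1 gives the
full link set, 3 the conservative preset used for the tight autoimmune-style
core), and the phenotype-pathway bipartite graph of significant associations
is exportable alongside it.  Category annotations are attached to nodes for
styling only — the construction itself is unsupervised.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult
from .io import CategoryMap, write_tsv


@dataclass(frozen=True)
class PhenotypeLink:
    """Unordered phenotype pair sharing significant pathways."""

    phenotype_a: str
    phenotype_b: str
    shared_pathways: frozenset[str]

    def __post_init__(self) -> None:
        if self.phenotype_a == self.phenotype_b:
            raise ValueError("self-links are not allowed")
        if self.phenotype_a > self.phenotype_b:
            raise ValueError("pair must be in canonical (sorted) order")
        if not self.shared_pathways:
            raise ValueError("a link requires at least one shared pathway")

    @property
    def weight(self) -> int:
        return len(self.shared_pathways)


@dataclass(frozen=True)
class PhenotypeNetwork:
    """Thresholded unipartite network plus its connected components."""

    links: tuple[PhenotypeLink, ...]
    threshold: int
    graph: nx.Graph
    components: tuple[frozenset[str], ...]
    isolated: tuple[str, ...]


def _significant_pathways(results: Sequence[EnrichmentResult]) -> dict[str, set[str]]:
    sig: dict[str, set[str]] = {}
    for r in results:
        if r.significant:
            sig.setdefault(r.phenotype_label, set()).add(r.pathway_id)
    return sig


def build_links(results: Sequence[EnrichmentResult]) -> list[PhenotypeLink]:
    """One link per unordered phenotype pair with >= 1 shared significant
    pathway, pairs in canonical (sorted label) order."""
    sig = _significant_pathways(results)
    links: list[PhenotypeLink] = []
    for a, b in combinations(sorted(sig), 2):
        shared = sig[a] & sig[b]
        if shared:
            links.append(PhenotypeLink(a, b, frozenset(shared)))
    return links


def filter_network(
    links: Sequence[PhenotypeLink],
    threshold: int = 1,
    categories: CategoryMap | None = None,
) -> PhenotypeNetwork:
    """Retain links with weight >= threshold and report connected components
    (largest first).  Phenotypes that carried links but lost all of them to
    the threshold are listed as isolated."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    kept = tuple(l for l in links if l.weight >= threshold)
    graph = nx.Graph()
    for link in kept:
        graph.add_edge(
            link.phenotype_a,
            link.phenotype_b,
            weight=link.weight,
            shared_pathways=";".join(sorted(link.shared_pathways)),
        )
    if categories is not None:
        for node in graph.nodes:
            graph.nodes[node]["category"] = categories.category_of(node)
    components = tuple(
        sorted(
            (frozenset(c) for c in nx.connected_components(graph)),
            key=lambda c: (-len(c), min(c)),
        )
    )
    all_endpoints = {l.phenotype_a for l in links} | {l.phenotype_b for l in links}
    isolated = tuple(sorted(all_endpoints - set(graph.nodes)))
    return PhenotypeNetwork(
        links=kept, threshold=threshold, graph=graph,
        components=components, isolated=isolated,
    )


def export_bipartite(
    results: Sequence[EnrichmentResult],
    categories: CategoryMap | None = None,
) -> nx.Graph:
    """Bipartite graph of significant phenotype-pathway associations
    (phenotypes on side 0, pathways on side 1)."""
    graph = nx.Graph()
    for r in sorted(
        (r for r in results if r.significant),
        key=lambda r: (r.phenotype_label, r.pathway_id),
    ):
        if r.phenotype_label not in graph:
            graph.add_node(r.phenotype_label, bipartite=0, kind="phenotype")
            if categories is not None:
                graph.nodes[r.phenotype_label]["category"] = categories.category_of(
                    r.phenotype_label
                )
        if r.pathway_id not in graph:
            graph.add_node(
                r.pathway_id, bipartite=1, kind="pathway", name=r.pathway_name
            )
        graph.add_edge(r.phenotype_label, r.pathway_id, dp=r.dp, p_emp=r.p_emp)
    return graph


# ---------------------------------------------------------------------------
# TSV round trips


def links_to_frame(links: Sequence[PhenotypeLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phenotype_a": [l.phenotype_a for l in links],
            "phenotype_b": [l.phenotype_b for l in links],
            "weight": [l.weight for l in links],
            "shared_pathways": [";".join(sorted(l.shared_pathways)) for l in links],
        }
    )


def links_from_frame(df: pd.DataFrame) -> list[PhenotypeLink]:
    return [
        PhenotypeLink(
            str(row.phenotype_a),
            str(row.phenotype_b),
            frozenset(str(row.shared_pathways).split(";")),
        )
        for row in df.itertuples(index=False)
    ]


def write_edge_list(links: Sequence[PhenotypeLink], path, params=None) -> None:
    write_tsv(links_to_frame(links), path, params=params)


def read_edge_list(path) -> list[PhenotypeLink]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return links_from_frame(df)


def write_bipartite_tsv(results: Sequence[EnrichmentResult], path, params=None) -> None:
    rows = sorted(
        (r for r in results if r.significant),
        key=lambda r: (r.phenotype_label, r.pathway_id),
    )
    df = pd.DataFrame(
        {
            "phenotype": [r.phenotype_label for r in rows],
            "pathway_id": [r.pathway_id for r in rows],
            "dp": [r.dp for r in rows],
            "p_emp": [r.p_emp for r in rows],
        }
    )
    write_tsv(df, path, params=params)
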