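"""Pathway-clustering scores and their pooled resampling null.

For phenotype i and pathway j the association score ``DP_ij`` is the number
of phenotype genes inside pathway j.  Its null distribution is built by
drawing G genes (G = the phenotype's universe-restricted gene count)
uniformly without replacement from the pathway universe, counting the draw's
hits in every pathway, and repeating; all ``reps x P`` counts are pooled into
one multiset of expected random scores.  The empirical p-value of an
observed count is the fraction of pooled scores at least as large.

Because the pool aggregates over pathways, the p-value is a function of
``(G, DP)`` only — two phenotypes with the same gene-set size and the same
observed count get identical p-values regardless of which pathway is
involved.  A per-pathway conditional null (comparing ``DP_j`` only against
pathway j's own replicate counts) is available as a documented variant.

``exact_pooled_tail`` gives the closed form of the pooled tail: the pooled
marginal is the uniform mixture over pathways of hypergeometric counts,

    Pr[S >= k] = (1/P) * sum_j Pr[X_j >= k],   X_j ~ Hypergeom(N, m_j, G),

which serves as an analytic cross-check for the sampler.

Significance additionally requires ``DP >= min_dp`` (default 2): genes are
considered clustered into a pathway only when at least two distinct genes
fall in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import PathwayDB
from .mapping import PhenotypeGeneSet

# Fixed stream labels keeping the pool / pseudo-draw RNGs on disjoint
# deterministic streams for one master seed.
_POOL_STREAM = 1009
_PSEUDO_STREAM = 104729

_CHUNK = 4096


def compute_dp(genes: PhenotypeGeneSet | Iterable[str], db: PathwayDB) -> dict[str, int]:
    """Observed count per pathway: |universe genes of the phenotype ∩ pathway|.

    Every pathway appears in the output, zeros included.  Genes outside the
    universe violate the precondition and raise.
    """
    if isinstance(genes, PhenotypeGeneSet):
        gset = set(genes.universe_genes)
    else:
        gset = set(genes)
    if not gset <= db.universe:
        bad = sorted(gset - db.universe)[:5]
        raise ValueError(f"genes outside the pathway universe: {bad}")
    return {pid: len(gset & db.genes_of(pid)) for pid in db.pathway_ids}


def exact_pooled_tail(k: int, G: int, db: PathwayDB) -> float:
    """Closed-form pooled tail probability Pr[pooled score >= k] for draw
    size G: the uniform mixture over pathways of hypergeometric tails.

    ``k <= 0`` returns 1; ``k > G`` returns 0 by convention.
    """
    if G < 1 or G > db.N:
        raise ValueError(f"G={G} outside [1, N={db.N}]")
    if k <= 0:
        return 1.0
    if k > G:
        return 0.0
    tails = hypergeom.sf(k - 1, db.N, db.sizes, G)
    return float(np.mean(tails))


def _entropy(seed) -> list[int]:
    if isinstance(seed, (int, np.integer)):
        return [int(seed)]
    return [int(s) for s in seed]


def _random_count_matrix(rng: np.random.Generator, membership: np.ndarray,
                         G: int, n: int) -> np.ndarray:
    """(n, P) pathway-hit counts for n independent uniform draws of G
    distinct genes.  Chunked so memory stays bounded at any n."""
    N, P = membership.shape
    out = np.empty((n, P), dtype=np.int32)
    if G == N:
        out[:] = membership.sum(axis=0, dtype=np.int32)
        return out
    m16 = membership.astype(np.int32)
    for s in range(0, n, _CHUNK):
        e = min(n, s + _CHUNK)
        u = rng.random((e - s, N))
        idx = np.argpartition(u, G, axis=1)[:, :G]
        out[s:e] = m16[idx].sum(axis=1)
    return out


@dataclass
class NullScorePool:
    """Pooled null scores for one draw size G.

    ``counts`` holds the per-replicate, per-pathway hit counts (reps x P);
    the pooled view flattens them into one multiset of reps*P scores.
    """

    G: int
    reps: int
    seed: int | tuple[int, ...]
    counts: np.ndarray
    _tail: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        flat = self.counts.ravel()
        cnt = np.bincount(flat, minlength=self.G + 2)
        # _tail[k] = number of pooled scores >= k; index G+1 is always 0.
        self._tail = cnt[::-1].cumsum()[::-1]

    @property
    def scores(self) -> np.ndarray:
        """The pooled multiset (reps * P scores)."""
        return self.counts.ravel()

    @property
    def size(self) -> int:
        return self.counts.size

    def pvalues(self, dp, smoothed: bool = False) -> np.ndarray:
        """Vectorized pooled empirical p-values for observed counts ``dp``."""
        k = np.clip(np.asarray(dp, dtype=np.int64), 0, self.G + 1)
        t = self._tail[k].astype(float)
        if smoothed:
            return (t + 1.0) / (self.size + 1.0)
        return t / self.size

    def pvalue(self, dp: int, smoothed: bool = False) -> float:
        return float(self.pvalues(np.array([dp]), smoothed=smoothed)[0])

    def pathway_pvalue(self, dp: int, j: int, smoothed: bool = False) -> float:
        """Conditional variant: compare dp against pathway j's own replicate
        counts instead of the pooled multiset."""
        hits = int((self.counts[:, j] >= dp).sum())
        if smoothed:
            return (hits + 1.0) / (self.reps + 1.0)
        return hits / self.reps

    def histogram(self) -> np.ndarray:
        """Pooled score frequencies (index = score, value = fraction)."""
        cnt = np.bincount(self.scores, minlength=self.G + 1)
        return cnt / self.size


def sample_null_pool(G: int, db: PathwayDB, reps: int,
                     seed: int | Sequence[int] = 0) -> NullScorePool:
    """Draw the pooled null for draw size G.

    Each replicate samples G distinct genes uniformly from the universe and
    contributes one count per pathway.  The pool depends only on
    ``(G, db, seed)`` and is bit-reproducible for a fixed seed.
    """
    if not (0 < G <= db.N):
        raise ValueError(f"G={G} outside [1, N={db.N}]")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(_entropy(seed) + [_POOL_STREAM, G])
    counts = _random_count_matrix(rng, db.membership(), G, reps)
    return NullScorePool(G=G, reps=reps, seed=tuple(_entropy(seed)), counts=counts)


def empirical_pvalue(dp: int, pool: NullScorePool, smoothed: bool = False) -> float:
    """Fraction of pooled null scores >= dp (optionally (c+1)/(n+1) smoothed,
    which never reports exactly zero)."""
    return pool.pvalue(dp, smoothed=smoothed)


class NullPoolCache:
    """Per-G cache of null pools for one (db, reps, seed) configuration.

    The pooled null depends only on the draw size, so phenotypes sharing a G
    share a pool; recomputing per phenotype would sample the identical
    distribution again.
    """

    def __init__(self, db: PathwayDB, reps: int, seed: int | Sequence[int] = 0):
        self.db = db
        self.reps = reps
        self.seed = seed
        self._pools: dict[int, NullScorePool] = {}

    def get(self, G: int) -> NullScorePool:
        if G not in self._pools:
            self._pools[G] = sample_null_pool(G, self.db, self.reps, seed=self.seed)
        return self._pools[G]


@dataclass(frozen=True)
class EnrichmentResult:
    """Scored association between one phenotype and one pathway."""

    phenotype_label: str
    pathway_id: str
    pathway_name: str
    dp: int
    p_emp: float
    significant: bool
    pool_reps: int
    G: int


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "phenotype": [r.phenotype_label for r in results],
            "pathway_id": [r.pathway_id for r in results],
            "pathway_name": [r.pathway_name for r in results],
            "dp": [r.dp for r in results],
            "p_emp": [r.p_emp for r in results],
            "significant": [r.significant for r in results],
            "pool_reps": [r.pool_reps for r in results],
            "G": [r.G for r in results],
        }
    )


def results_from_frame(df) -> list[EnrichmentResult]:
    return [
        EnrichmentResult(
            phenotype_label=str(row.phenotype),
            pathway_id=str(row.pathway_id),
            pathway_name=str(row.pathway_name),
            dp=int(row.dp),
            p_emp=float(row.p_emp),
            significant=bool(row.significant),
            pool_reps=int(row.pool_reps),
            G=int(row.G),
        )
        for row in df.itertuples(index=False)
    ]


def write_results_table(results: Sequence[EnrichmentResult], path, params=None) -> None:
    from .io import write_tsv

    write_tsv(results_to_frame(results), path, params=params)


def read_results_table(path) -> list[EnrichmentResult]:
    import pandas as pd

    return results_from_frame(pd.read_csv(path, sep="\t", comment="#"))


def run_enrichment(
    gene_sets: Sequence[PhenotypeGeneSet],
    db: PathwayDB,
    reps: int = 1000,
    alpha: float = 0.05,
    min_dp: int = 2,
    seed: int | Sequence[int] = 0,
    cache: NullPoolCache | None = None,
    smoothed: bool = False,
    per_pathway: bool = False,
    min_g: int = 2,
) -> list[EnrichmentResult]:
    """Score every (phenotype, pathway) pair against the resampling null.

    An association is significant iff ``p_emp <= alpha`` and ``dp >= min_dp``.
    Phenotypes with ``G < min_g`` are skipped (untestable for scoring).
    Results come out one row per pair, phenotypes in input order, pathways in
    database order; identical seed and inputs give identical tables.
    """
    if cache is None:
        cache = NullPoolCache(db, reps=reps, seed=seed)
    pids = db.pathway_ids
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        if gs.G < max(min_g, 1):
            continue
        pool = cache.get(gs.G)
        dp_map = compute_dp(gs, db)
        dps = np.array([dp_map[p] for p in pids], dtype=np.int64)
        if per_pathway:
            pv = np.array([
                pool.pathway_pvalue(int(dps[j]), j, smoothed=smoothed)
                for j in range(len(pids))
            ])
        else:
            pv = pool.pvalues(dps, smoothed=smoothed)
        sig = (pv <= alpha) & (dps >= min_dp)
        for j, pid in enumerate(pids):
            results.append(
                EnrichmentResult(
                    phenotype_label=gs.phenotype_label,
                    pathway_id=pid,
                    pathway_name=db.name_of(pid),
                    dp=int(dps[j]),
                    p_emp=float(pv[j]),
                    significant=bool(sig[j]),
                    pool_reps=pool.reps,
                    G=gs.G,
                )
            )
    return results
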