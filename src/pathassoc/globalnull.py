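"""Nested pseudo-phenotype simulation: the pipeline-wide multiple-testing null.

Running hundreds of phenotypes against hundreds of pathways at alpha = 0.05
is guaranteed to produce some significant calls by chance.  Rather than
adjusting individual p-values, the whole significance procedure is rerun on
pseudo phenotypes: for each real phenotype a random gene set of the same
size G is drawn from the universe, scored against every pathway, and
assessed with the same resampling null; the number of significant pseudo
associations, summed over phenotypes, is one replicate of the global null
total.  Repeating this gives the distribution of the total expected under
the hypothesis that no phenotype's genes cluster anywhere, and the observed
total is located within it (z-score and resampling p-value).

By default the inner null pools are reused from the per-G cache across outer
replicates; ``fresh_inner=True`` redraws them per replicate, the literal
nested procedure, at ``outer x inner x P`` resampling cost.  Both modes
target the same distribution; the cache introduces a slight coupling between
replicates that the calibration tests bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enrichment import (
    NullPoolCache,
    _PSEUDO_STREAM,
    _entropy,
    _random_count_matrix,
    sample_null_pool,
)
from .io import PathwayDB


@dataclass(frozen=True)
class GlobalNullReplicate:
    """One rerun of the whole procedure on pseudo phenotypes."""

    replicate_index: int
    total_significant: int


@dataclass(frozen=True)
class GlobalNullSummary:
    """Location of the observed total within the global null distribution.

    ``p_global`` counts null totals >= observed; when the observed total
    exceeds every replicate it is reported as 1/outer_reps with
    ``p_is_upper_bound`` set — the resampling resolution is exhausted and the
    true p is below that value.
    """

    observed_total: int
    null_totals: tuple[int, ...]
    null_median: float
    null_mean: float
    null_sd: float
    z: float
    p_global: float
    p_is_upper_bound: bool
    degenerate_null: bool


def simulate_global_null(
    gene_set_sizes: Sequence[int],
    db: PathwayDB,
    outer_reps: int = 200,
    inner_reps: int = 1000,
    alpha: float = 0.05,
    min_dp: int = 2,
    seed: int | Sequence[int] = 0,
    cache: NullPoolCache | None = None,
    fresh_inner: bool = False,
) -> list[GlobalNullReplicate]:
    """Simulate the number of significant associations expected by chance.

    For each outer replicate and each phenotype, a pseudo gene set of that
    phenotype's size G is drawn uniformly from the universe, its per-pathway
    counts are scored against an inner null pool of ``inner_reps``
    replicates, and significant calls (p <= alpha and count >= min_dp) are
    summed across phenotypes.
    """
    if outer_reps < 1 or inner_reps < 1:
        raise ValueError("outer_reps and inner_reps must be >= 1")
    for g in gene_set_sizes:
        if not (1 <= g <= db.N):
            raise ValueError(f"gene-set size {g} outside [1, N={db.N}]")
    if cache is None:
        cache = NullPoolCache(db, reps=inner_reps, seed=seed)
    membership = db.membership()
    totals = np.zeros(outer_reps, dtype=np.int64)
    base = _entropy(seed)
    for i, g in enumerate(gene_set_sizes):
        rng = np.random.default_rng(base + [_PSEUDO_STREAM, i])
        counts = _random_count_matrix(rng, membership, int(g), outer_reps)
        if fresh_inner:
            for r in range(outer_reps):
                pool = sample_null_pool(
                    int(g), db, inner_reps, seed=base + [_PSEUDO_STREAM + 1, i, r]
                )
                pv = pool.pvalues(counts[r])
                totals[r] += int(((pv <= alpha) & (counts[r] >= min_dp)).sum())
        else:
            pool = cache.get(int(g))
            pv = pool.pvalues(counts)
            totals += ((pv <= alpha) & (counts >= min_dp)).sum(axis=1)
    return [
        GlobalNullReplicate(replicate_index=r, total_significant=int(totals[r]))
        for r in range(outer_reps)
    ]


def summarize_global_null(
    observed_total: int,
    replicates: Sequence[GlobalNullReplicate] | Sequence[int],
) -> GlobalNullSummary:
    """Summary statistics of the null totals and the observed total's place
    among them.

    A zero-variance null with a non-matching observed total yields an
    infinite z, flagged via ``degenerate_null``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 null replicates to summarize")
    totals = np.array(
        [r.total_significant if isinstance(r, GlobalNullReplicate) else int(r)
         for r in replicates],
        dtype=np.int64,
    )
    n = len(totals)
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        z = 0.0 if observed_total == mean else math.copysign(
            math.inf, observed_total - mean
        )
    else:
        z = (observed_total - mean) / sd
    ge = int((totals >= observed_total).sum())
    if ge == 0:
        p_global, upper = 1.0 / n, True
    else:
        p_global, upper = ge / n, False
    return GlobalNullSummary(
        observed_total=int(observed_total),
        null_totals=tuple(int(t) for t in totals),
        null_median=float(np.median(totals)),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p_global=p_global,
        p_is_upper_bound=upper,
        degenerate_null=degenerate,
    )
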