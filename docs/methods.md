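# Methods notes

## The model

The pipeline treats a GWAS catalog as a map from phenotypes to gene sets
and asks, per phenotype, whether that gene set concentrates in any pathway
beyond what uniform gene sampling produces.  The unit of evidence is a
gene, not a SNP: multiple SNPs in one gene collapse to one gene, and a
phenotype is testable only when at least two distinct genes were mapped —
repeated perturbations of a single gene say nothing about pathway-level
clustering.  Assumptions worth stating:

- Genes are exchangeable under the null.  The resampling null draws genes
  uniformly from the pathway universe (the union of all pathway member
  sets) without weighting by gene length, SNP density, or LD.  Real GWAS
  hit genes are not uniform in these respects; the synthetic data satisfy
  the assumption by construction, so passing calibration tests here does
  not certify calibration on real catalogs.
- Pathways are fixed, possibly overlapping sets.  Overlap is handled by
  counting a gene in every pathway that contains it, in observed scores and
  null draws alike.
- The pooled null deliberately ignores pathway identity: all `reps × P`
  counts form one reference multiset, so the p-value depends only on the
  draw size G and the observed count DP.  This is the strictest (most
  conservative) variant — large pathways inflate the pooled tail that small
  pathways are judged against.  A per-pathway conditional null
  (`per_pathway=True`, or `per_pathway_null` in the config) is provided as
  the statistically conventional alternative; it conditions each pathway's
  p-value on that pathway's own replicate counts.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `pvalue_threshold` | 1e-5 | catalog inclusion cut for association rows |
| `window` | 20 000 bp | max SNP-to-gene distance in coordinate mode |
| `mapping_mode` | `coordinate` (CLI), `reported` recommended for curated catalogs | gene assignment source |
| `reps` | 1000 | resampling replicates per null pool (pool size = reps × P) |
| `alpha` | 0.05 | per-pair significance level |
| `min_dp` | 2 | minimum genes in a pathway for a significant call |
| `outer_reps` | 200 | pseudo-phenotype replicates of the global null |
| `network_threshold` | 1 | minimum shared pathways per phenotype link (3 = conservative core) |

The mapping window is a declared parameter, not an attempt to reconstruct
any particular catalog's "near a gene" convention; 20 kb is a common
promoter-plus-flank scale.  Sample size per phenotype is the sum over its
distinct source studies (`sample_size_agg: max` switches to the largest
single study); rows without a study identifier are grouped by their
reported size so per-SNP rows from one study are not double-counted.

## Randomness and determinism

All randomness flows from one master seed through fixed stream constants:
null pools use entropy `[seed, 1009, G]`, pseudo-phenotype draws
`[seed, 104729, i]` (i = phenotype index), and the simulate stage
`[seed, 7919, stage]`.  Consequences: pools depend only on (G, database,
seed), so phenotypes sharing a G share a pool (that is also why equal
(G, DP) pairs carry byte-equal p-values); every stage is independently
reproducible; and two runs with one config and seed produce byte-identical
output files (provenance headers carry parameters but no timestamps or
paths).

The per-G pool cache is also reused across outer replicates of the global
null.  `fresh_inner: true` restores the literal nested procedure (a fresh
inner pool per phenotype per replicate) at `outer × inner × P` resampling
cost; both modes target the same distribution and both are covered by
calibration tests.  The cache couples replicates through shared pools —
with the observed data assessed against the same pools, the observed total
behaves exchangeably with the replicates, which is exactly what the
calibration check wants.

## Numerical choices

- Empirical p-values are the raw tail fraction `#{s ≥ dp}/(reps·P)`,
  matching the "within the top α of random scores" rule; p = 0 is possible.
  A `(c+1)/(n+1)` smoothed estimator is available (`smoothed`) when
  downstream consumers cannot tolerate zeros.
- `exact_pooled_tail` computes the pooled tail analytically as the uniform
  mixture of hypergeometric survival functions; it is the oracle against
  which the sampler is tested and is also used to check planted-signal
  detectability before recovery is asserted.
- Nearest-gene distances are gap sizes under 0-based half-open coordinates
  (a SNP at an interval's exclusive end is adjacent at distance 0, not
  inside).  Equidistant flanking genes resolve to the lexicographically
  smaller symbol — reproducibility over an arbitrary coin flip.
- The global-null p-value is never reported as 0: when the observed total
  exceeds every replicate it is reported as `1/outer_reps` with an
  upper-bound flag.
- Degenerate inputs fail loudly: genes outside the universe, G outside
  [1, N], zero-variance correlation inputs (reported as missing with a
  reason), malformed rows (fail-fast by default; `skip_bad_rows` drops them
  with a warning naming the line).

## The synthetic generator

`SyntheticSpec` defaults are the package's reference study condition: 20
pathways of 10–15 genes with overlap fraction 0.2 (≈200-gene universe), 50
null and 20 planted phenotypes of 8–12 genes, planted phenotypes drawing
each gene from their causal pathway with probability 0.8, one SNP per gene,
and study sizes `2000 + 300·n_genes + N(0, 500)` — a moderate, realistic
subjects~genes correlation (≈0.65 population value).  Pathway overlap uses
a shared gene pool of size `2·overlap·max_size`; with fixed sizes the
pairwise intersection is exactly hypergeometric, giving a closed-form
expectation the tests verify.  The causal pathway is drawn among the
largest pathways present so planted signal strength is comparable across
seeds.  Intervals are laid out non-overlapping with intragenic SNPs, so
coordinate mapping must recover the generator's gene choices exactly;
`messy: true` adds intergenic SNPs to exercise the window logic separately.

What the generator does *not* emulate: LD between SNPs, gene-length and
SNP-density biases, genotype-level noise, hierarchically related pathways,
and correlated phenotypes sharing causal genes.  Green tests therefore
demonstrate correctness of the machinery and calibration under
exchangeable-gene sampling, not robustness to those real-data violations.

## Problem sizes in tests and the acceptance script

Statistical tests run at desk scale chosen once: pool reps 10⁵ for the
oracle-equivalence check, 1000 inner replicates and 200 outer replicates
for the global null, 50 repeated experiments for the calibration study, 20
planted phenotypes for recovery.  The whole suite and the acceptance script
each complete in well under a minute on one CPU; larger designs (e.g.
1000 × 1000 nested resampling) only narrow Monte-Carlo error around the
same expectations.

## Known limitations

- The pooled null's conservatism is size-dependent: small pathways are
  harder to call than under a per-pathway null.  This is a property of the
  method, preserved deliberately; use the conditional variant to explore
  the difference.
- Reported-mode mapping inherits whatever curation the catalog applied;
  coordinate mode inherits the annotation and window.  Neither uses LD or
  regulatory evidence.
- Phenotype merging is exact string matching after normalization plus an
  optional synonym map; semantically identical traits with different names
  stay separate unless the synonym map says otherwise.
- Category summaries treat categories as given labels; no ontology
  reasoning is attempted.
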