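# Methods

## The exact two-library test

DGE designs sequence one tag library per condition, so per-gene
replication is absent and differential expression must be assessed from a
single pair of counts. Under the assumption that each gene's tag count is
a small fraction of the library — so counts are Poisson — the probability
of observing count *y* in library 2 given count *x* in library 1, when
the gene is equally expressed, is

    P(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

with N1, N2 the total clean tags of the two libraries. This arises by
placing the flat conjugate prior on the (shared) Poisson rate and
integrating it out; it is the classical Audic–Claverie statistic.

**Numerics.** The point mass is evaluated in log space via `gammaln`, so
counts up to ~10⁷ neither overflow nor lose the leading digits; agreement
with exact rational arithmetic is at the 10⁻¹³ level over the tested
grid. Writing p₀ = N1/(N1+N2), the distribution of y is exactly negative
binomial with r = x+1 successes and success probability p₀, so tail sums
are delegated to `scipy.stats.nbinom.cdf/sf` instead of explicit
summation — equally exact, vectorisable across a whole gene table, and
free of truncation heuristics. Tests verify the tails against an
independent recurrence-based summation oracle.

**Sidedness.** Both up- and down-regulated genes are reported, so the
default p-value is two-sided: 2·min(lower tail, upper tail), capped at 1.
One-sided modes are exposed. Note an asymmetry inherent to the statistic:
the tails are sums of P(k|x), i.e. conditional on the *first* library's
count. The point mass is symmetric in (x, y) when N1 = N2, but the
two-sided p-value is not exactly symmetric under swapping x and y
(p(3,17) = 0.0026 vs p(17,3) = 0.0015 at N1 = N2 = 10⁶): swapping the
roles of the libraries changes what is conditioned on. Callers should
keep a fixed library order, as the pipeline does.

**Calling rule.** p-values are adjusted by Benjamini–Hochberg (step-up,
via statsmodels); a gene is called when q ≤ 0.001 **and** |log₂FC| ≥ 1,
both inclusive. The fold change is computed on TPM with pseudocount 1
(configurable): raw zero counts are common at tag depth and would
otherwise give infinite ratios. With equal library sizes the TPM ratio
equals the count ratio, so the choice of substrate only matters for
unequal depths. Both the fold-change threshold and the pseudocount are
parameters of `call_degs`.

## Tag extraction and cleaning

The catalog tag of a gene is CATG plus the 17 nt immediately 3′ of the
**3′-most** CATG that has at least 17 valid nt downstream. The 3′-most
rule follows the library chemistry: after NlaIII digestion the 3′-most
fragment remains bound to the oligo-dT bead and is the one ligated and
sequenced. Windows containing characters outside A/C/G/T never form tags.
A brute-force scan over all CATG positions serves as the test oracle for
site selection.

Cleaning applies five ordered filters; a read failing several is counted
at the first: (1) trim everything from the first adaptor occurrence on
(the remainder is the tag candidate); (2) drop adaptor-only reads; (3)
drop candidates containing unknown bases; (4) drop candidates that are
not exactly 21 nt; (5) drop tags whose copy number within the library is
exactly one (likely sequencing errors). Step 5 is per library, applied
after steps 1–4. The cleaning report satisfies the exact identity
`input = clean + empty + lowq + length + singleton`, enforced on every
call and fuzzed in tests.

Mapping allows at most one mismatch, best-distance-first: an exact
catalog hit wins over 1-mismatch hits, and at the minimal observed
distance the set of reachable genes must be a singleton — exact hits on
tags shared by two genes, and 1-mismatch ties, are discarded. This
maximises specificity; only sense-strand tags are indexed. Neighbour
lookup enumerates the 63 single-substitution variants against a hash map,
so mapping is linear in the number of distinct tags.

TPM is count / total-mapped × 10⁶. Library similarity is summarised by
Pearson correlation on log₂(TPM+1) by default (raw-count scale
available); the log scale keeps the statistic from being dominated by the
few most abundant tags.

## DEG classification across cohorts

Inputs are threshold-filtered DEG tables (strict q < 0.001 and |log₂FC| >
1 for externally produced microarray-style tables; the DGE path uses the
inclusive thresholds above — both conventions appear in practice and both
are parameters). Duplicate symbols collapse to the minimum-q row.
Cross-species harmonisation defaults to case-folded symbol identity; an
explicit two-column ortholog map may be supplied, and unmapped rows are
dropped with a count.

Classification, per direction d ∈ {up, down}:

* castration-dependent: d(crpc_a) ∩ d(castration) — optionally also
  requiring crpc_b (off by default, mirroring the two-cohort design where
  the first cohort is the primary CRPC contrast);
* CRPC-specific: d(crpc_a) ∩ d(crpc_b) minus **all** castration DEGs of
  either direction — a gene regulated by castration in any direction is
  not castration-independent.

With `require_direction_match=False` membership ignores direction and the
reported direction is crpc_a's. The four output sets are pairwise
disjoint by construction; provenance records the supporting tables per
gene. Venn summaries report the seven inclusion–exclusion regions per
direction.

## Enrichment, network, qPCR

Over-representation uses the hypergeometric upper tail P(X ≥ k) for an
overlap of k between the query (n genes) and a set (K genes) in a
universe of M, BH-adjusted across the collection. The universe is the
union of all set members, intersected with an explicit background when
given — the policy is explicit because results are sensitive to it.
Query genes outside the universe are dropped with a logged count.

Network analysis filters a 3-column scored edge list at combined score
strictly > 0.15 (STRING's low-confidence cutoff), normalises (self-loops
removed, duplicate unordered pairs keep the maximum score, integer 0–999
scores auto-rescaled by 1/1000), and computes degrees on the simple
undirected graph; hubs are nodes with degree strictly > 30. Both
thresholds are parameters with those defaults.

qPCR fold changes use 2^−ΔΔCt with amplification efficiency fixed at 2:
ΔCt = Ct(gene) − Ct(reference) per replicate (gene and reference joined
on replicate id within each group), ΔΔCt = mean ΔCt(treated) − mean
ΔCt(control). Replicate pairing across groups is not assumed — group
means are used, which is the weaker and safer convention. Spread is the
SD of treated-replicate ΔΔCt values around the control mean, reported as
the asymmetric interval 2^−(ΔΔCt ± SD) since the Ct scale is
logarithmic. Invariances (reference self-fold 1, group-shift
cancellation, label-swap reciprocity) are tested. Concordance with a DEG
table is the fraction of shared genes whose fold-change direction matches.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, each with
planted, directly inspectable truth and an explicit seed (no global
random state):

* **Transcriptome** — random A/C/G/T sequences (default 120–400 nt) with
  controlled fractions of genes lacking CATG and of genes sharing their
  canonical tag pairwise; tag uniqueness is enforced at generation.
* **Library pair** — baseline relative abundances log-uniform over four
  orders of magnitude (the wide dynamic range typical of tag data);
  library-2 expectations of the chosen DE genes multiplied by 2^lfc;
  counts per-gene Poisson. Realised totals are recorded as the depths, so
  the conservation invariant holds exactly while the counts stay
  independent Poisson, matching the test's model. An optional floor on
  the expected library-1 count restricts which genes can carry planted
  effects.
* **Raw reads** — each count realised as tag + adaptor fill to 49 bp;
  contaminants (adaptor-only, N-containing, off-length, single-copy
  random tags) injected as binomial fractions of the clean read count,
  with the composition recorded.
* **DEG tables, gene sets, edge lists, Ct tables** — three cohort tables
  with planted shared/specific membership and consistent directions; one
  gene set planted to overlap a query by an exact count; one node planted
  at an exact degree; Ct values with one cycle per doubling and Gaussian
  noise.

Not emulated: realistic Illumina error profiles and quality scores,
positional biases, paired ends, antisense tags, inter-gene sequence
homology beyond exact shared tags, and replicate-level biological
variance (the Poisson model has none). Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to overdispersed real libraries — on real data with biological
replicates a replicate-aware model (e.g. negative-binomial GLMs) is the
appropriate tool, and this package deliberately does not provide one.

A known composition effect is worth noting: planting fold changes on
high-abundance genes inflates the affected library's total, so observed
TPM log-ratios sit slightly below the planted values (visible in the
worked example: ≈1.9 observed for 2.0 planted). This is a property of
per-million normalisation, not an implementation artifact.

## Pipeline and determinism

`run_pipeline` drives the stages in a fixed order from a validated YAML
configuration (validation precedes any work; invalid configs exit with
code 2, stage failures with 3 and a FAILED marker). Sub-seeds are derived
from the single configured seed by fixed offsets. All outputs are plain
text with deterministic serialisation, and the manifest records SHA-256
digests; two runs of the shipped demo configuration produce identical
digests. Demo problem sizes (300 genes, 2×10⁵ tags per library, 20
planted DEGs) were chosen so the full run completes in seconds while
every filter in the chain still has work to do.

## Testing strategy

Operations with closed-form or enumerable answers are checked against
independent oracles that share no code with the implementation: exact
`Fraction` arithmetic for the point probability, a multiplicative
recurrence for tail sums, a quadratic position scan for tag sites,
exhaustive Hamming comparison for mapping, a direct step-up loop for BH,
and `1/C(20,5)` for the enrichment corner case. Statistical behaviour
(type-I control under the global null, planted-truth sensitivity,
uniform-ish null enrichment p-values) is checked by seeded Monte Carlo at
sizes that keep the whole suite under a minute of test time, with bounds
that include the Monte-Carlo margin. Structural identities (cleaning
report reconciliation, TPM conservation, the handshake lemma,
classification disjointness) are fuzzed with seeded generators or
hypothesis in derandomised mode.
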