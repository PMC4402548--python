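# Methods

## The test

Every operation in this package is an over-representation analysis: a query
set and a reference set, both subsets of an explicit universe, compared with
the hypergeometric upper tail

P(X ≥ r) = Σ_{i=r..min(n,R)} C(n,i) C(N−n,R−i) / C(N,R)

with N the universe size, R the query size, n the reference size and r the
overlap. The implementation evaluates every binomial coefficient through
`scipy.special.gammaln` and sums the tail with log-sum-exp, so N in the
tens of thousands (a genome-scale gene universe) neither overflows nor
loses the tail to cancellation. The test is exact, one-sided (enrichment
only; mid-p and two-sided variants are out of scope), and symmetric in R
and n. A p-value that underflows to exactly 0 is clamped to the smallest
positive double so log-scale reporting never yields −inf.

Multiple testing across pathways uses the Benjamini–Hochberg step-up
procedure, implemented directly (sort, multiply p_(k) by m/k, cumulative
minimum from the largest rank, cap at 1) with the correction function kept
injectable. Selection is strict: `fdr < alpha`, default alpha = 0.05.
Pathways whose reference set is empty after intersection with the universe
are dropped *before* correction — they are untestable — and the drop count
is logged so the BH family size is auditable.

## Universe choices

The universe is the single most consequential free parameter of an ORA and
is rarely stated in applied work. The defaults here are:

| strategy | universe |
|---|---|
| 1 (indirect, native) | `annotation`: all pathway genes ∪ all targeted genes (modes `pathways` and `targeted` selectable) |
| 2 (indirect, tailored) | genes targeted by ≥1 miRNA in the database |
| 3 (direct, converted) | miRNAs with ≥1 target in the database |

Query sets are intersected with the universe before testing, which makes
the contingency invariants (r ≤ min(R, n), n ≤ N) true by construction.
Every result table records the universe definition in its metadata. No
minimum-overlap or minimum-pathway-size filter is applied by default: rows
with r = 0 are kept (at p = 1), because the degenerate identities — query
equal to universe forces p = 1 everywhere — are part of the method's
contract and are exercised by the tests.

## Conversion and its contract

A converted pathway is { m : targets(m) ∩ P ≠ ∅ }. The essential property
is that a miRNA is counted **once** per pathway no matter how many member
genes it targets; this is what removes the over-counting that makes the
indirect strategies non-specific. Converted sets are plain sets, so the
contract holds by construction; the tests additionally check the size
bounds and monotonicity under database growth.

## Calibration (negative controls)

`calibrate` draws B signatures of size k uniformly without replacement from
the database's miRNA universe, runs the chosen strategy on each, and counts
per pathway how often `fdr < alpha`. Per-draw RNGs are derived from the
master seed by counter (`SeedSequence(seed, spawn_key=(b,))`), which makes
reports bit-reproducible and — important for paired comparisons — gives two
calibrations with the same master seed identical signature draws. Random
draws are unrestricted (a signature's own miRNAs are not excluded); the
draws are exactly the hypergeometric null of strategy 3, which is why a
well-calibrated direct analysis shows near-zero selection frequencies.
Failed draws (a degenerate signature that raises) are counted and logged,
and B keeps counting attempted draws, so frequencies stay honest fractions
of B. Frequency thresholds 10% and 90% are reported by default.

## Redundancy clustering

Pairwise overlap is the Jaccard index J = |A∩B|/|A∪B|, computed as an exact
ratio of integer counts. "Clusters sharing on average at least 20% of their
members" is operationalized as average-linkage agglomerative clustering on
the distance 1−J with the tree cut at height 1−threshold (default
threshold 0.2 → cut at 0.8); the linkage is delegated to
`scipy.cluster.hierarchy` and is injectable in principle — average linkage
is a recorded choice, not the only defensible one. Pathways are sorted
lexicographically by id before linkage so dendrogram ties resolve
deterministically. Raising the threshold can only split clusters, never
merge them, so the cluster count is non-decreasing in the threshold.
`aggregate_clusters` merges each multi-pathway cluster into the union of
its member sets (singletons pass through), shrinking the BH family to the
cluster count; merging gene pathways and then converting gives the same
sets as converting and then merging, since conversion distributes over
unions.

## The synthetic world

The generator emulates the *structure* of a curated target database
without any download: pathways are uniform random gene subsets, each
(miRNA, gene) pair is an interaction independently with probability
`base_target_prob`, and genes belonging to designated "biased" pathways
have that probability multiplied (once, capped at 1) — knowledge bias
modelled as a property of genes' targeting rates. A master seed drives
three independent streams (pathway construction, interaction sampling,
signal-signature sampling).

Defaults: 2,000 genes, 300 miRNAs, 100 pathways of 20–80 genes,
base_target_prob = 0.01 (a miRNA targets ~20 genes, the scale of
validated-interaction databases), bias multiplier 5 for the 10 designated
pathways when bias is on, signal signatures of 15 miRNAs drawn from the
signal pathway's targeters. At these densities ~95% of genes are targeted
by ≥1 of the 300 miRNAs, so whole-target-list bias scans are nearly
query = universe; the bias-scan tests therefore also use a *sparse* variant
(50 miRNAs, base rate 0.005, ~⅓ of genes targeted) in which the whole-list
scan has room to detect the designated pathways. Both variants are fixed
worlds, chosen once on these grounds.

What the generator does **not** emulate: seed-match thermodynamics, 3′UTR
sequence structure, realistic degree distributions (hub miRNAs/genes),
cross-database identifier noise, or literature-driven *non-uniform* pathway
curation. A green test on synthetic worlds therefore establishes the
statistical mechanics of the strategies — bias propagation, specificity,
signal recovery — not performance against any particular real database.

## Identifiers

miRNA ids are trimmed and case-folded to the lowercase `mir`/`let` stem
("MIR-146A" ≡ "miR-146a" → `mir-146a`); arm suffixes (-5p/-3p) remain
distinct identifiers because the two arms have different target sets; an
optional flag strips species prefixes (`hsa-`). Normalization is
idempotent. Gene ids are opaque strings (symbols or Entrez ids both pass);
cross-namespace mapping is out of scope. Signature ids absent from the
target map are dropped with a logged count rather than erroring, matching
how published signatures shrink when matched against a given database.

## Known limitations

* ORA only — no ranked/weighted (GSEA-style) variant.
* One correction method (BH) in v1, though injectable.
* The indirect strategies' universe defaults are decisions, not community
  standards; results should always be reported with their universe string.
* Calibration cost is B full strategy runs; for large B and strategy 1 on
  big collections this is the dominant cost (it is linear and
  embarrassingly parallel, but runs serially here).
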