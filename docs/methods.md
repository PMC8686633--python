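# Methods

## Problem

Germline structural variants (SVs: deletions, insertions, duplications,
inversions ≥50 bp) called from short-read sequencing are notoriously
irreproducible: the same DNA run through different read mappers, sequenced
at different centers, or even re-sequenced as a technical replicate yields
visibly different call sets. `svfactor` implements an analysis that
decomposes that variability into per-factor contributions using a factorial
study design — a family quartet (two parents, monozygotic twins), each
sample sequenced in triplicate at three centers, each data set mapped four
ways and post-processed two ways (duplicate marking vs base-quality
recalibration), giving 72 call sets per sample and 288 in total — together
with a synthetic generator of such factorials, since the original raw data
are access restricted.

## SV matching and merging

Two records match when they are on the same contig, of the same type, and
both `|Δstart| ≤ d` and `|Δend| ≤ d` with `d = 1000 bp` (measured pairwise
from the beginnings and the ends of the two SVs). Insertions carry
`END = POS`, so for insertion pairs the test degenerates to start distance.
Coordinates are VCF 1-based inclusive everywhere except inside region
filtering, where BED intervals are half-open 0-based.

Merging n call sets builds a graph over all records with edges only between
records of *different* input sets that match; clusters are connected
components (single linkage). Consequences worth knowing:

* two records of one set can share a cluster via a bridging record from
  another set (tested explicitly);
* the partition is invariant to input order up to permutation of support-
  vector bits;
* each cluster's representative is the member with smallest coordinates
  among those from the lowest contributing input index — a deterministic
  choice; the exact rule is not externally mandated, so it is configurable
  behaviour of this package only in the sense that it is documented here.

Each cluster carries `SUPP_VEC`, a bit string with bit i set iff input i
contributed a member, and `SUPP`, the popcount. Merged sets are written as
VCF with those INFO keys (the SURVIVOR output dialect) and round-trip
through the reader.

Two size floors are used, following the two thresholds of the original
protocol: a strict `> 30 bp` floor for intermediate concordance merges and
an inclusive `≥ 50 bp` floor for final/union and truth-comparison merges.
Both are configurable. Matching deliberately ignores `SVLEN` agreement:
distance and type are the published criteria, and adding a length test
would silently drop imprecise calls.

## Stratification

To isolate the variability of one factor, the other three are collapsed in
sequence: for each non-target factor, its level call sets (sharing all
other labels) are merged and only clusters supported by *every* level
survive (full concordance: 2/2 postproc, 3/3 replicates, 3/3 centers,
4/4 mappers); the survivors' representatives feed the next stage. A final
union merge across the target factor's levels (≥ 50 bp floor) partitions
clusters by support level. Clusters supported by exactly one level
("singletons") carry the variability attributable to that level.

The collapse order is fixed per target factor (postproc first, then the
remaining two; see `DEFAULT_STAGE_ORDER`) because single-linkage clustering
is not associative, so order can change outcomes at the margin. Passing
representatives (not full member lists) between stages keeps the stages
composable and deterministic. Percentages in all reports are rounded to
two decimals with round-half-even.

## Concordance analyses

* **Truth overlap** — a query record overlaps the (long-read) truth set iff
  it matches ≥1 truth record; rates are reported per support level.
  Matching is one-to-many by default (query-side counting); a strict
  one-to-one mode exists behind a flag. DUP is compared as DUP only; a
  relaxation flag for DUP↔INS equivalence is deliberately *not* provided at
  the matching level — callers can disable `require_same_type` instead.
* **Family singletons** — a proband singleton is "family-shared" iff it
  matches any relative's singleton; recurrence across relatives separates
  systematic effects from private noise. Shared and unique partitions are
  each scored against truth.
* **Parental support** — per twin call set, the percentage of records
  matching the union of all parental call sets; with no de novo events
  simulated, anything unsupported is artifact or jitter-induced miss.
* **Pairwise overlap matrix** — entry (i, j) is the percentage of set i's
  records matching set j; asymmetric by construction, diagonal exactly 100.
  (A Jaccard variant is derivable from the emitted counts; the asymmetric
  query-in-subject form is the primary output.)
* **Consensus of mappers** — clusters supported by every mapper of a chosen
  subset, scored against truth: the precision-vs-sensitivity trade of
  intersecting callers.

## Covariates and window clustering

Per-call-set SV totals are correlated (Pearson r, two-sided t-based p
with n−2 df) against coverage and insert-size summaries supplied as a TSV —
computing those summaries from alignments is out of scope, so the TSV is
the interface. Singletons are binned into fixed windows (100 kb or 1 Mb)
by start position, window index `floor((start−1)/window_size)`, zeros
included.

The clustering screen is a **Poisson maximum test**: with N singletons over
W windows, each count is ≈ Poisson(N/W); the upper-tail probability of the
observed maximum is Bonferroni-corrected across W. This statistic is this
package's own choice (no published criterion exists for the corresponding
analysis); it is conservative by construction (empirical type-I ≤ nominal
in the calibration test) and results from it must not be read as a
replication of any published clustering claim.

## Synthetic quartet generator

What it emulates: the 4×3×3×2 factorial; Hardy–Weinberg parental genotypes
with a Mendelian child shared by both twins; per-factor multiplicative
detection sensitivities plus a per-record replicate drop; per-mapper
Gaussian breakpoint jitter truncated at the merge distance (a flag permits
untruncated jitter to study match failure); private false positives
(Poisson per call set); recurrent false-positive pools per mapper and per
center level at fixed coordinates shared by every call set of that level —
the minimal mechanism that makes level-specific singletons recur across
family members; and a higher-sensitivity long-read-style call set with
per-type sensitivities.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| genome | 2 contigs × 10 Mb | smallest genome that hosts the default locus count at the separation constraint |
| n_loci | 500 | fast default; analyses scale it up explicitly |
| type mix | DEL .63 / INS .18 / DUP .08 / INV .11 | deletion-dominated short-read composition |
| size | log-uniform 50–10,000 bp | most mass in 100–1000 bp, as observed for short-read SVs |
| allele frequency | uniform(0.05, 0.95) | segregating variation in all quartet members |
| locus separation | 25 kb | > 2·max size + 2·merge distance, so distinct loci can never merge and TP/FP labels are exact |
| base sensitivity | 0.98 per call set | detection failures are drawn independently per call set, so per-set sensitivity must be near one for a realistic (~50%) fraction of loci to survive 18-set full concordance |
| mapper/center multipliers | 0.97–1.0 | mild level structure (one mapper visibly weaker) |
| replicate noise | 0.005 | small per-record drop |
| private FPs | Poisson(30) per call set | sample-private noise floor |
| recurrent pools | n_loci/50 per mapper, n_loci/100 per center | visible but not dominant systematic artifact component |
| jitter | sd 50 bp per mapper, truncated at 1000 | breakpoint imprecision that never defeats the merge |
| long-read sensitivity | DEL .95 / INS .90 / DUP .85 / INV .90, FP Poisson(20) | more sensitive than any single short-read set, imperfect on duplications |

Pool and locus coordinates are drawn under one global separation
constraint, and private false positives are rejection-sampled to sit more
than `2·max_dist` from any labeled coordinate, so every emitted record is
unambiguously a true positive, a pool artifact, or a private false
positive. Pool records are emitted without jitter: they model systematic
artifacts pinned to a genomic context, and this keeps pool-size recovery
exact even when true calls are jittered. Everything is a deterministic
function of (seed, factor key); seeds for sub-streams are derived by CRC32
of the key, keeping them below 2³¹.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated detection failures across pipeline
branches (real mappers fail on the same hard loci; here failures are
independent, which *overstates* concordance attrition per stage),
breakpoint errors correlated with genomic context, overlapping/nested loci,
translocations and complex events, coverage-driven sensitivity variation
(coverage enters only through the covariate TSV), and de novo variants in
the twins (twin-only calls are artifacts by construction).

## Numerical and degenerate-input choices

* Percent reporting: two decimals, round-half-even, via `Decimal`.
* Empty merged set → support summary of zeros with a warning; empty truth
  set → all overlap rates 0 with a warning; empty call set row in the
  overlap matrix → missing row.
* `filter_support` rejects thresholds outside 1..n; `concordant_reduce`
  names the absent factor level; `stratify` refuses an incomplete
  factorial, naming the first missing cell.
* Pearson correlation refuses vectors shorter than 3 or with zero variance
  (undefined); in the per-column covariate report a zero-variance column is
  reported as an error without aborting the other columns.
* Jitter that would invert a record (end ≤ start) is clamped to end =
  start + 1; jittered starts are clamped at 1.

## Problem sizes

Default analysis scales chosen for the bundled tests and the acceptance
script: merge-oracle cross-checks on ≤5 sets × ≤20 records; noiseless
identity at 2,000 loci; pool recovery at 5,000 loci; overlap gradients at
1,500 loci; twin consistency at 300 loci over 20 seeds; clustering
calibration over 200 null draws. These sizes give stable statistics while
keeping a full run in minutes on one core; all scale linearly with locus
count if larger runs are wanted.

## Known limitations

* Single-linkage merging can chain distinct nearby events through a bridge
  record; the separation constraint prevents this on synthetic data but
  not on arbitrary real VCFs.
* The stratification consumes representatives between stages; pipelines
  that re-merge full member lists could differ at the margin.
* No statistical variance decomposition (ANOVA-style) is attempted: the
  analysis counts and compares, as designed.
* The clustering screen tests only the maximum window; weaker multi-window
  enrichment goes undetected by design.
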