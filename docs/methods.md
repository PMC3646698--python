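# Methods

`mitofossil` implements the comparative analyses used to characterize slowly
evolving plant mitochondrial genomes: calling C-to-U RNA editing sites and
reconstructing their gains and losses on a fixed phylogeny, scoring
conservation of colinear gene clusters, estimating branch-specific silent
substitution rates and scaling them to absolute rates on a dated tree,
profiling plastid-derived inserts by sliding-window identity, and accounting
for genome content under iterative masking.  A seeded synthetic-data module
generates inputs with the statistical structure each analysis assumes, so the
whole pipeline is testable without sequence downloads.

## Data model

Trees are rooted, with node ids assigned by post-order index so event tables
and rate tables are byte-reproducible across runs.  Branch lengths are either
durations in million years (a chronogram; required on every branch) or
substitutions per site.  Chronogram estimation itself (fossil calibration,
relaxed clocks) is out of scope: a dated tree is an input.  Gene coordinates
are 1-based inclusive throughout, matching GenBank-style feature annotation.

## RNA editing

Editing sites are genomic-C/cDNA-T mismatches between in-frame CDS pairs of
equal length.  Any other mismatch is surfaced as QC output rather than
silently dropped; reverse (U-to-C) editing is not modeled.  Partial or
heteroplasmic editing is binarized upstream of this package: any reported
edit is a 1.

The multi-taxon matrix holds {0, 1, ?} per taxon and site, where `?` means
the column lies outside the taxon's sequenced coverage (gene lost, or no
cDNA).  A site's codon effect is classified by translating the reference
taxon's genomic codon with and without the single C→T change under the
standard genetic code (plant mitochondria use the standard code; the table is
a module constant so variant codes could be swapped).  Sites in codons with
more than one edit, and sites where the reference taxon does not encode a C,
are excluded from the synonymous/nonsynonymous partition but retained in the
totals, so partitioned counts sum to less than the total.  Sites with no
reference context at all (reference coverage missing) are likewise excluded
from the partition — the base is not known to be C — while the upstream
study dropped such regions entirely; the partitioned counts agree either
way, the totals here are more inclusive.

## Gain/loss reconstruction

Dollo parsimony allows one gain per character with unlimited losses — the
right model for editing sites, where independent origin of the same site is
implausible.  The gain is placed on the branch above the MRCA of all taxa
observed in state 1; below it, each maximal subtree containing only 0/? leaves
receives one loss on its stem.  This is provably the minimum: every observed
absence must descend from exactly one loss, and no observed presence from any.
`?` constrains nothing (the policy of the original matrix software is
undocumented, so the permissive choice is made and stated here); subtrees of
only-`?` leaves receive no events.  A gain landing on a root-adjacent branch
is flagged ambiguous: the character could equally be ancestral and lost on
the sister branch, which parsimony cannot polarize.  By convention such gains
are credited to the basal terminal branch, not the root edge, and the root
edge never carries events.

Unordered (Fitch) parsimony, used for plastid-derived tRNA presence/absence,
is implemented as a Sankoff-style dynamic program over the two states with
unit change cost.  The DP also counts the number of optimal labelings, so
ties ("equally parsimonious scenarios") are flagged exactly rather than
heuristically.  The returned labeling is deterministic: state 0 preferred at
the root, each child keeping its parent's state whenever optimal.

A brute-force enumerator over all internal-node state assignments (with `?`
leaves free, and for Dollo a validity constraint of at most one implied gain,
counting presence at the root as the gain) serves as the independent oracle;
the test suite sweeps every 0/1/? column on dozens of random trees.

One caveat established during validation: when truth is simulated under
pure loss, inferred losses can undercount true loss events even without
nested losses — a loss on a basal branch shifts the inferred gain downward
(no loss needed), and losses on sibling branches merge into one loss on their
parent's stem.  Inferred losses are therefore a lower bound; equality holds
exactly when every true loss falls inside the inferred gain subtree and each
loss's parent retains an observed presence.

## Gene clusters

A cluster is two or more adjacent genes separated by fewer than `max_gap`
(default 5,000 bp, strict inequality) of intergenic sequence with no
intervening genes.  Gaps use annotated feature boundaries as given; no
sequence is consulted.  Pseudogenes participate, overlapping genes count as
gap 0 (with a warning), and circular genomes test the wrap-around adjacency.
Exon fragments of trans-spliced genes are treated as distinct named features.

Clusters longer than two genes decompose into all adjacent two-gene
subclusters (the exact decomposition used for one published four-gene cluster
is ambiguous in its source; all-adjacent-pairs is the choice here).  A pair's
canonical form orients the lexicographically smaller gene name first and
records same- vs opposite-strand relative orientation — invariant under
reverse-complementing the genome, which makes "same relative orientation"
well defined.  Multi-copy genes contribute every adjacency; duplicates within
a species collapse to one presence.

Reporting rules: a pair appears in the grid iff present, in identical
canonical orientation, in the magnoliid anchor or the gymnosperm outgroup
plus at least one monocot or eudicot; or, absent from both anchors, shared
between a monocot and a eudicot, a grass and a non-grass monocot, or an
asterid and a rosid.  Panel assignment: ancestral-angiosperm when carriers
span two of {magnoliid, monocots, eudicots} or include the outgroup plus any
angiosperm (the published figure states no formal rule; this
two-of-three-clades reconstruction is explicit here); otherwise the eudicot
or monocot panel; opposite-strand pairs always go to their own panel.

## Silent rates

Synonymous divergence is counted by Nei–Gojobori (1986): per-codon synonymous
site fractions (changes to stops count as nonsynonymous) averaged over the
two sequences, multi-difference codons averaged over all minimal mutational
paths with intermediate-stop paths excluded when a stop-free path exists, and
Jukes–Cantor correction dS = −(3/4)·ln(1 − (4/3)·pS), undefined at pS ≥ 0.75
(saturation raises an error).  Codon columns edited in any taxon, stop codons
in any taxon, and supplied low-quality intervals are masked before counting.
The original analysis used a maximum-likelihood codon model; this package
deliberately substitutes NG86 counting plus a least-squares branch fit — a
documented design choice validated by simulation recovery, not a
reimplementation of the ML machinery.

Per-branch substitution amounts are fitted by non-negative least squares of
branch indicators against pairwise dS path sums (`scipy.optimize.nnls`);
the fit is exact on additive matrices.  For a bifurcating root the two
root-adjacent branches are confounded (only their sum affects any path), so
the merged edge is estimated and split in proportion to branch durations when
available, equally otherwise.  Absolute rates are ssb = subs/site divided by
branch duration in billion years; ssb × duration reproduces the fitted
amount exactly by construction.  Reported per-taxon rates use terminal
branches.  Cross-genome comparison fits ordinary least squares of chloroplast
on mitochondrial terminal rates (free intercept; the direction is a
convention) and reports the mean and sample SD of per-taxon cp/mt ratios
after omitting designated outlier lineages.  Generation-time equivalents are
years_ref × rate_ref / rate_target.

## Window identity

Windows (default 25 columns, step 10) slide over alignment columns, not
ungapped coordinates; a column with a gap in either sequence is a mismatch,
and the final partial window is dropped (its handling in the original plotting
tool is undocumented; dropping is the explicit choice, giving
⌊(L − w)/s⌋ + 1 windows).  Fragment-level identity excludes gapped columns
from both numerator and denominator.  A toy global aligner (match +1,
mismatch −1, gap −2) is provided for convenience only; real inputs are
pre-aligned pairs.

## Content accounting

Pure interval arithmetic: each ordered category's raw coverage is the union
of its own intervals; exclusive coverage subtracts everything claimed by
earlier categories; the unclaimed remainder is unknown-intergenic.  Exclusive
amounts plus the remainder partition the genome exactly, the raw sum exceeds
the exclusive sum by the double-counted overlap, and permuting category order
changes only the exclusive split, never the remainder.  The homology and
repeat searches that produce interval sets in a real analysis are inputs
here, not computations.  Intervals with start > end wrap through the origin
of a circular genome.

## Synthetic data

Every generator takes an explicit integer seed, is bit-reproducible, and
emits a truth record sufficient to score downstream inference.

* **Chronograms** — forward Yule: the crown splits at time 0, waits are
  exponential in the number of extant lineages, and the process runs one
  further waiting time beyond the n-th split so no branch has zero length;
  node times are rescaled so the crown age is exact.
* **Edit matrices** — ancestral sites present at the root are lost along
  branches as Poisson events (rate per My; absorbing), new sites arise once
  each at a gain rate per My, optional per-branch loss-rate multipliers give
  lineage-specific regimes, and missing data is assigned per taxon×gene
  block.  Defaults (700 ancestral sites, loss 0.004/My, gain 0.0005/My on a
  ~200 My crown) put roughly an order of magnitude more losses than gains on
  the tree — the loss-dominated regime these analyses target.  Sites
  observed nowhere are dropped (a real matrix only has columns edited
  somewhere); the count is in truth.
* **Codon alignments** — ancestral codons come from four-fold-degenerate
  families whose first two positions admit no synonymous single changes
  (NG86 synonymous sites = exactly 1 per codon); third positions evolve
  under Jukes–Cantor with branch length equal to the branch's dS while other
  positions stay fixed, isolating synonymous divergence from any
  nonsynonymous model.  5,000 codons mirror a ~15 kb concatenated gene set.
* **Gene orders** — per-branch Poisson-distributed inversions of contiguous
  gene runs (strands flip, internal gaps travel with the segment, boundary
  gaps stay, so gap sizes are conserved as a multiset); breakpoints avoid
  planted protected adjacencies when requested.  Whole-genome inversions are
  skipped as pure relabelings.
* **Insert pairs** — per alignment column a divergence event occurs at
  1 − identity/100 (island vs flank rate); 75% of events are substitutions,
  25% single-column indels, matching the indels-count-as-mismatches identity
  convention.

What the generators do **not** emulate: rate variation among sites and genes,
GC/codon-usage bias, realistic indel length distributions, concerted
evolution between organelle copies, gene content turnover during
rearrangement, and partial editing.  Passing recovery tests therefore
demonstrates correctness of the estimators under their stated model, not
robustness to every property of real organellar data.

## Validation surface and problem sizes

The test suite checks, among others: exhaustive agreement of both parsimony
reconstructions with brute-force enumeration over every 0/1/? column on 50
random 4–7 leaf trees; NG86 site counts and path-averaged differences against
an independently written enumeration oracle for all codon pairs with ≤ 2
differences; absolute-rate recovery on 13-taxon trees with 100-fold rate
spread and 5,000-codon alignments over 20 replicates (median relative error
comfortably under 15%; short branches carry the largest relative noise, and
the root-edge split adds error confined to the two basal branches); exact
Dollo gain recovery and the loss lower-bound behaviour described above;
planted-cluster recovery and knock-out; and 1,000-case fuzzing of the
accounting and window-geometry identities.  `scripts/acceptance.py` re-runs
this surface end to end from a single seed and writes the resulting numbers
as JSON.

## Known limitations

* NG86+JC saturates near pS = 0.75; deeply diverged pairs need the ML
  machinery this package intentionally omits.
* The two root-adjacent branch amounts are not separately identifiable from
  pairwise distances; their duration-proportional split is a convention.
* Dollo loss totals are minima, not unbiased event-count estimates.
* The ancestral-node assignment rule is a reconstruction of an informally
  stated criterion; alternative formalizations could assign border cases
  differently.
* Confidence intervals on branch rates (likelihood-profile CIs in the
  original workflow) are not computed.
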