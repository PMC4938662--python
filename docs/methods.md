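# Methods

This note documents the models, conventions and design choices behind
cactakit, in the order the pipeline runs them.

## Alignment engine and identity convention

All pairwise alignment goes through Biopython's `PairwiseAligner` with a
BLASTN-like affine scheme: match +2, mismatch −3, gap open −5, gap extend −2
(a gap of length L costs −5 − 2(L−1); end gaps are penalized in global mode).
Identity is BLASTN-style: matches / alignment columns, counting internal gap
columns and excluding terminal overhangs; columns containing N are excluded
from both numerator and denominator.  Query coverage is the fraction of
query residues inside the aligned core (between the first and last column
where both sequences have residues).

Of the optimal alignments the engine returns its first-enumerated path,
which is deterministic.  The test suite checks the returned score against an
independent exhaustive Gotoh DP oracle on all short inputs, plus that the
returned alignment's residues are intact — properties that do not depend on
tie-breaking.

Local hit search (`align_local`) is seed-and-extend: exact 12-mer matches
against a sorted k-mer index of the target are clustered into candidate
windows (diagonal-projected, merged, padded by 60 bp) and each window with
≥2 seeds is aligned locally; the best hit is taken and the window's
remainder re-searched so tandem copies are reported separately.  Scores are
therefore exact for any hit sharing two exact 12-mers with the query, which
holds comfortably above ~80% identity for hits ≥50 bp.  The ≥2-seed rule
exists because AT-rich queries in an AT-rich genome produce abundant
single-seed coincidences.  This is a deliberate trade: no E-value
statistics, exact scores only where seeds land — sufficient for masking and
flank anchoring, not a general homology search engine.

## Kimura two-parameter distance

`K = −½ ln((1 − 2P − Q) √(1 − 2Q))` with P and Q the transition and
transversion proportions over comparable columns (both residues in
{A,C,G,T}).  When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the record is flagged
`saturated` and carries NaN rather than a silent number; zero comparable
sites is an error.  Distances used for dating are computed on
globally-aligned, strand-normalized element sequences.

## Element discovery

A candidate is any interval starting `CACTA` and ending `TAGTG` within the
configured size window (default 300–500 bp, bracketing the family's 330–446
bp).  Because the two termini are reverse complements of each other, a
minus-strand element shows the identical motif pair on the plus strand;
structural candidates are therefore strand-ambiguous and strand is assigned
from the orientation of the best overlapping library hit (or "." without a
library).  Validation requires (i) the terminal 5-mers, (ii) a TIR: the
longest L in [50, 160] at which the first L bases match the reverse
complement of the last L at ≥0.80 ungapped identity, and (iii) identical
3-bp flanks (the TSD).  The TIR length floor and identity threshold are
configuration, not biology: families differ, so both are exposed.

Homology discovery masks the genome with a library, keeping hits with score
\> 250 and length > 50 bp (the conventional cutoffs for this family), merging
overlapping hits by best score.  Structural and homology calls overlapping
≥50% of the shorter are one element, structural preferred; homology-only
hits become truncated copies.  Every emitted complete element is re-checked
against its own invariants (termini, TSD equality, TIR floor) on every run.

## Insertion-site profile

For each complete element the context is upstream flank (200 bp, excluding
the left TSD copy) + one TSD copy + downstream flank, orientation-normalized
to the element strand (a flag disables this).  The TSD is counted once
because it flanks both sides.  Elements within 203 bp of a contig edge are
dropped and counted; N bases are excluded per position.  The 403-column
matrix (positions −200…−1, TSD1–3, +1…+200) and a 23-column logo window
(±10 bp) are exported as count TSVs.

## Density and the centromere test

Windows tile each chromosome (100 kb default, last window partial); an
element belongs to the window containing its start (midpoint assignment is
a flag — start was chosen for determinism under half-open coordinates).
The centromere comparison is a Welch unequal-variance t-test on window
counts inside vs. outside the supplied intervals, labeling a window by its
midpoint.  Welch was chosen over the pooled-variance test because window
count variance differs between depleted and enriched regions by
construction; the report names the test.

## Subfamily clustering

Greedy multi-round grouping: the first unassigned element (queries ordered
by (genome, chromosome, start) — content-based, so file order is
irrelevant; longest-first is available) becomes a new subfamily's
representative; every unassigned element with global identity ≥0.85 over
≥0.85 coverage joins and leaves the pool.  Coverage is measured on the
query's length by default ("its element size" read as the query's); a
min-length convention is a flag.  Subfamilies are ranked by size, ties by
representative order.  The partition property (every element in exactly one
subfamily) and rank monotonicity are asserted on every output.  Greedy
clustering is order-sensitive in principle; with the intra/inter divergence
separation this family shows (intra ≲ 10%, inter ≳ 30%) the partition is
stable under input reordering, which the tests check.

## Polymorphism calling

For each complete source element the two 100-bp flanks (TSD copies
excluded) are searched in the target.  A flank is *uniquely* mapped when
its best hit scores ≥1.5× the second best — the operational reading of
"regions with one hit".  Verdicts:

* **absent** (polymorphic): both flanks unique, same chromosome and strand,
  inter-flank gap ≤ `gap_max` (default 20 bp; the empty site retains one
  TSD copy so the expected gap is ~3 bp, and the allowance absorbs small
  indels), and no family sequence within or between the flank hits (both
  checks are recorded separately);
* **present**: flanks surround family sequence at ≥half the element length;
* **ambiguous** otherwise, with a reason code (edge, flank_unmapped,
  repeat, discordant, family_near_flank, unresolved).

Absence cannot distinguish insertion on the source branch from precise
excision on the target branch; the verdict vocabulary deliberately says
"absent", never which event occurred.  The partition (one verdict per
element) is asserted on every run.

## Ortholog pairing and the molecular clock

Elements mutually called present whose flank anchors bracket the same locus
are paired one-to-one; conflicting anchors drop both members and are
reported.  Calibration uses the arithmetic mean K̄ of pair distances
(median reported alongside; saturated pairs excluded and counted):
`r = K̄ / (2T)` with T the split time in years (default 110,000), and
`t = k / (2r)` converts divergences to ages.  Subfamily divergence
histograms are all-pairs K2P binned at 0.01; subfamily trees are built on
representative elements by neighbor joining (scikit-bio), with negative
branch-length estimates clamped to zero and counted.  NJ is exact on
additive matrices, which the tests verify against hand-computed distances.

## Gene-context classification

Gene models come from GFF3 (gffutils, in-memory DB).  Multi-transcript
genes are classified against the longest spliced transcript, matching the
one-location-per-gene reporting convention.  UTRs are taken from explicit
features when present, else inferred as exon-minus-CDS.  Intron/exon
ordinals are 1-based in transcript orientation ("1st intron" is the first
intron 5′→3′ on the gene's strand).  Elements wholly inside one feature
class get that class; straddling elements are "mixed" with the
dominant-overlap feature recorded, ties broken CDS > UTR > intron.

## The simulator

The simulator provides the ground truth everything is measured against; its
defaults are the study conditions.

**Background.**  Chromosomes are i.i.d. base draws over a mosaic: 2-kb
AT-rich islands (GC 0.21) covering 25% of the genome in a matrix whose GC
is set so the genome-wide value is 0.35.  The mosaic exists because flank
AT-enrichment cannot be produced by per-site rejection over a 400-bp window
(the acceptance probability vanishes); preferring islands at weight 10
reproduces the observed regime of flanks ~10 GC points below the genome.

**Elements.**  A family consensus (330–446 bp, TIR 145–158 bp, perfect TIR,
CACTA/TAGTG termini) spawns subfamily ancestors by substitution at 0.35/site
*within the W/S class* (A↔T, C↔G) — this keeps ancestors ~55% identical
without drifting genome GC; the divergence the pipeline *measures* is never
generated this way.  Copies mutate from their ancestor under a genuine K2P
process (transition:transversion 2:1) at 0.035 subs/site, giving
intra-subfamily all-pairs divergence ≈ 0.07 + 2rT ≈ 0.085 — a young,
recently amplified family.  Truncated copies are 160–330 bp single-end
fragments planted without TSD; the floor keeps them above the masking
cutoffs so truncated-recall tests measure discovery, not the score filter.

**Insertion.**  Sites are drawn position-weighted (telomeric outer 5% ×3,
centromeric middle 20% ×0.2, islands ×10), ≥700 bp apart, avoiding gene
exons unless targeted.  The TSD's W/S class pattern is drawn first (each
position W with probability `tsd_at_bias` = 0.85) and a matching host
3-mer located, so the planted TSD W-fraction equals the configured bias by
construction while remaining genuine duplicated host sequence.  Insertion
duplicates the 3-mer on both sides of the element.

**Divergence.**  All shared insertions (including genic ones) go into the
ancestral genome, which then evolves along two branches for `split_time` =
110,000 yr at 6.63 × 10⁻⁸ subs/site/yr (per-site substitution probability
rT per branch), so ortholog pairs diverge by ≈ 2rT = 0.0146.
Genome-specific insertions (30 per genome, lightly diverged at 0.01) are
applied per branch afterwards; a config flag converts a fraction of them to
precise excisions (element + one TSD copy removed) instead.  By default the
terminal 5-mers and TSD triplets of planted elements are excluded from
branch substitutions (`protect_motifs`), so the truth table's completeness
labels remain valid for recovery scoring; this biases pair K2P downward by
~2–3% (10 protected of ~390 element sites), well inside the recovery
tolerances, and is switchable off.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: other repeat families and nested insertions (no
decoy landscape; real flank anchoring contends with far more repetitive
context), indels and segmental duplication (boundaries stay exact; real
boundary calling is harder), sequencing/assembly gaps and Ns, rate
variation across sites and lineages, and selection on insertion sites
beyond the composition bias.  Recovery numbers here are best-case
calibrations of the machinery, not field performance estimates.

## Problem sizes in the test suite

The full-scale recovery fixture is one simulated pair at the default
conditions (2 chromosomes × 2 Mb per genome; 400 shared complete + 100
truncated + 30 + 30 specific), shared session-wide and used for discovery
recall, centromere-depletion significance and clock recovery (100 ortholog
pairs drawn from ~400 recovered).  Insertion-bias recovery uses a 520-
element single-genome run so the binomial check has n ≥ 500.  Polymorphism
sensitivity/precision pools 10 independent seeds at a reduced size (2 ×
500 kb, 120 complete + 10 + 10 specific per genome) — the caller's per-element
behavior is size-independent, so seeds buy more than bases.  Clustering
recovery runs 20 seeds of 4 × 12 elements at intra 0.0375/inter ≳ 0.45.
Decoy precision uses 20 background-only genomes of 2 × 250 kb.

## Known limitations

* `align_local` misses hits sharing fewer than two exact 12-mers with the
  query (below ~75–80% identity); the masking thresholds make this moot for
  the family itself but it bounds library generality.
* Strand of structure-only elements is unknowable from the palindromic
  termini; downstream orientation-sensitive steps need a library.
* The greedy clustering reproduces the field's procedure, including its
  dependence on query order; the content-based default order makes results
  reproducible, not order-free.
* Window-based density treats the last partial window like any other;
  per-Mb densities are exact, window counts near chromosome ends are not
  length-normalized.
* The clock assumes neutral post-insertion divergence and a correct split
  time; r inherits any error in T linearly.
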