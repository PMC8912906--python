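# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and records

All internal coordinates are 0-based half-open on the forward strand; the
1-based inclusive GenBank convention is converted at the parse boundary
(`n..m` → `[n−1, m)`). Sequences are stored linearized at the deposited
origin; features spanning the origin of a circular record are kept as
two-exon annotations. Ambiguity codes other than N are rejected at parse
time because the variant caller assumes a five-letter alphabet.

## Quadripartite structure

Detection seeds exact 25-mer matches between the doubled sequence and its
reverse complement, merges co-diagonal runs whose combined ungapped
identity stays ≥ 99.5 % (the two IR copies of a real plastome may differ by
a few bases), and keeps the longest pair of circle-disjoint segments
≥ `min_ir_len` (default 10 kb). Because copies are ungapped co-diagonal
runs, the two reported copy lengths are equal by construction; when the
underlying copies differ, this amounts to trimming to the shorter exact
core. Searching the doubled circle makes the reported lengths invariant to
where the deposited origin falls. The two single-copy arcs are labeled by
length (the longer is the LSC). Absence of any qualifying inverted
duplication raises `StructureNotFound` rather than guessing.

Repeat finding uses 8-bp exact seeds per repeat kind (forward, palindrome,
reverse, complement — i.e. the sequence against itself, its reverse
complement, its reverse, and its complement), merges co-diagonal runs while
the running identity stays above the cutoff, and suppresses hits wholly
contained in a longer hit of the same kind. `min_len < 8` is rejected
because an 8-mer seed can no longer be guaranteed inside a qualifying
repeat. Identity is matches/columns of the ungapped pairing; no E-value
model is applied — the two thresholds (≥ 30 bp, ≥ 90 %) are the contract.
On inputs ≤ 2 kb at identity 1.0 the finder is tested to agree exactly with
an O(n²) definition-based oracle.

## Pairwise alignment and variant calling

Anchors are 31-mers that occur exactly once in each genome; the longest
collinear chain (LIS in the second genome's coordinates) is merged into
co-diagonal exact blocks, block heads being trimmed where repeat-context
ambiguity makes adjacent blocks overlap by a few bases. If the chain covers
< 90 % of either genome, the pair is reported as non-collinear instead of
producing a misleading alignment. Inter-anchor gaps are closed with
affine-gap global alignment (match +1, mismatch −2, open −5, extend −1, via
Biopython's `PairwiseAligner`); at the ≥ 99 % identity of congeneric
plastomes the called counts are insensitive to these scores. Orientation is
harmonized first: if the reverse complement of genome B shares more unique
anchors with A than forward B does, B is flipped (SSC orientation flips are
common between depositions).

One maximal run of gap columns is one InDel event regardless of length —
event counting is the only convention under which a 43-event InDel list is
compatible with a 271 bp total length difference. InDels are
left-normalized (shifted to the leftmost equivalent position through
repeat/homopolymer context) so calls are independent of the aligner's gap
placement. Variants are counted at every alignment position, including both
IR copies; percentages in the pairwise matrix use
`round_half_up(100·SNPs/mean(L_a, L_b), 2)` — the mean-length denominator
reproduces printed two-decimal brackets regardless of which genome of the
pair is taken as reference.

## Marker design

Diagnostic selection operates on variants called against one reference
individual: a locus qualifies when every individual of each species carries
the same allele, at least two species differ, and the largest
between-species length difference is ≥ `min_len` (default 5 bp, below
which a 3 % agarose gel cannot be expected to resolve the shift).

Primer feasibility is a closed-form filter rather than a thermodynamic
model: length 18–27 nt, GC fraction 0.40–0.60, `Tm = 64.9 + 41·(GC_count −
16.4)/N` within 54–62 °C, no homopolymer of 5, G/C 3′ clamp. Windows must
occur exactly once in every panel genome (counting both strands), which
simultaneously enforces flank conservation and single-site binding. Among
feasible pairs the winner minimizes |ΔTm|, then product length, with
positional tie-breaks for determinism.

In-silico PCR accepts binding sites with ≤ 2 mismatches but demands an
exact 3′-terminal 3-mer (polymerase extension is 3′-anchored), considers
both strands, and reports every convergent pair ≤ 3 kb apart; product
length runs outer edge to outer edge. Expected marker sizes always come
from in-silico PCR on each genome, never from summing ledger events, so
nested InDels inside one amplicon are sized the way a gel sees them.
Resolvability is max(10 bp, 5 % of the smaller product) in gel mode and
3 bp in capillary mode; a species pair is separated only if every
cross-species size difference meets the threshold and all individuals give
single bands. Markers are named `ar` + zero-padded ordinal by genomic
position on the reference.

## Phylogeny

Shared protein-coding genes are matched case-insensitively, the first copy
is used when a gene is IR-duplicated, exons are spliced in annotation order
and reverse-complemented on the minus strand. Per-gene multiple alignment
is star-progressive: the most central sequence (highest mean 8-mer Jaccard
similarity) is the merge reference, every other sequence is aligned to it
pairwise, and insertion columns are merged by taking the longest insertion
per reference position. For plastid CDS at ≥ 70 % pairwise identity any
consistent progressive scheme yields the same column classes; sequences
below 70 % identity to the reference drop the gene with a warning. Genes
are concatenated in sorted name order and the column range of each gene is
recorded.

Distances default to Kimura 2-parameter with pairwise deletion (sites with
a gap or N in either member are excluded from that pair only);
`p-distance` is the fallback when K2P saturates (its log argument is
non-positive, raised as an error with that hint). Neighbor joining follows
Saitou–Nei with negative branch lengths clamped to zero and ties in the Q
criterion broken toward the pair whose smallest member label sorts first,
ending in a trifurcating root. On additive matrices NJ recovers the
generating topology and lengths to numerical precision (tested against a
brute-force least-squares search over all unrooted topologies at 5 taxa).
Bootstrap resamples whole alignment columns with replacement (n = 1000 by
default) with a seeded generator; support is the percentage of replicate
trees containing each internal bipartition of the full-data tree.

## LC-MS analytics

Monoisotopic masses are pinned constants (C 12, H 1.00782503, N 14.0030740,
O 15.9949146, S 31.9720707, P 30.9737615) so outputs are bit-stable. The
[M−H]⁻ m/z subtracts a neutral hydrogen atom with no electron-mass
correction — the convention that reproduces the audited annotation tables
(e.g. C16H18O9 → 353.0873, where the electron-corrected 353.0878 would
not). All printed-precision outputs use half-up rounding (4 dp for m/z,
1 dp for ppm, 2 dp for percentages) because printed tables use commercial
rounding. The audit flags rows whose printed calculated m/z deviates from
the formula-derived value by > 0.001 Th; it corrects nothing.

Internal-standard normalization divides each sample column by its IS
intensity, cancelling per-sample scale factors exactly. PCA operates on
log10(x+1)-transformed, mean-centered (not variance-scaled) normalized
intensities; the transform and the absence of unit scaling are this
package's choice, made for robustness to the heavy right tail of ion
intensities — exact reproduction of any particular study's variance
fractions additionally depends on the upstream feature-extraction settings
and is out of scope. Component signs are fixed so the largest-magnitude
loading is positive. ANOVA is one-way fixed-effects per feature on
normalized intensities with a p < 1e-4 ("four star") flag;
Benjamini–Hochberg q-values are reported alongside but gate nothing, since
the ranking convention of the field reports raw ANOVA significance.

## Synthetic data

The plastome generator draws a uniform-random ancestor with a planted
LSC/IRb/SSC/IRa layout (single-copy edge bases pinned so the planted IR
cannot extend by a chance boundary match) and evenly spaced CDS genes (one
of them intron-bearing), then applies SNP and InDel events down a star
species tree: one stem branch per species, one terminal branch per
individual. Event positions are sampled ≥ 62 bp apart — twice the 31-mer
anchor size — which is the regime in which anchor-chained alignment
recovers every planted event exactly; InDel lengths are geometric
(p = 0.25) truncated to [1, 50]. By default events land only in single-copy
regions, keeping the two IR copies identical panel-wide: mirroring an IR
edit into both copies (available via `events_in_ir=True`) would preserve
the quadripartite invariant but make each planted event appear twice to an
alignment that traverses both copies, breaking the one-to-one ledger
arithmetic the tests rely on. Default panel scale mirrors the real study
system (~151 kb genomes, ~25 kb IR, hundreds of interspecific and tens of
intraspecific events); the test suite runs scaled-down panels (6–17 kb,
tens of events) chosen so the full suite completes in well under a minute
per module while exercising the same code paths.

The feature-table generator uses log-normal baselines (log10 intensity
~ N(4, 1)), disjoint per-group marker sets multiplied by a fold change
(default 100, matching the magnitude of intensity shifts the markers are
meant to detect), multiplicative log-normal noise at CV 0.10, an internal
standard spiked at a level comparable to the median analyte, and a
per-sample log-normal scale jitter applied after spiking so normalization
must actually cancel it. Default group sizes (6/6/3) mirror two plants ×
triplicate injections for two species and one plant × triplicate for the
third.

What the generators deliberately do not emulate: realistic substitution
models (no transition bias, no rate heterogeneity), structural
rearrangements, IR boundary shifts, homopolymer sequencing error,
correlated metabolite blocks, or retention-time drift. Passing tests
therefore demonstrate correctness of the bookkeeping and algorithms under
clean, well-spaced signals — not robustness to assembly artifacts or
matrix effects in real data.

## Known limitations

* Alignment assumes collinear genomes; rearranged inputs are rejected, not
  resolved.
* Events closer together than the anchor spacing can merge into fewer
  called events; exact-count guarantees hold only in the ≥ 62 bp regime.
* Primer design is combinatorial, not thermodynamic: no dimer/hairpin
  screening, no salt correction.
* The NJ implementation is O(n³) in taxa and intended for panel-scale
  trees (tens of taxa), not large phylogenomic matrices.
* PCA variance fractions depend on upstream feature extraction and
  normalization choices; only the qualitative group separation is a stable
  target.
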