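# Methods

This note records the models, conventions and numerical choices behind
`tastkit`, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Coordinates and records

All internal coordinates are 0-based half-open; 1-based inclusive
coordinates exist only at the BLAST `-outfmt 6` boundary. The tabular
reader accepts exactly the 12 standard columns and rejects anything else,
so a malformed file fails loudly rather than silently dropping columns. A
subject interval reported descending (sstart > send) is stored ascending
with `strand="reverse"`; query coordinates must be ascending. Soft-masking
(lowercase) is discarded on read. Translation uses the standard codon
table with stops rendered `*`; any codon containing N renders `X` (a
deliberate, uniform rule — ambiguity codes are never resolved, even when
the amino acid would be unambiguous).

## Open reading frames

ORFs are defined on the forward strand only, because transcripts enter the
toolkit already oriented by their poly-A tail. For each (frame, stop
codon) pair one ORF is reported, anchored at the 5′-most in-frame ATG
since the previous stop; the stop codon lies inside the interval and
outside the protein. By default ORFs without a terminal stop are excluded
(`require_stop=False` relaxes this for truncated reads). The longest ORF
is flagged, ties broken 5′-most. The cysteine-rich selector used in mining
additionally enumerates every alternative in-frame ATG per stop, so
cysteine-dense sub-ORFs are found even when a longer, poorer ORF shares
the stop.

## Chaining transcript alignments

Within one transcript, HSPs are sorted by query start and numbered 0..n−1.
The genomic distance between adjacent blocks' subject intervals is
compared to `max_intron`; each offending adjacency disconnects the chain,
and of the resulting fragments the one with the highest summed bitscore
survives (ties to the 5′-most). This is deterministic and
scoring-consistent; a brute-force enumeration of all contiguous candidate
runs agrees with it on random instances (tested). Coverage is the union
length of surviving query intervals over the transcript length; the
min-coverage filter then applies. Collinearity is evaluated in genomic
order: runs whose order indices step by 0 or +1 (e.g. 1, 2, 3, 3) are
flagged, and a lone block is trivially collinear.

Adjacent surviving blocks can claim the same transcript bases — the
signature of a local alignment extended across a splice junction by
chance sequence agreement. When the two blocks differ in percent
identity, the disputed span is trimmed from the lower-identity block: a
chance extension that crossed the junction carries mismatches, while the
neighbouring exon block covers those bases exactly, so identity is an
informative arbiter. Exact ties are genuinely ambiguous (both placements
match perfectly) and are left untrimmed; `trim_overlaps=False` disables
arbitration entirely. Transcripts hitting both target strands are kept
and rendered per block.

## Splice-boundary error

Against an annotated set of exon boundaries, every internal block edge
(all edges except the two outermost) contributes its distance to the
nearest annotated boundary; the transcript's error is the sum. Whether a
per-junction or summed figure is the more natural report is an open
question of the underlying approach; the summed rule is the package's
decision, and callers can divide by the junction count.

An inherent accuracy limit is worth stating precisely. Any aligner that
trims an HSP at its score maximum — which every BLAST-like and
Smith–Waterman-consistent tool does — must extend an exon block past the
true boundary whenever the intron happens to continue the transcript's
sequence, because each chance match adds score. With uniform random
sequence at GC 0.42 the per-base chance-match probability is
Σp² ≈ 0.256, so an internal edge overruns by ≥1 bp about a quarter of the
time and by ≥2 bp with probability ≈0.066. A four-exon transcript has six
internal edges, which caps the fraction of random loci achieving a summed
error ≤ 1 bp per junction at roughly 0.82 — identity-based overlap
arbitration recovers the mismatch-carrying overruns, but the
perfect-match ties are unresolvable without splice-site knowledge, and
splice-consensus scoring is deliberately outside this package's scope.
On a real locus the junction contexts are fixed, so a single gene either
shows these small errors on every transcript or on none.

## Self-alignment depth and monomers

The depth profile excludes the trivial self-identity HSP, counts exact
(q,s)/(s,q) mirror duplicates once, and adds +1 over both the query and
subject interval of every remaining HSP — a symmetric convention, so the
profile is invariant under swapping query and subject, and the profile sum
equals the summed interval lengths of the counted HSPs.

Monomer extraction automates a manual procedure: the profile is smoothed
with a centred moving average (default window 25 bp) and cut at local
minima inside the repeat region. Smoothing flattens trough bottoms into
plateaus, so minima are located with `scipy.signal.find_peaks` on the
negated curve, which counts a plateau once and cuts at its midpoint.
Explicit breakpoints bypass detection to reproduce manual splits. A region
with zero depth throughout is an error ("no repeat signal").

Monomer features are overlapping k-mer counts (default decamers, k = 10);
columns are the union of observed k-mers and a monomer shorter than k
contributes a zero row. PCA uses mean-centred counts without unit-variance
scaling — counts share a unit, and scaling would inflate rare k-mers. Two
components are kept and their captured variance reported; a zero-variance
matrix (identical monomers) reports 1.0 by convention. DBSCAN runs on the
2-D coordinates with Euclidean distance, `min_samples=2`, noise label −1
permitted.

The default eps is the top of the sorted k-distance curve: the smallest
radius at which no monomer is noise (k matches scikit-learn's
self-inclusive `min_samples` convention, i.e. the (min_samples−1)-th
neighbour distance, with a 1% margin). The more common knee heuristic
assumes a background noise population whose distances dominate the tail of
the curve; a monomer set carves a repeat region exhaustively and has no
such population, so the knee of its curve falls inside the clusters and
fragments them (measured: mean adjusted Rand 0.55 for the knee vs 0.93 for
the no-noise rule on two-template fixtures). Eps remains a free parameter
for data that does contain junk monomers.

## Total identity T = I/L

Identities are fractions in [0, 1] internally; percent appears only at
I/O and on figures. Each coordinate of each sequence takes the maximum
identity among HSPs covering it (0 where uncovered); I sums both tracks, L
sums both lengths, T = I/L. Reverse-strand HSPs contribute by coordinate
span — the statistic is orientation-agnostic. T is monotone under adding
HSPs, symmetric in the two sequences, and inflated by repeats present in
unequal copy number (a copy on one side aligns to every copy on the
other); the test suite constructs this inflation explicitly. In the
comparison figure, connector width and opacity are bitscore divided by
the maximum bitscore in the plotted set (the normalization is this
package's definition), colour encodes strand, and T is printed as
percent.

## Preprocessing

The Q30 filter is interpreted as mean Phred ≥ 30 (threshold inclusive).
Barcode search is Hamming-distance scanning of each barcode and its
reverse complement within the first and last `window` bp (default 150),
best hit per end with at most `max_mismatches` (default 2); a tie between
two barcodes at the same distance is treated as no hit. A read is
assigned only when both ends report the same barcode; one-ended,
conflicting and barcode-less reads are reported with those statuses.
Assigned reads are then oriented by the poly-A rule: the longest terminal
A-run within the last 50 bp wins over the longest leading T-run within
the first 50 bp (reverse-complement if the T-run wins; ties and tail-less
reads filtered, the latter reported as `no_polya` so that "assigned"
always means "oriented"). Exact scanning replaces the original
BLAST-based barcode search: the contract is "find this short sequence
near the ends", and scanning is deterministic and dependency-free, while
BLAST-tabular ingestion remains available for parity. N50 is the largest
L such that reads of length ≥ L contain at least half the summed length.

## Mining

Exon-query retrieval keeps transcripts with any hit at or above a bitscore
threshold. Clade classification by 3′-UTR assigns each transcript the
clade of its highest-bitscore passing hit; an exact top-score tie between
clades yields "unclassified". The tissue table computes all percentages
and the representation ratio on unrounded fractions and rounds
half-away-from-zero to one decimal; the representation ratio is the
tissue's share of family transcripts divided by its share of all
transcripts — a formula inferred from the published table, which it
reproduces at every row. Splice-site consensus takes, per position, the
minimal IUPAC code covering every base at frequency ≥ 0.25 (all observed
bases when none reaches the threshold); mean identity is the mean over
unordered sequence pairs of positionwise percent identity. Motif scanning
matches IUPAC patterns at every offset, optionally on both strands; no
metal-responsive-element pattern ships because no canonical definition
exists — the pattern is always user-supplied.

## Synthetic fixtures

`simulate_locus` builds flank + exons (defaults 22, 26, 150, 250 bp —
the first two deliberately at the hard short end) separated by GT...AG
introns (defaults 1500, 1000, 800 bp, long enough to be intron-like yet
cheap to align), background GC 0.42 to match the repeat-monomer
composition of the system it emulates, optional tandem array (mutated
copies of ~180 bp templates) inserted mid-intron-1, and records exon
intervals, the spliced transcript and monomer truth labels. Splicing the
truth intervals out of the genome reproduces the transcript exactly, and
everything is a pure function of (spec, seed).

`simulate_reads` wraps the transcript as barcode + transcript + poly-A
(length uniform in 15–30 bp) + reverse-complemented barcode, flips half
the reads, applies i.i.d. substitutions and assigns flat Phred scores
matching the substitution rate. It does not emulate PacBio homopolymer
indels, chimeras or quality-score miscalibration — so preprocessing
results on fixtures bound what clean data can achieve, not what raw
instrument output will.

The naive aligner is a small seed-and-extend implementation: exact
`word_size` seeds (default 4), ungapped extension at +1 match / −2
mismatch with X-drop 6, HSPs trimmed at the score maximum (earliest end
on ties), per-diagonal merging of overlapping segments, both strands,
minimum HSP length 12. Its bitscore is the raw score and its e-value a
placeholder 0 — filtering in pipelines and tests therefore uses bitscore
or identity. On short planted cases its top HSP interval agrees with a
full dynamic-programming local alignment within ±2 bp (tested against
Biopython's `PairwiseAligner`). It exists so the toolkit is testable
without an external BLAST; it is ungapped and unsuitable for diverged
sequences.

`tandem_pair_hsps` is an idealized, explicitly synthetic self-alignment
of a tandem array — one HSP per monomer pair with 1–8 bp of edge erosion —
emulating the junction-frayed HSP pattern a self-BLAST of a *diverged*
array produces. The seed-and-extend aligner on a lightly mutated array
breaks HSPs at mutation sites rather than junctions, so depth troughs at
monomer boundaries (the signal the splitting step uses) are supplied by
this generator in tests and examples.

## Problem sizes

Default study conditions throughout the tests and the acceptance script:
50 seeded loci (~4.7 kb genome, 448 bp transcript) for exon recovery;
20 seeds × 40 monomers (two 180 bp templates, 2% substitution) for
cluster recovery; 120 noise-free plus 500 noisy (1%) reads for the
demultiplexing round trip; 200 random instances for the T = I/L oracle.
These sizes make every property measurable in seconds while keeping the
statistical assertions meaningful.

## Known limitations

- Splice junctions are placed purely by local alignment; no splice-site
  consensus, k-mer or probabilistic model refines them (see the accuracy
  limit above). That refinement is an explicit non-goal here.
- The chain keeps a single best fragment per transcript; genuinely
  trans-spliced or multi-locus transcripts are not represented.
- The depth convention (count both intervals, deduplicate mirrors) is one
  of several defensible choices; absolute depth values are comparable
  only within a convention, which is why the repeat figure labels its
  y-axis qualitatively.
- `tandem_pair_hsps` idealizes repeat self-alignment; real self-BLAST of
  a young, near-identical array yields long HSPs spanning junctions, and
  trough-based splitting then needs manual breakpoints (supported).
- T = I/L loses local resolution by design and is inflated by asymmetric
  repeats; the comparison figure's connectors are the intended antidote,
  showing rearrangement and multiplicity that the scalar hides.
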