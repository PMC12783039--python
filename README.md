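# tastkit

A BLAST-HSP toolkit for dissecting complex genomic loci with full-length
transcript reads. It grew out of a concrete problem in invertebrate
genomics: metallothionein genes — small, cysteine-rich, metal-binding
proteins — have exons as short as ~22 and ~26 bp, sit next to 10–19 kb
intronic tandem-repeat arrays, and are duplicated and variable enough that
standard spliced aligners and gene predictors misplace or miss them.
Working from ~100 kb contigs (e.g. BAC clones) and long-read RNA-seq,
`tastkit` turns plain BLAST tabular output into interpretable gene models
and statistics.

It is a library first (everything is importable from `tastkit`), with a
thin `tastkit` command-line wrapper and runnable walkthroughs in
`examples/`.

## What it computes

**Transcript-to-locus alignment (TAST view).** The local alignments (HSPs)
of each transcript against a genomic target are chained: blocks are
numbered 0..n−1 by transcript order, chains are cut where the genomic gap
between adjacent blocks exceeds a maximal intron length (the
lower-bitscore fragment is dropped), transcripts below a minimal query
coverage are removed, and runs of blocks whose order indices step by 0 or
+1 along the genome are flagged collinear. Open reading frames (ATG →
TAG/TAA/TGA, standard codon table) are overlaid so each block is drawn as
longest-ORF, minor-ORF or non-ORF. Against an annotation, the summed
distance of internal block edges to the nearest true exon boundary gives a
splice-placement error in bp.

**Repeat architecture.** From a self-alignment of a contig, a
per-coordinate depth profile (each off-diagonal HSP adds +1 over both its
intervals; mirror pairs counted once) exposes tandem arrays as plateaus.
Arrays are cut into monomers at troughs of the smoothed profile; monomers
are described by overlapping decamer counts, projected onto the first two
principal components and clustered with DBSCAN.

**Total identity between two sequences.** From the collection of pairwise
HSPs, each coordinate of each sequence takes the highest percent identity
of any alignment covering it, and

    T = I / L

where *I* is the sum of those per-coordinate best identities over both
sequences and *L* the sum of the two lengths. T is deliberately tolerant
of rearrangement and repeat-count differences (and provably inflated by
asymmetric repeat copies — the package tests this property).

**Long-read preprocessing.** Mean-quality filtering, barcode assignment
requiring the same barcode within 150 bp of *both* read ends, forward
orientation by the poly-A tail, and the N50 statistic.

**Cysteine-rich transcript mining.** Candidate transcripts retrieved by
exon-query hits; per transcript the ORF with the most cysteines is
selected (the longest ORF often is not the metal-binding one) and
transcripts under 10 cysteines are dropped; identical proteins are
collapsed; transcripts are classified into clades by their best 3′-UTR
hit; per-tissue counts are summarized with a representation ratio
(tissue's share of family transcripts ÷ its share of all transcripts);
splice-site flanks are condensed to IUPAC consensus strings; degenerate
motifs (e.g. the AATAAA poly-A signal) are scanned.

**Synthetic fixtures.** A seeded generator of multi-exon loci (defaults
22/26/150/250 bp exons, GT...AG introns, GC 0.42, optional intronic
tandem arrays from mutated monomer templates) and of barcoded, poly-A
tailed, optionally noisy reads — plus a small deterministic
seed-and-extend local aligner producing BLAST-style HSPs, so every
pipeline is testable end to end without external binaries.

## Worked example

`examples/transcript_alignment.py` builds a four-exon locus, aligns its
transcript back and measures splice placement:

```
locus: 4748 bp, transcript: 448 bp
true exons: [(500, 522), (2022, 2048), (3048, 3198), (3998, 4248)]

chained blocks (order index, query span, genomic span, ORF class):
  0: q[0,22) -> s[500,522)  non_orf
  1: q[21,48) -> s[2021,2048)  minor_orf
  2: q[48,200) -> s[3048,3200)  longest_orf
  3: q[198,448) -> s[3998,4248)  minor_orf
transcript coverage: 1.00  (fraction of transcript bases inside some block)
summed splice boundary error: 3 bp over 3 junctions
```

All four exons — including the 22 bp and 26 bp ones — are recovered as
blocks 0–3 with full coverage. The 3 bp of boundary error is the
signature ambiguity of local alignment: at three junction edges the
intron happens to continue the transcript sequence by one base, so the
score-maximal HSP extends one base past the true boundary. The other
examples walk through repeat clustering (`repeat_clustering.py`),
the T statistic (`pairwise_identity.py`), demultiplexing
(`read_preprocessing.py`) and mining (`transcript_mining.py`).

The same pipelines are available from the shell, e.g.:

```bash
tastkit simulate --what locus --seed 2 --out-dir demo/
tastkit tast --fasta demo/genome.fasta --transcripts demo/transcripts.fasta \
             --blast6 hsps.tsv --out plot.png --table blocks.tsv
tastkit tissue-table --counts counts.tsv --out table.tsv
```

Every CLI run writes its effective configuration as a JSON sidecar next to
its outputs so the run can be reproduced exactly.

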