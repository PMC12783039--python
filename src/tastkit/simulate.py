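"""Seeded generators of loci, repeats and reads with known truth, plus a
naive local aligner producing BLAST-style HSPs.

The locus generator emulates the study system: a multi-exon gene with very
short leading exons (defaults 22 and 26 bp), canonical GT...AG introns, an
optional intronic tandem-repeat array built from mutated ~180 bp monomer
templates, and a background GC content of 0.42.  The read generator wraps
each spliced transcript in end barcodes and a poly-A tail, flips half of
the reads, and applies i.i.d. substitution noise with matching Phred
scores.

The aligner is a deliberately small seed-and-extend implementation: exact
``word_size`` seeds, ungapped extension with +1/-2 scoring and X-drop 6
(trimmed to the score maximum, earliest end on ties), per-diagonal merging,
both strands.  It fills the HSP data contract so the toolkit is testable
without an external BLAST binary; its ``e_value`` is a placeholder 0 and
filtering in tests goes by bitscore or identity.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import HspRecord, ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "RepeatSpec",
    "LocusSpec",
    "SimulatedTruth",
    "ReadTruth",
    "simulate_locus",
    "simulate_reads",
    "naive_local_align",
    "tandem_pair_hsps",
]

_BASES = np.array(list("ACGT"))


@dataclass
class RepeatSpec:
    """Tandem array built from mutated monomer templates.

    ``copy_numbers[i]`` copies of ``templates[i]`` are laid down in order,
    each copy independently mutated at ``sub_rate`` per base.  The
    orientation pattern is one character per template: 'F' forward, 'R'
    reverse-complemented copies.
    """

    templates: list[str]
    copy_numbers: list[int]
    sub_rate: float = 0.02
    orientation: str = ""

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.copy_numbers):
            raise ValueError("templates and copy_numbers differ in length")
        if not self.orientation:
            self.orientation = "F" * len(self.templates)
        if len(self.orientation) != len(self.templates):
            raise ValueError("orientation pattern length mismatch")


@dataclass
class LocusSpec:
    """Parameters of one simulated multi-exon locus."""

    exon_lengths: list[int] = field(default_factory=lambda: [22, 26, 150, 250])
    intron_lengths: list[int] = field(default_factory=lambda: [1500, 1000, 800])
    repeat_spec: RepeatSpec | None = None
    utr_lengths: tuple[int, int] = (0, 0)
    flank_lengths: tuple[int, int] = (500, 500)
    gc_content: float = 0.42
    seed: int = 0

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError(
                f"{self.n_exons} exons require {self.n_exons - 1} introns, "
                f"got {len(self.intron_lengths)}"
            )
        if any(x < 1 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("all exon and intron lengths must be >= 1")


@dataclass
class ReadTruth:
    read_id: str
    barcode_id: str
    forward: bool
    polya_length: int
    tissue: str


@dataclass
class SimulatedTruth:
    """A simulated locus with every generated feature recorded."""

    genome: SequenceRecord
    exon_intervals: list[tuple[int, int]]
    transcripts: list[SequenceRecord]
    monomer_intervals: list[tuple[int, int]] = field(default_factory=list)
    monomer_labels: list[int] = field(default_factory=list)
    read_truth: list[ReadTruth] = field(default_factory=list)

    @property
    def exon_boundaries(self) -> list[int]:
        out: list[int] = []
        for s, e in self.exon_intervals:
            out.extend((s, e))
        return out


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float) -> str:
    if sub_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < sub_rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_locus(spec: LocusSpec) -> SimulatedTruth:
    """Build a genome with known exon intervals and its spliced transcript.

    The genome is flank + exons separated by GT...AG introns + flank; if a
    repeat spec is given the tandem array is inserted in the middle of the
    first intron and its monomer intervals and template-of-origin labels
    are recorded.  Untranslated leaders/trailers extend the first and last
    exon.  Deterministic for a fixed seed; splicing the exon intervals back
    out of the genome reproduces the transcript exactly.
    """
    rng = np.random.default_rng(spec.seed)
    exon_lengths = list(spec.exon_lengths)
    exon_lengths[0] += spec.utr_lengths[0]
    exon_lengths[-1] += spec.utr_lengths[1]

    introns: list[str] = []
    monomer_spans: list[tuple[int, int]] = []  # relative to their intron
    monomer_labels: list[int] = []
    repeat_intron_offset = 0
    for i, ilen in enumerate(spec.intron_lengths):
        if ilen < 4:
            raise ValueError("introns must be >= 4 bp to carry GT...AG ends")
        body = _random_seq(rng, ilen - 4, spec.gc_content)
        intron = "GT" + body + "AG"
        if i == 0 and spec.repeat_spec is not None:
            array_parts: list[str] = []
            pos = 0
            for t_idx, (template, copies) in enumerate(
                zip(spec.repeat_spec.templates, spec.repeat_spec.copy_numbers)
            ):
                for _ in range(copies):
                    copy = _mutate(rng, template, spec.repeat_spec.sub_rate)
                    if spec.repeat_spec.orientation[t_idx] == "R":
                        copy = reverse_complement(copy)
                    array_parts.append(copy)
                    monomer_spans.append((pos, pos + len(copy)))
                    monomer_labels.append(t_idx)
                    pos += len(copy)
            array = "".join(array_parts)
            mid = len(intron) // 2
            repeat_intron_offset = mid
            intron = intron[:mid] + array + intron[mid:]
        introns.append(intron)

    parts: list[str] = []
    exon_intervals: list[tuple[int, int]] = []
    pos = 0

    def _append(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    _append(_random_seq(rng, spec.flank_lengths[0], spec.gc_content))
    intron_starts: list[int] = []
    for i, elen in enumerate(exon_lengths):
        exon = _random_seq(rng, elen, spec.gc_content)
        exon_intervals.append((pos, pos + elen))
        _append(exon)
        if i < len(introns):
            intron_starts.append(pos)
            _append(introns[i])
    _append(_random_seq(rng, spec.flank_lengths[1], spec.gc_content))

    genome = SequenceRecord(f"locus_seed{spec.seed}", "".join(parts))
    transcript_seq = "".join(
        genome.residues[s:e] for s, e in exon_intervals
    )
    transcript = SequenceRecord(f"tx_seed{spec.seed}", transcript_seq)

    monomer_intervals = []
    if monomer_spans:
        base = intron_starts[0] + repeat_intron_offset
        monomer_intervals = [(base + a, base + b) for a, b in monomer_spans]

    return SimulatedTruth(
        genome=genome,
        exon_intervals=exon_intervals,
        transcripts=[transcript],
        monomer_intervals=monomer_intervals,
        monomer_labels=monomer_labels,
    )


def simulate_reads(
    truth: SimulatedTruth,
    n_reads: int,
    barcodes: Sequence[SequenceRecord],
    sub_rate: float = 0.0,
    polya_range: tuple[int, int] = (15, 30),
    seed: int = 0,
    tissues: Sequence[str] | None = None,
) -> tuple[list[ReadRecord], list[ReadTruth]]:
    """Simulate barcoded, poly-A-tailed long reads from the truth transcripts.

    Each read is barcode + transcript + poly-A + reverse-complemented
    barcode, reverse-complemented as a whole with probability one half,
    with i.i.d. substitutions at ``sub_rate`` and flat Phred scores
    consistent with that error rate.  Returns the reads and a per-read
    truth table (barcode, orientation, poly-A length, tissue label).
    """
    if not 0.0 <= sub_rate <= 0.1:
        raise ValueError("sub_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    if tissues is None:
        tissues = [b.id for b in barcodes]
    phred = 93 if sub_rate == 0 else min(93, int(round(-10 * np.log10(sub_rate))))
    reads: list[ReadRecord] = []
    table: list[ReadTruth] = []
    for i in range(n_reads):
        tx = truth.transcripts[i % len(truth.transcripts)]
        b_idx = int(rng.integers(len(barcodes)))
        bc = barcodes[b_idx]
        polya = int(rng.integers(polya_range[0], polya_range[1] + 1))
        seq = bc.residues + tx.residues + "A" * polya + reverse_complement(bc.residues)
        forward = bool(rng.random() < 0.5)
        if not forward:
            seq = reverse_complement(seq)
        seq = _mutate(rng, seq, sub_rate)
        read_id = f"read{i:05d}"
        reads.append(ReadRecord(read_id, seq, "", quality=[phred] * len(seq)))
        table.append(ReadTruth(read_id, bc.id, forward, polya, tissues[b_idx]))
    return reads, table


# ---------------------------------------------------------------------------
# Naive local aligner

_MATCH = 1
_MISMATCH = -2
_XDROP = 6


def _extend_on_diagonal(
    q: str, s: str, q_pos: int, s_pos: int, word_size: int
) -> tuple[int, int, int, int] | None:
    """Extend an exact seed at (q_pos, s_pos) in both directions.

    Returns (q_start, q_end, matches, score) of the score-maximal segment
    on this diagonal (earliest end on ties), or None.
    """
    # right extension from the seed end
    score = word_size * _MATCH
    best_score = score
    best_right = q_pos + word_size
    i, j = q_pos + word_size, s_pos + word_size
    while i < len(q) and j < len(s):
        score += _MATCH if q[i] == s[j] else _MISMATCH
        i += 1
        j += 1
        if score > best_score:
            best_score = score
            best_right = i
        elif score <= best_score - _XDROP:
            break
    # left extension from the seed start
    score = best_score
    best_left = q_pos
    i, j = q_pos - 1, s_pos - 1
    while i >= 0 and j >= 0:
        score += _MATCH if q[i] == s[j] else _MISMATCH
        if score > best_score:
            best_score = score
            best_left = i
        elif score <= best_score - _XDROP:
            break
        i -= 1
        j -= 1
    matches = sum(
        1 for a, b in zip(q[best_left:best_right],
                          s[best_left - q_pos + s_pos : best_right - q_pos + s_pos])
        if a == b
    )
    return best_left, best_right, matches, best_score


def _align_one_strand(
    q: str, s: str, word_size: int, min_hsp_len: int
) -> list[tuple[int, int, int, int, int]]:
    """HSPs of q vs s on the given orientation.

    Returns (q_start, q_end, diag, matches, score) tuples with
    diag = s_start - q_start; overlapping HSPs on one diagonal are merged.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(s) - word_size + 1):
        index.setdefault(s[j : j + word_size], []).append(j)
    covered: dict[int, list[tuple[int, int]]] = {}
    raw: dict[int, list[tuple[int, int, int, int]]] = {}
    for i in range(len(q) - word_size + 1):
        for j in index.get(q[i : i + word_size], ()):
            diag = j - i
            skip = False
            for a, b in covered.get(diag, ()):
                if a <= i and i + word_size <= b:
                    skip = True
                    break
            if skip:
                continue
            ext = _extend_on_diagonal(q, s, i, j, word_size)
            q0, q1, matches, score = ext
            covered.setdefault(diag, []).append((q0, q1))
            raw.setdefault(diag, []).append((q0, q1, matches, score))
    out: list[tuple[int, int, int, int, int]] = []
    for diag, hsps in raw.items():
        hsps.sort()
        merged: list[list[int]] = []
        for q0, q1, matches, score in hsps:
            if merged and q0 <= merged[-1][1]:
                if q1 > merged[-1][1]:
                    merged[-1][1] = q1
            else:
                merged.append([q0, q1])
        for q0, q1 in merged:
            if q1 - q0 < min_hsp_len:
                continue
            matches = sum(
                1 for a, b in zip(q[q0:q1], s[q0 + diag : q1 + diag]) if a == b
            )
            score = matches * _MATCH + (q1 - q0 - matches) * _MISMATCH
            out.append((q0, q1, diag, matches, score))
    return out


def naive_local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    word_size: int = 4,
    min_hsp_len: int = 12,
) -> list[HspRecord]:
    """Seed-and-extend local alignment of query against subject, both strands.

    Produces BLAST-style HspRecords with percent identity and a raw
    +1/-2 score as bitscore; ``e_value`` is a placeholder 0.  Deterministic.
    """
    if word_size < 2:
        raise ValueError(f"word_size must be >= 2, got {word_size}")
    q = query.residues
    s = subject.residues
    hsps: list[HspRecord] = []
    for strand in ("forward", "reverse"):
        qq = q if strand == "forward" else reverse_complement(q)
        for q0, q1, diag, matches, score in _align_one_strand(
            qq, s, word_size, min_hsp_len
        ):
            if score <= 0:
                continue
            length = q1 - q0
            s0, s1 = q0 + diag, q1 + diag
            if strand == "reverse":
                # map back to forward-query coordinates
                q0f, q1f = len(q) - q1, len(q) - q0
            else:
                q0f, q1f = q0, q1
            hsps.append(
                HspRecord(
                    query_id=query.id,
                    subject_id=subject.id,
                    q_start=q0f,
                    q_end=q1f,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    percent_identity=100.0 * matches / length,
                    align_length=length,
                    mismatches=length - matches,
                    gap_opens=0,
                    bitscore=float(score),
                    e_value=0.0,
                )
            )
    hsps.sort(key=lambda h: (-h.bitscore, h.q_start, h.s_start))
    return hsps


# ---------------------------------------------------------------------------
# Idealized tandem self-alignment


def tandem_pair_hsps(
    seq_id: str,
    monomer_intervals: Sequence[tuple[int, int]],
    seed: int = 0,
    max_edge_erosion: int = 8,
) -> list[HspRecord]:
    """Synthetic self-alignment HSP set of a tandem array.

    Emulates the HSP pattern a self-BLAST of a diverged tandem array
    produces — one local alignment per monomer pair, frayed at the monomer
    edges where divergence accumulates — so that the depth profile carries
    troughs at monomer junctions.  This is an idealized, clearly synthetic
    stand-in for a real self-alignment, useful for exercising trough-based
    monomer splitting deterministically.
    """
    rng = np.random.default_rng(seed)
    hsps: list[HspRecord] = []
    for i, (a0, a1) in enumerate(monomer_intervals):
        for j, (b0, b1) in enumerate(monomer_intervals):
            if j <= i:
                continue
            e1, e2, e3, e4 = rng.integers(1, max_edge_erosion + 1, size=4)
            qa, qb = a0 + int(e1), a1 - int(e2)
            sa, sb = b0 + int(e3), b1 - int(e4)
            if qb - qa < 10 or sb - sa < 10:
                continue
            length = min(qb - qa, sb - sa)
            hsps.append(
                HspRecord(
                    query_id=seq_id,
                    subject_id=seq_id,
                    q_start=qa,
                    q_end=qb,
                    s_start=sa,
                    s_end=sb,
                    strand="forward",
                    percent_identity=95.0,
                    align_length=length,
                    bitscore=float(length),
                    e_value=0.0,
                )
            )
    return hsps
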