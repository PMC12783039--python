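"""Sequence and alignment I/O shared by every other module.

FASTA/FASTQ parsing is delegated to Biopython; the BLAST tabular reader is
implemented here because its contract (exactly twelve ``-outfmt 6`` columns,
1-based inclusive coordinates normalized to 0-based half-open, reverse-strand
subject intervals stored ascending) is the data contract the rest of the
toolkit relies on.

All internal coordinates are 0-based half-open.  1-based inclusive
coordinates exist only at the BLAST-tab boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "ReadRecord",
    "HspRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_blast_tab",
    "write_blast_tab",
    "reverse_complement",
    "translate_dna",
    "hamming_distance",
    "gc_fraction",
]


class FormatError(ValueError):
    """A file violated the expected format."""


@dataclass
class SequenceRecord:
    """One identified nucleotide or protein sequence.

    ``id`` is non-empty and whitespace-free; ``residues`` is upper-cased.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise ValueError(f"empty sequence for id {self.id!r}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord(SequenceRecord):
    """A sequencing read: a SequenceRecord plus per-base Phred scores."""

    quality: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.quality) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )
        if any(q < 0 or q > 93 for q in self.quality):
            raise ValueError(f"read {self.id!r}: Phred score outside [0, 93]")

    @property
    def mean_quality(self) -> float:
        return sum(self.quality) / len(self.quality)


@dataclass
class HspRecord:
    """One local alignment (high-scoring segment pair).

    Query and subject intervals are 0-based half-open with start < end;
    ``strand`` records the orientation of the subject interval relative to
    the query.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "forward"  # forward | reverse
    percent_identity: float = 100.0
    align_length: int = 1
    mismatches: int = 0
    gap_opens: int = 0
    bitscore: float = 0.0
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start}, {self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval [{self.s_start}, {self.s_end})")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.bitscore < 0 or self.e_value < 0:
            raise ValueError("bitscore and e_value must be non-negative")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Residues are concatenated across wrapped lines and upper-cased.  An
    empty file or a duplicated id raises :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = []
    for r in records:
        desc = r.description or ""
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a Phred+33 FASTQ file into ReadRecords."""
    reads: list[ReadRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise FormatError(f"duplicate read id {rec.id!r} in {path}")
        seen.add(rec.id)
        reads.append(
            ReadRecord(
                rec.id,
                str(rec.seq),
                "",
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    if not reads:
        raise FormatError(f"no FASTQ records found in {path}")
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    bio = []
    for r in reads:
        rec = _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6)

_BLAST6_COLUMNS = 12


def read_blast_tab(path: str | Path) -> list[HspRecord]:
    """Read a 12-column BLAST ``-outfmt 6`` file into HspRecords.

    Input coordinates are 1-based inclusive; they are normalized to 0-based
    half-open.  A subject interval given with sstart > send is stored
    ascending with ``strand="reverse"``.  Lines starting with ``#`` are
    ignored.  Any deviation from exactly twelve tab-separated columns raises
    :class:`FormatError` naming the line.
    """
    hsps: list[HspRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST6_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST6_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mism = int(fields[4])
                gaps = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qstart > qend:
                raise FormatError(
                    f"{path}:{lineno}: qstart > qend is not supported "
                    "(query coordinates must be ascending)"
                )
            if sstart <= send:
                strand = "forward"
                s_lo, s_hi = sstart, send
            else:
                strand = "reverse"
                s_lo, s_hi = send, sstart
            hsps.append(
                HspRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=s_lo - 1,
                    s_end=s_hi,
                    strand=strand,
                    percent_identity=pident,
                    align_length=length,
                    mismatches=mism,
                    gap_opens=gaps,
                    bitscore=bitscore,
                    e_value=evalue,
                )
            )
    return hsps


def write_blast_tab(hsps: Iterable[HspRecord], path: str | Path) -> None:
    """Write HspRecords back to the 12-column outfmt-6 dialect."""
    with open(path, "w") as fh:
        for h in hsps:
            if h.strand == "forward":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.align_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(sstart),
                        str(send),
                        f"{h.e_value:.2g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Basic sequence operations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string over {A, C, G, T, N}."""
    seq = seq.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-nucleotide characters: {sorted(invalid)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_dna(seq: str, frame: int = 0) -> str:
    """Translate from ``frame`` to the last complete codon.

    Standard codon table; stop codons render as ``*`` and any codon
    containing N renders as ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    if len(seq) < frame + 3:
        raise ValueError("sequence shorter than one codon in this frame")
    aa = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aa.append("X")
        else:
            try:
                aa.append(_CODON_TABLE[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r} at position {i}") from None
    return "".join(aa)


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    """Fraction of G+C residues in a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)
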