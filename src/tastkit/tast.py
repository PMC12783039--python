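"""Transcript-to-locus alignment structures: the TAST core.

Takes the HSPs of full-length transcripts aligned to one genomic target,
chains them into ordered, numbered alignment blocks, annotates each block
with its relation to the transcript's open reading frames, flags collinear
runs, measures splice-boundary placement error against a known annotation,
and renders the whole thing as a figure.

Open reading frames are defined on the forward strand only (transcripts are
assumed pre-oriented by their poly-A tail) from an ATG start through a
TAG/TAA/TGA stop under the standard codon table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import HspRecord, SequenceRecord, translate_dna, _STOP_CODONS

__all__ = [
    "OrfRegion",
    "AlignmentBlock",
    "TranscriptAlignment",
    "find_orfs",
    "chain_transcript_alignments",
    "detect_collinearity",
    "classify_block",
    "annotate_orf_classes",
    "splice_boundary_error",
    "render_tast_plot",
]

LONGEST_ORF = "longest_orf"
MINOR_ORF = "minor_orf"
NON_ORF = "non_orf"


@dataclass
class OrfRegion:
    """An open reading frame on a transcript, 0-based half-open.

    When the ORF terminates at a stop codon, the stop lies inside
    [start, end) and is excluded from ``protein``.
    """

    start: int
    end: int
    frame: int
    protein: str
    cysteine_count: int
    is_longest: bool = False
    has_stop: bool = True

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return max(self.start, start) < min(self.end, end)


@dataclass
class AlignmentBlock:
    """One HSP placed in transcript order within a chained alignment."""

    hsp: HspRecord
    order_index: int
    orf_class: str = NON_ORF


@dataclass
class TranscriptAlignment:
    """Chained, ordered alignment of one transcript on a genomic target."""

    transcript_id: str
    transcript_length: int
    blocks: list[AlignmentBlock]
    coverage: float
    collinear_runs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def s_leftmost(self) -> int:
        return min(b.hsp.s_start for b in self.blocks)

    @property
    def s_rightmost(self) -> int:
        return max(b.hsp.s_end for b in self.blocks)


# ---------------------------------------------------------------------------
# ORFs


def find_orfs(transcript: SequenceRecord, require_stop: bool = True) -> list[OrfRegion]:
    """Find ORFs in all three forward frames.

    For each (frame, stop codon) pair the maximal ORF runs from the 5'-most
    in-frame ATG through that stop (stop included in the interval).  With
    ``require_stop=False`` a trailing ATG-anchored frame without a stop is
    also reported, truncated at the last complete codon.  The single longest
    ORF is flagged ``is_longest`` (ties broken 5'-most).
    """
    seq = transcript.residues
    orfs: list[OrfRegion] = []
    for frame in range(3):
        atg: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if atg is None and codon == "ATG":
                atg = i
            elif codon in _STOP_CODONS:
                if atg is not None:
                    protein = translate_dna(seq[atg:i], 0) if i > atg else ""
                    if protein:
                        orfs.append(
                            OrfRegion(
                                start=atg,
                                end=i + 3,
                                frame=frame,
                                protein=protein,
                                cysteine_count=protein.count("C"),
                            )
                        )
                    atg = None
                # a stop without a preceding ATG just resets the frame
            i += 3
        if atg is not None and not require_stop:
            last = atg + 3 * ((len(seq) - atg) // 3)
            if last > atg:
                protein = translate_dna(seq[atg:last], 0)
                orfs.append(
                    OrfRegion(
                        start=atg,
                        end=last,
                        frame=frame,
                        protein=protein,
                        cysteine_count=protein.count("C"),
                        has_stop=False,
                    )
                )
    if orfs:
        best = max(orfs, key=lambda o: (len(o), -o.start))
        best.is_longest = True
    return orfs


# ---------------------------------------------------------------------------
# Chaining


def _genomic_gap(a: HspRecord, b: HspRecord) -> int:
    """Distance between two subject intervals (0 if they touch or overlap)."""
    if b.s_start >= a.s_end:
        return b.s_start - a.s_end
    if a.s_start >= b.s_end:
        return a.s_start - b.s_end
    return 0


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in ivs:
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def _trim_query_overlaps(ordered: list[HspRecord]) -> list[HspRecord]:
    """Arbitrate query overlaps between adjacent HSPs by identity.

    When two adjacent blocks claim the same transcript bases, the disputed
    span is removed from the block with the lower percent identity: a
    chance extension across a splice junction carries mismatches while the
    neighbouring exon block covers those bases exactly.  Exact ties are
    genuinely ambiguous and are left untrimmed.
    """
    out: list[HspRecord] = []
    for cur in ordered:
        if not out:
            out.append(cur)
            continue
        prev = out[-1]
        v = prev.q_end - cur.q_start
        if v <= 0 or prev.percent_identity == cur.percent_identity:
            out.append(cur)
            continue
        if prev.percent_identity < cur.percent_identity:
            if prev.q_end - v > prev.q_start:
                prev = replace(
                    prev,
                    q_end=prev.q_end - v,
                    s_end=prev.s_end - v if prev.strand == "forward" else prev.s_end,
                    s_start=prev.s_start if prev.strand == "forward" else prev.s_start + v,
                )
                out[-1] = prev
            out.append(cur)
        else:
            if cur.q_start + v < cur.q_end:
                cur = replace(
                    cur,
                    q_start=cur.q_start + v,
                    s_start=cur.s_start + v if cur.strand == "forward" else cur.s_start,
                    s_end=cur.s_end if cur.strand == "forward" else cur.s_end - v,
                )
            out.append(cur)
    return out


def chain_transcript_alignments(
    hsps: Sequence[HspRecord],
    transcript_lengths: Mapping[str, int],
    max_intron: int,
    min_coverage: float,
    trim_overlaps: bool = True,
) -> list[TranscriptAlignment]:
    """Group HSPs by transcript and chain them into alignment structures.

    Within one transcript the HSPs are sorted by query start and numbered
    0..n-1.  Wherever the genomic gap between adjacent blocks exceeds
    ``max_intron`` the chain is disconnected; of the resulting fragments the
    one with the highest summed bitscore survives (ties: the 5'-most).
    With ``trim_overlaps`` (default), query overlaps between adjacent
    surviving blocks are arbitrated by percent identity (see
    :func:`_trim_query_overlaps`); exact ties stay untrimmed.  Transcripts
    whose surviving query coverage falls below ``min_coverage`` are
    dropped.  Results are sorted by leftmost subject coordinate.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError(f"min_coverage must lie in [0, 1], got {min_coverage}")
    by_tx: dict[str, list[HspRecord]] = {}
    for h in hsps:
        if h.query_id not in transcript_lengths:
            raise ValueError(f"unknown transcript id {h.query_id!r}")
        by_tx.setdefault(h.query_id, []).append(h)

    alignments: list[TranscriptAlignment] = []
    for tx_id, tx_hsps in by_tx.items():
        ordered = sorted(tx_hsps, key=lambda h: (h.q_start, h.q_end, h.s_start))
        # split at adjacencies whose genomic gap exceeds max_intron
        fragments: list[list[HspRecord]] = [[ordered[0]]]
        for prev, cur in zip(ordered, ordered[1:]):
            if _genomic_gap(prev, cur) > max_intron:
                fragments.append([cur])
            else:
                fragments[-1].append(cur)
        kept = max(fragments, key=lambda f: sum(h.bitscore for h in f))
        if trim_overlaps:
            kept = _trim_query_overlaps(kept)
        length = transcript_lengths[tx_id]
        coverage = _interval_union_length((h.q_start, h.q_end) for h in kept) / length
        if coverage < min_coverage:
            continue
        blocks = [AlignmentBlock(h, i) for i, h in enumerate(kept)]
        aln = TranscriptAlignment(tx_id, length, blocks, coverage)
        aln.collinear_runs = detect_collinearity(blocks)
        alignments.append(aln)
    alignments.sort(key=lambda a: a.s_leftmost)
    return alignments


# ---------------------------------------------------------------------------
# Collinearity


def detect_collinearity(blocks: Sequence[AlignmentBlock]) -> list[tuple[int, int]]:
    """Find maximal collinear runs of blocks in genomic order.

    Blocks are walked in ascending genomic position; a run continues while
    the order index stays the same or increments by one (e.g. 1, 2, 3, 3).
    Each run is returned as the genomic interval spanning its first to last
    block; single blocks form trivial runs of length one.
    """
    if not blocks:
        return []
    by_pos = sorted(blocks, key=lambda b: (b.hsp.s_start, b.hsp.s_end))
    runs: list[tuple[int, int]] = []
    run = [by_pos[0]]
    for prev, cur in zip(by_pos, by_pos[1:]):
        if cur.order_index - prev.order_index in (0, 1):
            run.append(cur)
        else:
            runs.append((min(b.hsp.s_start for b in run), max(b.hsp.s_end for b in run)))
            run = [cur]
    runs.append((min(b.hsp.s_start for b in run), max(b.hsp.s_end for b in run)))
    return runs


# ---------------------------------------------------------------------------
# ORF classification


def classify_block(block: AlignmentBlock, orfs: Sequence[OrfRegion]) -> str:
    """Classify a block by overlap (>= 1 bp) with the transcript's ORFs."""
    q0, q1 = block.hsp.q_start, block.hsp.q_end
    minor = False
    for orf in orfs:
        if orf.overlaps(q0, q1):
            if orf.is_longest:
                return LONGEST_ORF
            minor = True
    return MINOR_ORF if minor else NON_ORF


def annotate_orf_classes(
    alignment: TranscriptAlignment, orfs: Sequence[OrfRegion]
) -> TranscriptAlignment:
    """Set ``orf_class`` on every block of an alignment, in place."""
    for block in alignment.blocks:
        block.orf_class = classify_block(block, orfs)
    return alignment


# ---------------------------------------------------------------------------
# Boundary error


def splice_boundary_error(
    alignment: TranscriptAlignment, annotated_boundaries: Sequence[int]
) -> int:
    """Summed distance of internal block edges to the nearest true boundary.

    The outermost two edges (transcript start and end on the genome) are
    excluded; every remaining block edge contributes its distance to the
    nearest annotated exon boundary.  0 means perfect splice placement.
    """
    if not annotated_boundaries:
        raise ValueError("annotated boundary list is empty")
    edges: list[int] = []
    for b in alignment.blocks:
        edges.extend((b.hsp.s_start, b.hsp.s_end))
    edges.sort()
    internal = edges[1:-1]
    return sum(min(abs(e - a) for a in annotated_boundaries) for e in internal)


# ---------------------------------------------------------------------------
# Rendering

_BASE_COLORS = ["tab:red", "tab:blue", "tab:green", "tab:orange", "tab:purple",
                "tab:brown", "tab:cyan", "tab:olive"]


def _pack_rows(alignments: Sequence[TranscriptAlignment]) -> list[int]:
    """Greedy left-to-right row packing; returns a row index per alignment."""
    order = sorted(range(len(alignments)), key=lambda i: alignments[i].s_leftmost)
    row_ends: list[int] = []
    rows = [0] * len(alignments)
    for i in order:
        a = alignments[i]
        for r, end in enumerate(row_ends):
            if a.s_leftmost > end:
                rows[i] = r
                row_ends[r] = a.s_rightmost
                break
        else:
            rows[i] = len(row_ends)
            row_ends.append(a.s_rightmost)
    return rows


def render_tast_plot(
    alignments: Sequence[TranscriptAlignment],
    target: SequenceRecord,
    out: str | Path,
    figsize: tuple[float, float] = (12.0, 6.0),
    highlight_collinear: bool = True,
) -> Path:
    """Render chained transcript alignments over the target sequence.

    Blocks are rectangles linked by a line per transcript; fill encodes the
    ORF class (longest ORF = yellow fill, minor ORF = base colour with a
    yellow border, otherwise base colour), the order index is printed above
    each block, and collinear runs are shaded pink.  Transcripts are packed
    greedily into rows; transcripts sharing a row get distinct colours.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not alignments:
        raise ValueError("no alignments to render")
    rows = _pack_rows(alignments)
    n_rows = max(rows) + 1
    fig, ax = plt.subplots(figsize=figsize)
    row_height = 1.0
    block_h = 0.35
    for i, (aln, row) in enumerate(zip(alignments, rows)):
        y = (n_rows - 1 - row) * row_height
        color = _BASE_COLORS[i % len(_BASE_COLORS)]
        if highlight_collinear:
            for (s, e) in aln.collinear_runs:
                ax.axvspan(s, e, ymin=0, ymax=1, color="pink", alpha=0.15, lw=0)
        xs = sorted((b.hsp.s_start, b.hsp.s_end) for b in aln.blocks)
        ax.plot([xs[0][0], xs[-1][1]], [y, y], color=color, lw=1.0, zorder=1)
        for b in aln.blocks:
            if b.orf_class == LONGEST_ORF:
                face, edge = "gold", color
            elif b.orf_class == MINOR_ORF:
                face, edge = color, "gold"
            else:
                face, edge = color, color
            ax.broken_barh(
                [(b.hsp.s_start, b.hsp.s_end - b.hsp.s_start)],
                (y - block_h / 2, block_h),
                facecolors=face, edgecolors=edge, lw=1.5, zorder=2,
            )
            ax.text(
                (b.hsp.s_start + b.hsp.s_end) / 2, y + block_h, str(b.order_index),
                ha="center", va="bottom", fontsize=7,
            )
    ax.set_xlim(0, len(target.residues))
    ax.set_ylim(-1, n_rows * row_height + 0.5)
    ax.set_xlabel(f"{target.id} position (bp)")
    ax.set_yticks([])
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
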