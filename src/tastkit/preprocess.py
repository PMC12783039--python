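"""Long-read preprocessing: quality filtering, two-ended barcode
demultiplexing, poly-A orientation and read-set statistics.

The demultiplexer mirrors a PacBio-style protocol: each barcode (and its
reverse complement) is searched within a terminal window at both read ends
by Hamming-distance scanning; a read is assigned only when both ends carry
the same barcode.  Reads with a barcode at one end only, with conflicting
barcodes, or (after assignment) without a detectable poly-A tail are
reported with an explanatory status and excluded from the assigned set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "DemuxResult",
    "filter_by_quality",
    "demultiplex_barcodes",
    "orient_by_polya",
    "compute_n50",
]

ASSIGNED = "assigned"
NO_BARCODE = "no_barcode"
ONE_END_ONLY = "one_end_only"
CONFLICTING_ENDS = "conflicting_ends"
NO_POLYA = "no_polya"


@dataclass
class DemuxResult:
    """Demultiplexing outcome for one read.

    ``status == "assigned"`` implies a barcode and a successful poly-A
    orientation; ``oriented_read`` then holds the forward-oriented read.
    """

    read_id: str
    barcode_id: str | None
    status: str
    oriented: bool = False
    polya_length: int | None = None
    oriented_read: SequenceRecord | None = None


def filter_by_quality(
    reads: Sequence[ReadRecord], min_mean_q: float = 30.0
) -> list[ReadRecord]:
    """Keep reads with mean Phred score >= ``min_mean_q`` (order preserved)."""
    return [r for r in reads if r.mean_quality >= min_mean_q]


def _best_hit(window_seq: str, variants: dict[str, str], max_mismatches: int) -> str | None:
    """Best barcode in a window by Hamming scan; None if absent or ambiguous.

    ``variants`` maps barcode id to one orientation of its sequence; both
    orientations should be included by the caller.  A tie between two
    different barcodes at the minimal mismatch count is ambiguous and
    reported as no hit.
    """
    best_d = max_mismatches + 1
    best_ids: set[str] = set()
    for bc_id, bc_seq in variants.items():
        L = len(bc_seq)
        for i in range(len(window_seq) - L + 1):
            d = sum(a != b for a, b in zip(window_seq[i : i + L], bc_seq))
            if d < best_d:
                best_d = d
                best_ids = {bc_id}
            elif d == best_d:
                best_ids.add(bc_id)
    if best_d > max_mismatches or len(best_ids) != 1:
        return None
    return next(iter(best_ids))


def demultiplex_barcodes(
    reads: Sequence[SequenceRecord],
    barcodes: Sequence[SequenceRecord],
    window: int = 150,
    max_mismatches: int = 2,
    orient: bool = True,
    min_tail: int = 10,
    polya_window: int = 50,
) -> list[DemuxResult]:
    """Assign reads to barcodes found within ``window`` bp of both ends.

    Each barcode and its reverse complement are scanned in the first and
    last ``window`` bp of the read.  A read is assigned when both ends carry
    the same barcode; with ``orient=True`` the assigned read must then
    orient by its poly-A tail, otherwise it is demoted to status
    ``no_polya``.
    """
    if not barcodes:
        raise ValueError("empty barcode list")
    ids = [b.id for b in barcodes]
    if len(set(ids)) != len(ids):
        raise ValueError("barcode ids are not pairwise distinct")
    variants: dict[str, str] = {}
    for b in barcodes:
        variants[b.id] = b.residues
    rc_variants = {b.id: reverse_complement(b.residues) for b in barcodes}

    results: list[DemuxResult] = []
    for read in reads:
        seq = read.residues
        head = seq[:window]
        tail = seq[-window:]
        hit5 = _best_hit(head, variants, max_mismatches) or _best_hit(
            head, rc_variants, max_mismatches
        )
        hit3 = _best_hit(tail, variants, max_mismatches) or _best_hit(
            tail, rc_variants, max_mismatches
        )
        if hit5 is None and hit3 is None:
            results.append(DemuxResult(read.id, None, NO_BARCODE))
            continue
        if hit5 is None or hit3 is None:
            results.append(DemuxResult(read.id, hit5 or hit3, ONE_END_ONLY))
            continue
        if hit5 != hit3:
            results.append(DemuxResult(read.id, None, CONFLICTING_ENDS))
            continue
        if not orient:
            results.append(DemuxResult(read.id, hit5, ASSIGNED, oriented=False))
            continue
        oriented_read, polya = orient_by_polya(read, min_tail, polya_window)
        if oriented_read is None:
            results.append(DemuxResult(read.id, hit5, NO_POLYA))
        else:
            results.append(
                DemuxResult(read.id, hit5, ASSIGNED, oriented=True,
                            polya_length=polya, oriented_read=oriented_read)
            )
    return results


def _longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def orient_by_polya(
    read: SequenceRecord, min_tail: int = 10, search_window: int = 50
) -> tuple[SequenceRecord | None, int | None]:
    """Orient a read forward by its poly-A tail.

    If the longest A-run within the last ``search_window`` bp reaches
    ``min_tail`` the read is kept as-is; else if the longest T-run within
    the first ``search_window`` bp reaches it, the read is
    reverse-complemented.  When both qualify the longer run wins; ties and
    tail-less reads are filtered (None).
    """
    a_run = _longest_run(read.residues[-search_window:], "A")
    t_run = _longest_run(read.residues[:search_window], "T")
    a_ok = a_run >= min_tail
    t_ok = t_run >= min_tail
    if a_ok and (not t_ok or a_run > t_run):
        return read, a_run
    if t_ok and (not a_ok or t_run > a_run):
        rc = SequenceRecord(read.id, reverse_complement(read.residues),
                            read.description)
        return rc, t_run
    return None, None


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold half the total."""
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")
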