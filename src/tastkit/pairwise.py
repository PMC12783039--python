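"""Merged-HSP pairwise comparison of two long sequences.

Given the collection of BLAST HSPs between two sequences, this module
builds a per-coordinate best-identity track on each sequence (at every
coordinate, the highest percent identity among HSPs covering it) and the
scalar total-identity statistic

    T = I / L

where I is the sum of the per-coordinate best identities over both
sequences and L is the sum of the two sequence lengths.  Identities are
stored as fractions in [0, 1] internally; percent appears only at I/O and
on figures.

The statistic is orientation-agnostic and deliberately lax about element
order and copy number: a repeat present in unequal copy numbers on the two
sequences can only raise the per-coordinate maxima, never lower them, so T
is inflated by asymmetric repeats (adding alignments is monotone).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import HspRecord

__all__ = [
    "IdentityTrack",
    "IdentityComparison",
    "merge_alignment_intervals",
    "best_identity_track",
    "total_identity",
    "render_pairwise_comparison",
]


@dataclass
class IdentityTrack:
    """Per-coordinate best alignment identity (fraction) on one sequence."""

    seq_id: str
    length: int
    best_identity: np.ndarray  # float array in [0, 1], 0 where uncovered


@dataclass
class IdentityComparison:
    """Two identity tracks plus the scalar statistic T = I/L."""

    track_a: IdentityTrack
    track_b: IdentityTrack
    I: float
    L: int
    T: float


def merge_alignment_intervals(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Minimal sorted set of disjoint intervals with the same union.

    Abutting half-open intervals ([0,5), [5,9)) merge into one.
    """
    for s, e in intervals:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def best_identity_track(
    hsps: Sequence[HspRecord], seq_id: str, seq_length: int, side: str
) -> IdentityTrack:
    """Per-coordinate maximum identity among HSPs covering each position.

    ``side`` selects whether the named sequence is the query or the subject
    of the HSPs.  Reverse-strand intervals contribute by their coordinate
    span regardless of orientation.
    """
    if side not in ("query", "subject"):
        raise ValueError(f"side must be 'query' or 'subject', got {side!r}")
    track = np.zeros(seq_length, dtype=float)
    for h in hsps:
        hid = h.query_id if side == "query" else h.subject_id
        if hid != seq_id:
            continue
        lo, hi = (h.q_start, h.q_end) if side == "query" else (h.s_start, h.s_end)
        if hi > seq_length:
            raise ValueError(
                f"HSP interval [{lo},{hi}) exceeds {seq_id} length {seq_length}"
            )
        frac = h.percent_identity / 100.0
        np.maximum(track[lo:hi], frac, out=track[lo:hi])
    return IdentityTrack(seq_id, seq_length, track)


def total_identity(track_a: IdentityTrack, track_b: IdentityTrack) -> IdentityComparison:
    """The total-identity statistic T = I/L over two tracks."""
    L = track_a.length + track_b.length
    if L == 0:
        raise ValueError("zero total length")
    I = float(track_a.best_identity.sum() + track_b.best_identity.sum())
    return IdentityComparison(track_a, track_b, I=I, L=L, T=I / L)


def render_pairwise_comparison(
    hsps: Sequence[HspRecord],
    seq_a_id: str,
    seq_a_length: int,
    seq_b_id: str,
    seq_b_length: int,
    out: str | Path,
    exon_annotations_a: Sequence[tuple[int, int]] = (),
    exon_annotations_b: Sequence[tuple[int, int]] = (),
    figsize: tuple[float, float] = (12.0, 5.0),
) -> IdentityComparison:
    """Two-lane comparison figure with connectors, identity curves and T.

    Merged alignment blocks are drawn in red on each lane; one connector per
    unmerged HSP with width and opacity proportional to bitscore normalized
    by the maximum bitscore in the set, coloured red (forward) or blue
    (reverse); best-identity area curves sit above and below the lanes; the
    shorter sequence gets end borders; the scalar T is printed (as percent)
    on the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not hsps:
        raise ValueError("no HSPs to render")
    track_a = best_identity_track(hsps, seq_a_id, seq_a_length, "query")
    track_b = best_identity_track(hsps, seq_b_id, seq_b_length, "subject")
    comparison = total_identity(track_a, track_b)

    fig, ax = plt.subplots(figsize=figsize)
    y_a, y_b = 1.0, 0.0
    lane_h = 0.06
    max_bits = max(h.bitscore for h in hsps) or 1.0
    # merged blocks per lane
    for y, ivs in (
        (y_a, merge_alignment_intervals([(h.q_start, h.q_end) for h in hsps])),
        (y_b, merge_alignment_intervals([(h.s_start, h.s_end) for h in hsps])),
    ):
        ax.broken_barh([(s, e - s) for s, e in ivs], (y - lane_h / 2, lane_h),
                       facecolors="red", lw=0, zorder=3)
    # lane baselines
    ax.plot([0, seq_a_length], [y_a, y_a], color="grey", lw=0.8, zorder=2)
    ax.plot([0, seq_b_length], [y_b, y_b], color="grey", lw=0.8, zorder=2)
    # connectors, one per unmerged HSP
    for h in hsps:
        w = h.bitscore / max_bits
        color = "red" if h.strand == "forward" else "blue"
        qa = (h.q_start + h.q_end) / 2
        sb = (h.s_start + h.s_end) / 2
        ax.plot([qa, sb], [y_a - lane_h / 2, y_b + lane_h / 2],
                color=color, lw=0.3 + 2.2 * w, alpha=max(0.1, w), zorder=1)
    # identity curves above/below the lanes
    xa = np.arange(seq_a_length)
    xb = np.arange(seq_b_length)
    ax.fill_between(xa, y_a + lane_h, y_a + lane_h + 0.3 * track_a.best_identity,
                    color="black", lw=0)
    ax.fill_between(xb, y_b - lane_h, y_b - lane_h - 0.3 * track_b.best_identity,
                    color="black", lw=0)
    # exon annotations
    for s, e in exon_annotations_a:
        ax.broken_barh([(s, e - s)], (y_a - lane_h / 2, lane_h),
                       facecolors="gold", lw=0, zorder=4)
    for s, e in exon_annotations_b:
        ax.broken_barh([(s, e - s)], (y_b - lane_h / 2, lane_h),
                       facecolors="gold", lw=0, zorder=4)
    # end borders on the shorter sequence
    short_len, short_y = (
        (seq_a_length, y_a) if seq_a_length <= seq_b_length else (seq_b_length, y_b)
    )
    for x in (0, short_len):
        ax.plot([x, x], [short_y - 0.12, short_y + 0.12], color="black", lw=1.5)
    ax.text(0.01, 0.5, f"T = {100 * comparison.T:.1f}%", transform=ax.transAxes,
            fontsize=10, va="center")
    ax.set_ylim(-0.6, 1.6)
    ax.set_xlim(0, max(seq_a_length, seq_b_length))
    ax.set_yticks([y_b, y_a])
    ax.set_yticklabels([seq_b_id, seq_a_id])
    ax.set_xlabel("position (bp)")
    fig.savefig(Path(out), dpi=120)
    plt.close(fig)
    return comparison
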