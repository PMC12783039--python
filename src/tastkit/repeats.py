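"""Tandem-repeat architecture analysis of a genomic sequence.

A sequence is BLASTed against itself; every off-diagonal HSP deepens a
per-coordinate depth profile whose plateaus reveal tandem repeat arrays.
Monomers are cut at troughs of the smoothed profile, described by their
decamer (k-mer) composition, projected onto two principal components and
clustered with DBSCAN.

Depth convention: the trivial full-length self-identity HSP is excluded;
every remaining HSP contributes +1 over its query interval and +1 over its
subject interval, with exact (q,s)/(s,q) mirror pairs counted once.  The
profile is therefore symmetric under swapping query and subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import HspRecord, SequenceRecord, gc_fraction

__all__ = [
    "DepthProfile",
    "RepeatMonomer",
    "MonomerClustering",
    "self_alignment_depth",
    "split_monomers_at_troughs",
    "kmer_feature_matrix",
    "estimate_eps",
    "cluster_monomers",
    "monomer_stats",
    "render_repeat_map",
]


@dataclass
class DepthProfile:
    """Per-coordinate self-alignment coverage of one sequence."""

    seq_id: str
    depth: np.ndarray  # int array, one entry per coordinate


@dataclass
class RepeatMonomer:
    """One unit of a tandem repeat array."""

    sequence: str
    source_interval: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class MonomerClustering:
    """k-mer features, 2-D principal-component embedding and DBSCAN labels."""

    k: int
    kmers: list[str]
    feature_matrix: np.ndarray          # monomers x distinct k-mers
    pc_coordinates: np.ndarray | None = None   # monomers x 2
    variance_captured: float | None = None
    labels: np.ndarray | None = None    # -1 = noise
    dbscan_eps: float | None = None
    dbscan_min_samples: int | None = None


# ---------------------------------------------------------------------------
# Depth


def self_alignment_depth(
    hsps: Sequence[HspRecord], seq_length: int, seq_id: str | None = None
) -> DepthProfile:
    """Build the per-coordinate depth profile from a self-alignment HSP set.

    All HSPs must have ``query_id == subject_id``.  The self-identity HSP
    (query interval equal to subject interval) is excluded; mirror pairs
    count once; every counted HSP adds +1 over both of its intervals.
    """
    depth = np.zeros(seq_length, dtype=np.int64)
    seen: set[tuple] = set()
    sid = seq_id
    for h in hsps:
        if h.query_id != h.subject_id:
            raise ValueError(
                f"not a self-alignment HSP: {h.query_id!r} vs {h.subject_id!r}"
            )
        if sid is None:
            sid = h.query_id
        if h.q_end > seq_length or h.s_end > seq_length:
            raise ValueError(
                f"HSP exceeds sequence length {seq_length}: "
                f"q[{h.q_start},{h.q_end}) s[{h.s_start},{h.s_end})"
            )
        if h.q_interval == h.s_interval:
            continue  # the trivial identity diagonal
        key = (tuple(sorted((h.q_interval, h.s_interval))), h.strand)
        if key in seen:
            continue
        seen.add(key)
        depth[h.q_start : h.q_end] += 1
        depth[h.s_start : h.s_end] += 1
    return DepthProfile(sid or "", depth)


# ---------------------------------------------------------------------------
# Monomer extraction


def _smooth(depth: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge-shrunk windows."""
    kernel = np.ones(window)
    num = np.convolve(depth.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(depth, dtype=float), kernel, mode="same")
    return num / den


def split_monomers_at_troughs(
    seq: SequenceRecord,
    region: tuple[int, int],
    profile: DepthProfile,
    smoothing_window: int = 25,
    breakpoints: Sequence[int] | None = None,
) -> list[RepeatMonomer]:
    """Cut a repeat region into monomers at depth troughs.

    The profile is smoothed by a centred moving average; cut positions are
    the strict local minima of the smoothed profile inside the region, and
    monomers are the substrings between consecutive cuts (region edges
    included).  Explicit ``breakpoints`` (absolute positions, including the
    region edges) bypass trough detection.
    """
    start, end = region
    if not (0 <= start < end <= len(seq.residues)):
        raise ValueError(f"region {region} outside sequence of length {len(seq.residues)}")
    if breakpoints is not None:
        cuts = sorted(set(breakpoints))
        if len(cuts) < 2:
            raise ValueError("need at least two breakpoints")
    else:
        if not np.any(profile.depth[start:end]):
            raise ValueError("no repeat signal: depth is zero throughout the region")
        smoothed = _smooth(profile.depth, smoothing_window)
        # local minima of the smoothed curve; smoothing flattens trough
        # bottoms into plateaus, which count once (cut at the midpoint)
        peaks, _ = find_peaks(-smoothed[start:end])
        minima = (peaks + start).tolist()
        cuts = [start, *minima, end]
    monomers = []
    for a, b in zip(cuts, cuts[1:]):
        if b > a:
            monomers.append(RepeatMonomer(seq.residues[a:b], (a, b)))
    return monomers


# ---------------------------------------------------------------------------
# k-mer features, PCA and DBSCAN


def kmer_feature_matrix(monomers: Sequence[RepeatMonomer], k: int = 10) -> MonomerClustering:
    """Count overlapping k-mers (default decamers) per monomer.

    Columns are the union of k-mers observed in any monomer; monomers
    shorter than k contribute a zero row.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not monomers:
        raise ValueError("empty monomer list")
    counts: list[dict[str, int]] = []
    for m in monomers:
        c: dict[str, int] = {}
        for i in range(len(m.sequence) - k + 1):
            kmer = m.sequence[i : i + k]
            c[kmer] = c.get(kmer, 0) + 1
        counts.append(c)
    kmers = sorted(set().union(*counts))
    col = {km: j for j, km in enumerate(kmers)}
    mat = np.zeros((len(monomers), len(kmers)), dtype=np.int64)
    for i, c in enumerate(counts):
        for km, n in c.items():
            mat[i, col[km]] = n
    return MonomerClustering(k=k, kmers=kmers, feature_matrix=mat)


def estimate_eps(coords: np.ndarray, min_samples: int = 2) -> float:
    """Default DBSCAN eps: the top of the sorted k-distance curve.

    Returns the smallest radius at which every point has ``min_samples``
    points (itself included, matching scikit-learn's convention) within
    reach — i.e. the maximum (min_samples - 1)-th neighbour distance, with
    a 1% margin.  At this radius no point is labelled noise and clusters
    are the eps-connected components.  Monomer sets carve a repeat region
    exhaustively, so unlike field data they contain no background noise
    population for the usual knee heuristic to cut away; the knee of a
    noise-free curve falls inside the clusters and fragments them.
    """
    n = len(coords)
    k = min(max(min_samples - 1, 1), n - 1)
    if k < 1:
        raise ValueError("need at least two points to estimate eps")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)
    kdist = np.sort(dists[:, -1])
    if kdist[-1] == 0:
        return 1.0  # all points coincide; any positive eps gives one cluster
    return float(kdist[-1]) * 1.01


def cluster_monomers(
    features: MonomerClustering,
    eps: float | None = None,
    min_samples: int = 2,
) -> MonomerClustering:
    """Project k-mer counts onto two principal components and run DBSCAN.

    Counts are mean-centred but not scaled to unit variance.  When ``eps``
    is None it is estimated from the k-distance knee.  A zero-variance
    feature matrix (all monomers identical) reports variance_captured 1.0
    by convention and a single cluster.
    """
    mat = features.feature_matrix.astype(float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two monomers to cluster")
    centred = mat - mat.mean(axis=0)
    total_var = float((centred ** 2).sum())
    if total_var == 0.0:
        features.pc_coordinates = np.zeros((n, 2))
        features.variance_captured = 1.0
    else:
        n_comp = min(2, n - 1, mat.shape[1])
        pca = PCA(n_components=n_comp)
        coords = pca.fit_transform(mat)
        if n_comp < 2:
            coords = np.column_stack([coords, np.zeros(n)])
        features.pc_coordinates = coords
        features.variance_captured = float(pca.explained_variance_ratio_.sum())
    if eps is None:
        eps = estimate_eps(features.pc_coordinates, min_samples)
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        features.pc_coordinates
    )
    features.labels = labels
    features.dbscan_eps = float(eps)
    features.dbscan_min_samples = min_samples
    return features


# ---------------------------------------------------------------------------
# Statistics and rendering


def monomer_stats(monomers: Sequence[RepeatMonomer]) -> dict:
    """Length and GC summary of a monomer set."""
    if not monomers:
        raise ValueError("empty monomer list")
    lengths = [m.length for m in monomers]
    gcs = [m.gc_content for m in monomers]
    mean_len = sum(lengths) / len(lengths)
    mean_gc = sum(gcs) / len(gcs)
    return {
        "n": len(monomers),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "mean_length": mean_len,
        "mean_length_rounded": round(mean_len),
        "mean_gc": mean_gc,
        "mean_gc_percent_rounded": round(mean_gc * 100),
    }


def render_repeat_map(
    seq_length: int,
    profile: DepthProfile,
    monomers: Sequence[RepeatMonomer],
    labels: Sequence[int],
    out: str | Path,
    annotations: Sequence[tuple[int, int, str]] = (),
    orientations: Sequence[str] | None = None,
    figsize: tuple[float, float] = (12.0, 4.0),
) -> Path:
    """Depth curve plus per-monomer cluster-coloured blocks and annotations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(monomers) != len(labels):
        raise ValueError(
            f"{len(labels)} labels for {len(monomers)} monomers"
        )
    fig, ax = plt.subplots(figsize=figsize)
    ax.plot(np.arange(seq_length), profile.depth, color="black", lw=0.6)
    uniq = sorted(set(labels))
    cmap = matplotlib.colormaps["tab20"]
    colors = {lab: ("lightgrey" if lab == -1 else cmap(i % 20))
              for i, lab in enumerate(uniq)}
    top = float(profile.depth.max() or 1)
    for m, lab in zip(monomers, labels):
        a, b = m.source_interval
        ax.axvspan(a, b, ymin=0.0, ymax=0.08, color=colors[lab], lw=0)
    if orientations:
        for m, lab, o in zip(monomers, labels, orientations):
            a, b = m.source_interval
            dx = (b - a) * (0.4 if o == "forward" else -0.4)
            ax.annotate(
                "", xy=((a + b) / 2 + dx, top * 1.02), xytext=((a + b) / 2 - dx, top * 1.02),
                arrowprops=dict(arrowstyle="->", color=colors[lab], lw=0.8),
            )
    for (a, b, name) in annotations:
        ax.axvspan(a, b, ymin=0.92, ymax=1.0, color="tab:blue", alpha=0.6, lw=0)
        ax.text((a + b) / 2, top * 1.08, name, ha="center", fontsize=7)
    handles = [plt.Line2D([0], [0], color=colors[lab], lw=4,
                          label=("noise" if lab == -1 else f"cluster {lab}"))
               for lab in uniq]
    if handles:
        ax.legend(handles=handles, fontsize=7, loc="upper right")
    ax.set_xlim(0, seq_length)
    ax.set_xlabel(f"{profile.seq_id} position (bp)")
    ax.set_ylabel("self-alignment depth")
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
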