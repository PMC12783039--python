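"""Mining a transcript set for a cysteine-rich gene family.

Covers the metallothionein-style workflow: retrieve candidate transcripts
by exon-query BLAST hits, pick the most cysteine-rich ORF per transcript
(the longest ORF does not always encode the metal-binding protein), drop
transcripts below a cysteine threshold, collapse identical proteins,
classify transcripts into clades by their best 3'-UTR hit, summarize
per-tissue counts with a representation ratio, build IUPAC splice-site
consensus strings, and scan for degenerate motifs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping, Sequence

from .io_formats import HspRecord, SequenceRecord, hamming_distance, reverse_complement, _STOP_CODONS
from .tast import OrfRegion, find_orfs

__all__ = [
    "ProteinCluster",
    "TissueCountRow",
    "ConsensusResult",
    "mine_transcripts_by_exon",
    "select_cysteine_rich_orf",
    "dedupe_protein_clusters",
    "classify_by_utr",
    "tissue_summary",
    "splice_site_consensus",
    "scan_motif",
    "IUPAC_CODES",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ProteinCluster:
    protein: str
    member_ids: list[str]
    cysteine_count: int

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class TissueCountRow:
    """One tissue's transcript counts and derived percentages.

    ``representation`` is the tissue's share of target transcripts divided
    by its share of all transcripts, computed on unrounded fractions; >1
    means the target gene is over-represented in that tissue.
    """

    tissue: str
    transcripts: int
    transcripts_pct: float
    target_count: int
    target_pct: float
    representation: float


@dataclass
class ConsensusResult:
    consensus: str
    mean_identity_pct: float | None
    n_sequences: int
    site: str = ""


# ---------------------------------------------------------------------------
# Retrieval and ORF selection


def mine_transcripts_by_exon(
    hsps: Sequence[HspRecord], min_bitscore: float
) -> set[str]:
    """Transcript (subject) ids with at least one HSP at or above the bitscore."""
    return {h.subject_id for h in hsps if h.bitscore >= min_bitscore}


def _all_orf_candidates(seq: str) -> list[OrfRegion]:
    """Every ATG-to-stop ORF, including alternative in-frame ATGs per stop."""
    from .io_formats import translate_dna

    candidates: list[OrfRegion] = []
    for frame in range(3):
        atgs: list[int] = []
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon == "ATG":
                atgs.append(i)
            elif codon in _STOP_CODONS:
                for a in atgs:
                    if i > a:
                        protein = translate_dna(seq[a:i], 0)
                        candidates.append(
                            OrfRegion(a, i + 3, frame, protein, protein.count("C"))
                        )
                atgs = []
            i += 3
    return candidates


def select_cysteine_rich_orf(
    transcript: SequenceRecord, min_cys: int = 10
) -> OrfRegion | None:
    """The ORF with the most cysteines; None if the best has fewer than min_cys.

    All ATG-to-stop ORFs are considered, including alternative in-frame
    start codons within each (frame, stop) unit.  Ties go to the longest
    ORF, then the 5'-most.
    """
    candidates = _all_orf_candidates(transcript.residues)
    if not candidates:
        return None
    best = max(candidates, key=lambda o: (o.cysteine_count, len(o), -o.start))
    if best.cysteine_count < min_cys:
        return None
    return best


def dedupe_protein_clusters(
    proteins: Sequence[tuple[str, str]]
) -> list[ProteinCluster]:
    """Collapse (transcript id, protein) pairs into 100%-identity clusters.

    Sorted by member count descending, ties broken lexicographically by
    protein string.
    """
    groups: dict[str, list[str]] = {}
    for tx_id, protein in proteins:
        groups.setdefault(protein, []).append(tx_id)
    clusters = [
        ProteinCluster(p, members, p.count("C")) for p, members in groups.items()
    ]
    clusters.sort(key=lambda c: (-c.count, c.protein))
    return clusters


# ---------------------------------------------------------------------------
# Clade classification and tissue summary


def classify_by_utr(
    hsps: Sequence[HspRecord],
    query_clades: Mapping[str, str],
    min_bitscore: float,
) -> dict[str, str]:
    """Label transcripts by the clade of their best-scoring 3'-UTR hit.

    Only HSPs at or above ``min_bitscore`` count.  A transcript whose top
    bitscore is shared by two different clades is labelled "unclassified".
    """
    best: dict[str, tuple[float, set[str]]] = {}
    for h in hsps:
        if h.bitscore < min_bitscore:
            continue
        clade = query_clades[h.query_id]
        score, clades = best.get(h.subject_id, (-1.0, set()))
        if h.bitscore > score:
            best[h.subject_id] = (h.bitscore, {clade})
        elif h.bitscore == score:
            clades.add(clade)
    return {
        tx: (next(iter(clades)) if len(clades) == 1 else UNCLASSIFIED)
        for tx, (_, clades) in best.items()
    }


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tissue_summary(
    rows: Sequence[tuple[str, int, int]]
) -> tuple[list[TissueCountRow], TissueCountRow]:
    """Per-tissue percentage and representation table plus a totals row.

    Input rows are (tissue, total transcript count, target-gene transcript
    count).  Percentages and the representation ratio are computed on
    unrounded fractions and then rounded half-away-from-zero to one
    decimal.
    """
    if not rows:
        raise ValueError("no tissue rows")
    for tissue, tx, target in rows:
        if tx < 0 or target < 0:
            raise ValueError(f"negative count for tissue {tissue!r}")
    total_tx = sum(r[1] for r in rows)
    total_target = sum(r[2] for r in rows)
    if total_tx == 0 or total_target == 0:
        raise ValueError("zero column total")
    out: list[TissueCountRow] = []
    for tissue, tx, target in rows:
        tx_frac = tx / total_tx
        target_frac = target / total_target
        rep = target_frac / tx_frac if tx_frac > 0 else float("nan")
        out.append(
            TissueCountRow(
                tissue=tissue,
                transcripts=tx,
                transcripts_pct=_round1(100 * tx_frac),
                target_count=target,
                target_pct=_round1(100 * target_frac),
                representation=_round1(rep),
            )
        )
    totals = TissueCountRow("Total count", total_tx, 100.0, total_target, 100.0, 1.0)
    return out, totals


# ---------------------------------------------------------------------------
# IUPAC consensus and motif scanning

IUPAC_CODES: dict[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

IUPAC_SETS: dict[str, frozenset] = {code: bases for bases, code in IUPAC_CODES.items()}


def splice_site_consensus(
    flanks: Sequence[str],
    ambiguity_threshold: float = 0.25,
    site: str = "",
    require_pairs: bool = True,
) -> ConsensusResult:
    """IUPAC consensus and mean pairwise identity of equal-length flanks.

    Per position, the minimal IUPAC code covering every base whose
    frequency reaches ``ambiguity_threshold``; if no base reaches it, all
    observed bases are covered.  Mean identity is the mean over all
    unordered sequence pairs of their positionwise percent identity; with
    fewer than two sequences it is only available with
    ``require_pairs=False`` (reported as None).
    """
    if not flanks:
        raise ValueError("no flank sequences")
    flanks = [f.upper() for f in flanks]
    L = len(flanks[0])
    if any(len(f) != L for f in flanks):
        raise ValueError("flank sequences differ in length")
    n = len(flanks)
    if n < 2 and require_pairs:
        raise ValueError("need >= 2 sequences for identity (or require_pairs=False)")
    consensus = []
    for pos in range(L):
        counts = Counter(f[pos] for f in flanks)
        chosen = {b for b, c in counts.items() if c / n >= ambiguity_threshold}
        if not chosen:
            chosen = set(counts)
        consensus.append(IUPAC_CODES[frozenset(chosen)])
    if n >= 2:
        idents = [
            100.0 * (L - hamming_distance(a, b)) / L
            for a, b in combinations(flanks, 2)
        ]
        mean_identity = sum(idents) / len(idents)
    else:
        mean_identity = None
    return ConsensusResult("".join(consensus), mean_identity, n, site)


def scan_motif(
    seq: SequenceRecord, pattern: str, both_strands: bool = False
) -> list[int]:
    """0-based start positions of windows matching an IUPAC pattern.

    With ``both_strands=True``, positions where the reverse complement of
    the pattern matches the forward sequence are included too.
    """
    pattern = pattern.upper()
    for c in pattern:
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {c!r}")
    sets = [IUPAC_SETS[c] for c in pattern]

    def _scan(sets_: list[frozenset]) -> list[int]:
        s = seq.residues
        L = len(sets_)
        return [
            i
            for i in range(len(s) - L + 1)
            if all(s[i + j] in sets_[j] for j in range(L))
        ]

    hits = _scan(sets)
    if both_strands:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_sets = [frozenset(comp[b] for b in st) for st in reversed(sets)]
        hits = sorted(set(hits) | set(_scan(rc_sets)))
    return hits
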