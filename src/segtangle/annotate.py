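"""Segment-structure annotation.

Open reading frames, 3' poly-A tails, shared 3'-terminal motifs, and
pairwise amino-acid identity between homologous segments.  These are the
structural features that corroborate a set of co-occurring contigs as the
segments of one virus: each segment of the viruses targeted here carries a
single long ORF, terminates in a poly-A tract, and (for most segments)
shares a conserved ~150 nt sequence at the 3' end.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

__all__ = [
    "OrfAnnotation",
    "IdentityResult",
    "MotifReport",
    "find_longest_orf",
    "count_long_orfs",
    "polya_tail",
    "shared_terminal_motif",
    "global_align_identity",
    "reverse_complement",
]


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class OrfAnnotation:
    """A single ORF call.

    ``frame`` is 0-2 for the given strand, 3-5 for the reverse complement;
    ``start``/``end`` are 0-based half-open nt coordinates on the strand the
    ORF was found on (i.e. on the reverse complement for frames 3-5) and
    include the stop codon.  ``n_long_orfs`` counts ORFs of at least
    ``min_long`` nt over all six frames, so "single open reading frame" can
    be asserted directly.
    """

    frame: int
    start: int
    end: int
    protein: str
    coding_fraction: float
    n_long_orfs: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with coordinates")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


def _scan_frames(sequence: str) -> list[tuple[int, int, int]]:
    """All complete ATG->stop ORFs as (frame, start, end) over six frames.

    Within one frame, each ORF runs from the 5'-most unclaimed ATG to the
    next in-frame stop (stop included).
    """
    orfs: list[tuple[int, int, int]] = []
    strands = (sequence.upper(), reverse_complement(sequence.upper()))
    for strand_idx, strand in enumerate(strands):
        for offset in range(3):
            frame = 3 * strand_idx + offset
            start: int | None = None
            for pos in range(offset, len(strand) - 2, 3):
                codon = strand[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        orfs.append((frame, start, pos + 3))
                        start = None
                elif codon == START_CODON and start is None:
                    start = pos
    return orfs


def find_longest_orf(sequence: str, min_long: int = 300) -> OrfAnnotation | None:
    """Longest complete ORF over all six reading frames.

    Ties are broken by frame index, then by 5'-most start.  Returns None
    when no ATG->stop ORF exists.  Stop-free runs are not ORFs here; a
    truncated CDS at a contig edge is reported as absent, not guessed.
    """
    orfs = _scan_frames(sequence)
    if not orfs:
        return None
    n_long = sum(1 for _, s, e in orfs if e - s >= min_long)
    frame, start, end = max(orfs, key=lambda o: (o[2] - o[1], -o[0], -o[1]))
    strand = sequence.upper() if frame < 3 else reverse_complement(sequence.upper())
    protein = str(Seq(strand[start : end - 3]).translate())
    return OrfAnnotation(
        frame=frame,
        start=start,
        end=end,
        protein=protein,
        coding_fraction=(end - start) / len(sequence),
        n_long_orfs=n_long,
    )


def count_long_orfs(sequence: str, min_long: int = 300) -> int:
    """Number of complete ORFs of at least ``min_long`` nt over six frames."""
    return sum(1 for _, s, e in _scan_frames(sequence) if e - s >= min_long)


def polya_tail(sequence: str, min_len: int = 8, max_mismatch: int = 1) -> tuple[bool, int]:
    """Detect a 3'-terminal poly-A tract.

    The tail is the longest suffix containing at most ``max_mismatch``
    non-A bases, trimmed to begin with an A.  Present iff the tail reaches
    ``min_len`` nt.
    """
    seq = sequence.upper()
    mismatches = 0
    tail_start = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        if seq[i] != "A":
            mismatches += 1
            if mismatches > max_mismatch:
                break
        tail_start = i
    while tail_start < len(seq) and seq[tail_start] != "A":
        tail_start += 1
    tail_len = len(seq) - tail_start
    return tail_len >= min_len, tail_len


@dataclass(frozen=True)
class MotifReport:
    """Largest group of sequences sharing a 3'-terminal motif."""

    member_ids: tuple[str, ...]
    motif_length: int
    consensus: str
    excluded_ids: tuple[str, ...]


def _suffix_window(sequence: str, window: int) -> str | None:
    """3'-terminal window after stripping any poly-A tail."""
    present, tail = polya_tail(sequence)
    core = sequence[: len(sequence) - tail] if present else sequence
    if len(core) < window:
        return None
    return core[-window:].upper()


def shared_terminal_motif(
    sequences: Mapping[str, str], window: int = 200, id_min: float = 0.7
) -> MotifReport | None:
    """Find the largest set of sequences sharing a conserved 3' motif.

    Poly-A tails are stripped, the terminal ``window`` nt are aligned
    right-to-left without gaps, and the motif group is the largest set
    whose pairwise identities over the window all reach ``id_min``.  The
    reported motif length is the longest suffix over which the group's
    mean pairwise identity stays at or above ``id_min``.  Returns None
    when no pair qualifies.
    """
    import networkx as nx

    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    windows: dict[str, str] = {}
    excluded: list[str] = []
    for sid, seq in sequences.items():
        w = _suffix_window(seq, window)
        if w is None:
            excluded.append(sid)
        else:
            windows[sid] = w
    ids = sorted(windows)
    if len(ids) < 2:
        return None

    arrs = {sid: np.frombuffer(windows[sid].encode(), dtype="S1") for sid in ids}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    match: dict[tuple[str, str], np.ndarray] = {}
    for a, b in itertools.combinations(ids, 2):
        m = arrs[a] == arrs[b]
        match[(a, b)] = m
        if m.mean() >= id_min:
            graph.add_edge(a, b)
    cliques = [c for c in nx.find_cliques(graph) if len(c) >= 2]
    if not cliques:
        return None
    group = tuple(sorted(max(cliques, key=lambda c: (len(c), sorted(c)))))

    # longest suffix keeping mean pairwise identity >= id_min
    pair_matches = np.array(
        [match[(a, b)] for a, b in itertools.combinations(group, 2)], dtype=float
    )
    rev_cum = np.cumsum(pair_matches[:, ::-1], axis=1)  # matches in last-l columns
    lengths = np.arange(1, window + 1)
    mean_ident = rev_cum.mean(axis=0) / lengths
    ok = np.nonzero(mean_ident >= id_min)[0]
    motif_length = int(ok[-1] + 1) if ok.size else 0

    stacked = np.vstack([arrs[sid][-motif_length:] for sid in group]) if motif_length else None
    if stacked is not None:
        consensus_chars = []
        for col in stacked.T:
            vals, counts = np.unique(col, return_counts=True)
            consensus_chars.append(vals[np.argmax(counts)].decode())
        consensus = "".join(consensus_chars)
    else:
        consensus = ""
    return MotifReport(
        member_ids=group,
        motif_length=motif_length,
        consensus=consensus,
        excluded_ids=tuple(sorted(excluded)),
    )


@dataclass(frozen=True)
class IdentityResult:
    """Pairwise percent identity from a global alignment.

    Identity is counted over aligned columns excluding terminal gap
    columns; internal gap columns stay in the denominator and count as
    mismatches.  This convention matters when comparing divergent
    segments and is applied uniformly.
    """

    id_a: str
    id_b: str
    percent_identity: float
    aligned_columns: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity out of range")


def _build_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align_identity(
    protein_a: str,
    protein_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    id_a: str = "a",
    id_b: str = "b",
) -> IdentityResult:
    """Needleman-Wunsch global alignment with affine gaps, as percent identity.

    Inputs are canonicalised (lexically smaller sequence first) so the
    result is exactly symmetric in its arguments even when co-optimal
    alignments exist.
    """
    if not protein_a or not protein_b:
        raise ValueError("protein sequences must be non-empty")
    aligner = _build_aligner(matrix_name, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet)) - {"*"}
    for label, seq in ((id_a, protein_a), (id_b, protein_b)):
        bad = [i for i, ch in enumerate(seq) if ch not in alphabet]
        if bad:
            raise ValueError(f"illegal residues in {label} at positions {bad}")

    swap = protein_b < protein_a
    first, second = (protein_b, protein_a) if swap else (protein_a, protein_b)
    alignment = aligner.align(first, second)[0]
    row_a, row_b = alignment[0], alignment[1]

    non_gap = [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != "-" and y != "-"]
    lo, hi = non_gap[0], non_gap[-1] + 1
    cols = hi - lo
    ident = sum(1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-")
    return IdentityResult(
        id_a=id_a,
        id_b=id_b,
        percent_identity=100.0 * ident / cols,
        aligned_columns=cols,
        score=float(alignment.score),
    )
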