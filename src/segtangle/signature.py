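"""Small-RNA viral-signature scoring and dark-candidate filtering.

In arthropods the antiviral RNAi response (Dicer-2) dices replicating
viral RNA into 21 nt small interfering RNAs drawn from both strands and
from along the whole length of the virus.  Host transcripts instead yield
degradation products and miRNAs: broader length distributions, almost
entirely single-stranded.  A contig whose small-RNA profile is 21 nt
dominated, two-stranded and contig-spanning is therefore being recognised
by the host as a replicating double-stranded target — evidence of viral
origin that requires no sequence homology.

The dark-candidate filter combines this signature with presence rules:
length >= 1 kbp, present as RNA but not DNA, a long open reading frame,
and no detectable homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .annotate import OrfAnnotation

__all__ = [
    "SmallRnaProfile",
    "SignatureThresholds",
    "SignatureScore",
    "DarkCandidateDecision",
    "score_small_rna",
    "classify_dark_candidate",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class SmallRnaProfile:
    """Length x strand histogram of small-RNA reads mapped to one contig.

    ``histogram`` maps (read_length_nt, strand) -> read count, with strand
    "+" or "-".  ``breadth`` gives, per strand, the fraction of fixed-width
    windows (default 100 nt) receiving at least one read.
    """

    contig_id: str
    histogram: Mapping[tuple[int, str], int]
    breadth: Mapping[str, float] = field(default_factory=lambda: {"+": 1.0, "-": 1.0})

    def __post_init__(self) -> None:
        for (length, strand), count in self.histogram.items():
            if count < 0:
                raise ValueError(f"negative count for ({length}, {strand})")
            if strand not in STRANDS:
                raise ValueError(f"unknown strand {strand!r}")
        for strand, b in self.breadth.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"breadth out of [0,1] for strand {strand}")

    def total(self) -> int:
        return sum(self.histogram.values())

    def strand_total(self, strand: str) -> int:
        return sum(c for (_, s), c in self.histogram.items() if s == strand)

    def length_total(self, length: int) -> int:
        return sum(c for (l, _), c in self.histogram.items() if l == length)


@dataclass(frozen=True)
class SignatureThresholds:
    """Cutoffs quantifying a 'substantial' viRNA signature.

    ``peak_length`` is 21 nt for Drosophila-like Dicer-2; other host
    clades produce other dominant lengths and can be accommodated here.
    """

    frac_peak_min: float = 0.5
    minority_strand_min: float = 0.2
    breadth_min: float = 0.5
    peak_length: int = 21


@dataclass(frozen=True)
class SignatureScore:
    frac_21nt: float
    minority_strand_frac: float
    min_strand_breadth: float
    is_viral_signature: bool

    def __post_init__(self) -> None:
        for name in ("frac_21nt", "minority_strand_frac", "min_strand_breadth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]")


def score_small_rna(
    profile: SmallRnaProfile, thresholds: SignatureThresholds | None = None
) -> SignatureScore:
    """Score a small-RNA profile against the viRNA signature.

    The signature requires (i) at least ``frac_peak_min`` of reads at the
    peak length (both strands pooled), (ii) a minority-strand fraction of
    at least ``minority_strand_min`` (both strands diced), and (iii) both
    strands covered along the contig (min per-strand breadth).

    Raises on an empty histogram: zero reads means the evidence is
    missing, not that the contig is non-viral.
    """
    thresholds = thresholds or SignatureThresholds()
    total = profile.total()
    if total == 0:
        raise ValueError(f"no small-RNA reads for contig {profile.contig_id}")
    frac_peak = profile.length_total(thresholds.peak_length) / total
    pos = profile.strand_total("+")
    minority = min(pos, total - pos) / total
    min_breadth = min(profile.breadth.get("+", 0.0), profile.breadth.get("-", 0.0))
    is_viral = (
        frac_peak >= thresholds.frac_peak_min
        and minority >= thresholds.minority_strand_min
        and min_breadth >= thresholds.breadth_min
    )
    return SignatureScore(
        frac_21nt=frac_peak,
        minority_strand_frac=minority,
        min_strand_breadth=min_breadth,
        is_viral_signature=is_viral,
    )


@dataclass(frozen=True)
class DarkCandidateDecision:
    contig_id: str
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when no reasons are given")


def classify_dark_candidate(
    contig_id: str,
    contig_length: int,
    present_in_dna: bool,
    has_homology: bool,
    orf: OrfAnnotation | None,
    sig: SignatureScore,
    min_length: int = 1000,
    min_orf: int = 300,
) -> DarkCandidateDecision:
    """Apply the dark-virus candidate criteria to one contig.

    Passes iff the contig is >= ``min_length`` nt, absent from DNA, lacks
    homology, carries an ORF of >= ``min_orf`` nt and shows the viRNA
    signature.  Every failed criterion is listed, so a rejection is
    traceable.
    """
    reasons: list[str] = []
    if contig_length < min_length:
        reasons.append("too_short")
    if present_in_dna:
        reasons.append("in_dna")
    if has_homology:
        reasons.append("has_homology")
    if orf is None or orf.nt_length < min_orf:
        reasons.append("no_long_orf")
    if not sig.is_viral_signature:
        reasons.append("no_signature")
    return DarkCandidateDecision(
        contig_id=contig_id, passed=not reasons, reasons=tuple(reasons)
    )
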