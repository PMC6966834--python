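"""Genome-sense inference from strand-specific read counts.

In strand-specific RNA sequencing, the ratio of positive- to
negative-sense reads mapping to a virus reflects its replication
strategy: +ssRNA viruses are very strongly biased to positive-sense reads
(genomic strand plus mRNA-like products), replicating dsRNA viruses are
weakly positive-biased, and replicating -ssRNA viruses are weakly
negative-biased.  The qualitative rules are made operational here as
bands on an exact (Clopper-Pearson) binomial confidence interval for the
positive-strand fraction, so that a call is only made when the data rule
the alternatives out.

Poly-A-enriched libraries artificially enrich mRNA-like products and are
untrustworthy for this purpose; they are flagged, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .cooccur import AbundanceMatrix, SegmentGroup

__all__ = [
    "StrandCall",
    "SenseThresholds",
    "strand_fraction",
    "classify_genome_sense",
    "call_group_sense",
    "abundance_summary",
]

CALLS = ("positive_ss", "double_stranded_like", "negative_ss", "ambiguous")


@dataclass(frozen=True)
class SenseThresholds:
    """Bands on the positive-strand-fraction confidence interval.

    ``strong_pos``: lower CI bound at or above this calls +ssRNA.
    ``weak_margin``: upper CI bound at or below 0.5 - margin calls -ssRNA.
    A CI lying entirely inside (0.5, strong_pos) calls a replicating
    dsRNA-like pattern; anything else is ambiguous.
    """

    strong_pos: float = 0.95
    weak_margin: float = 0.02
    confidence: float = 0.95


@dataclass(frozen=True)
class StrandCall:
    id: str
    positive_fraction: float
    n_fragments: int
    call: str
    ci_low: float
    ci_high: float
    library_trusted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction out of [0,1]")
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def strand_fraction(
    pos: int, neg: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Positive-strand read fraction with an exact binomial CI.

    Returns (fraction, ci_low, ci_high) using the Clopper-Pearson
    interval, which is conservative (coverage >= nominal) even at the
    extreme fractions typical of +ssRNA viruses.
    """
    if pos < 0 or neg < 0:
        raise ValueError("strand counts must be non-negative")
    total = pos + neg
    if total == 0:
        raise ValueError("no strand-assigned fragments")
    ci = binomtest(pos, total).proportion_ci(confidence_level=confidence, method="exact")
    return pos / total, float(ci.low), float(ci.high)


def classify_genome_sense(
    pos: int,
    neg: int,
    thresholds: SenseThresholds | None = None,
    id: str = "",
    library_trusted: bool = True,
) -> StrandCall:
    """Call genome sense from strand counts via CI bands.

    positive_ss when the CI lower bound clears ``strong_pos``;
    double_stranded_like when the whole CI sits in (0.5, strong_pos);
    negative_ss when the CI upper bound is at most 0.5 - ``weak_margin``;
    ambiguous otherwise (including whenever the CI straddles bands, as it
    will at small n).
    """
    t = thresholds or SenseThresholds()
    frac, lo, hi = strand_fraction(pos, neg, confidence=t.confidence)
    if lo >= t.strong_pos:
        call = "positive_ss"
    elif lo > 0.5 and hi < t.strong_pos:
        call = "double_stranded_like"
    elif hi <= 0.5 - t.weak_margin:
        call = "negative_ss"
    else:
        call = "ambiguous"
    return StrandCall(
        id=id,
        positive_fraction=frac,
        n_fragments=pos + neg,
        call=call,
        ci_low=lo,
        ci_high=hi,
        library_trusted=library_trusted,
    )


def call_group_sense(
    group: SegmentGroup,
    strand_counts: pd.DataFrame,
    thresholds: SenseThresholds | None = None,
    group_id: str = "",
    library_trusted: bool = True,
) -> StrandCall:
    """Pool member contigs' strand counts and call sense for the group.

    Segments of one genome share a sense, so pooling gains power;
    ``group`` is a SegmentGroup or an iterable of contig ids, and
    ``strand_counts`` has columns (contig_id, pos, neg) or is indexed by
    contig_id.
    """
    sc = strand_counts.set_index("contig_id") if "contig_id" in strand_counts else strand_counts
    members = list(group.contig_ids if isinstance(group, SegmentGroup) else group)
    missing = set(members) - set(sc.index)
    if missing:
        raise ValueError(f"strand counts missing for contigs: {sorted(missing)}")
    pos = int(sc.loc[members, "pos"].sum())
    neg = int(sc.loc[members, "neg"].sum())
    return classify_genome_sense(
        pos, neg, thresholds, id=group_id or "+".join(members),
        library_trusted=library_trusted,
    )


def abundance_summary(
    matrix: AbundanceMatrix, groups: Iterable[SegmentGroup]
) -> pd.DataFrame:
    """Per-group abundance corroboration summary.

    For each group, the per-sample group RPKM (total member fragments per
    total member kilobases per million library fragments) is summarised
    over the samples where the group is present (all members detected):
    min, median, max, and the largest fraction of a library the group
    accounts for.  A group never present is flagged, not an error.
    """
    rows = []
    for gi, group in enumerate(groups):
        members = list(group.contig_ids if isinstance(group, SegmentGroup) else group)
        missing = set(members) - set(matrix.rpkm.index)
        if missing:
            raise ValueError(f"group contigs absent from matrix: {sorted(missing)}")
        frag = matrix.fragments.loc[members]
        total_kb = matrix.lengths.loc[members].sum() / 1000.0
        group_rpkm = frag.sum(axis=0) / total_kb / (matrix.library_sizes / 1e6)
        lib_frac = frag.sum(axis=0) / matrix.library_sizes
        present = matrix.presence.loc[members].all(axis=0)
        vals = group_rpkm[present]
        rows.append(
            {
                "group_id": gi,
                "contig_ids": ";".join(members),
                "n_support_samples": int(present.sum()),
                "min_rpkm": float(vals.min()) if len(vals) else np.nan,
                "median_rpkm": float(vals.median()) if len(vals) else np.nan,
                "max_rpkm": float(vals.max()) if len(vals) else np.nan,
                "max_library_fraction": float(lib_frac[present].max()) if len(vals) else np.nan,
                "never_present": not bool(present.any()),
            }
        )
    return pd.DataFrame(rows)
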