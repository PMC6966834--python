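"""Cross-sample co-occurrence association of contigs into segment groups.

Segments of one segmented virus travel together: a segment is present in
exactly the samples its virus infects, and its read count tracks the
per-sample viral load.  Contigs whose abundance profiles are strongly
correlated across samples, and whose presence/absence calls agree, are
therefore associated into putative multi-segment genomes.  The same logic
ranks candidate missing segments: a contig that mirrors an established
group's profile is likely a further segment of the same virus (this is
how the polymerase-encoding fifth segment of the founding viruses was
recovered).

Abundance is expressed as RPKM — fragments (read pairs) per kilobase of
contig per million library fragments.  Correlation is computed on
log10(RPKM + eps) over ALL samples: shared absences are themselves
evidence of co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMatrix",
    "CooccurrenceTables",
    "SegmentGroup",
    "rpkm",
    "build_abundance_matrix",
    "pairwise_cooccurrence",
    "cluster_segments",
    "find_candidate_segments",
]


def rpkm(fragments: float, length_nt: float, library_size: float) -> float:
    """Reads (fragments) Per Kilobase per Million library fragments."""
    if length_nt <= 0:
        raise ValueError("contig length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if fragments < 0:
        raise ValueError("fragment count must be non-negative")
    return fragments / ((length_nt / 1000.0) * (library_size / 1e6))


@dataclass
class AbundanceMatrix:
    """Contig x sample RPKM values with presence calls.

    ``rpkm`` and ``presence`` are DataFrames indexed by contig id with one
    column per sample; ``lengths`` (nt) and ``library_sizes`` (fragments)
    are Series over the same axes.
    """

    rpkm: pd.DataFrame
    presence: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    fragments: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM must be non-negative")
        if not self.rpkm.index.equals(self.presence.index) or not self.rpkm.columns.equals(
            self.presence.columns
        ):
            raise ValueError("rpkm/presence dimensions inconsistent")
        if (self.presence.values & ~(self.rpkm.values > 0)).any():
            raise ValueError("presence implies positive RPKM")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def build_abundance_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    presence_min_fragments: int = 5,
) -> AbundanceMatrix:
    """Build an RPKM + presence matrix from a long-format count table.

    ``counts`` has columns (contig_id, sample_id, fragments).  Presence is
    called at >= ``presence_min_fragments`` fragments; the default of 5
    sits just under the weakest accepted real-world evidence of six read
    pairs.  Contigs/samples absent from the count table but present in
    ``lengths``/``library_sizes`` appear as all-zero rows/columns.
    """
    required = {"contig_id", "sample_id", "fragments"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    unknown_contigs = set(counts["contig_id"]) - set(lengths.index)
    if unknown_contigs:
        raise ValueError(f"contigs without lengths: {sorted(unknown_contigs)}")
    unknown_samples = set(counts["sample_id"]) - set(library_sizes.index)
    if unknown_samples:
        raise ValueError(f"samples without library sizes: {sorted(unknown_samples)}")

    frag = (
        counts.pivot_table(
            index="contig_id", columns="sample_id", values="fragments", fill_value=0
        )
        .reindex(index=lengths.index, columns=library_sizes.index, fill_value=0)
        .astype(float)
    )
    rpkm_mat = frag.div(lengths / 1000.0, axis=0).div(library_sizes / 1e6, axis=1)
    presence = frag >= presence_min_fragments
    return AbundanceMatrix(
        rpkm=rpkm_mat,
        presence=presence,
        lengths=lengths.astype(float),
        library_sizes=library_sizes.astype(float),
        fragments=frag,
    )


@dataclass
class CooccurrenceTables:
    """Symmetric pairwise correlation and presence-concordance tables.

    ``r`` holds the correlation of log10(RPKM + eps) across all samples
    (NaN where a vector is constant, flagged in ``constant``);
    ``concordance`` is the fraction of samples whose presence calls agree.
    """

    r: pd.DataFrame
    concordance: pd.DataFrame
    constant: pd.Series
    eps: float
    method: str


def pairwise_cooccurrence(
    matrix: AbundanceMatrix, eps: float = 0.01, method: str = "pearson"
) -> CooccurrenceTables:
    """All-pairs co-occurrence statistics across samples.

    ``method`` is "pearson" (default, on log10(RPKM + eps)) or "spearman"
    (rank-based, eps irrelevant to the ordering but applied for
    uniformity).  Requires >= 3 samples; correlation over fewer is
    meaningless.
    """
    if matrix.rpkm.shape[1] < 3:
        raise ValueError("co-occurrence requires at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    log_ab = np.log10(matrix.rpkm.values + eps)
    if method == "spearman":
        log_ab = stats.rankdata(log_ab, axis=1)
    constant = log_ab.std(axis=1) == 0
    centered = log_ab - log_ab.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    ids = matrix.rpkm.index
    pres = matrix.presence.values
    agree = (pres[:, None, :] == pres[None, :, :]).mean(axis=2)
    return CooccurrenceTables(
        r=pd.DataFrame(r, index=ids, columns=ids),
        concordance=pd.DataFrame(agree, index=ids, columns=ids),
        constant=pd.Series(constant, index=ids),
        eps=eps,
        method=method,
    )


@dataclass(frozen=True)
class SegmentGroup:
    """A putative segmented-virus genome: contigs that co-occur."""

    contig_ids: tuple[str, ...]
    min_pairwise_r: float
    min_concordance: float
    support_samples: int

    def __post_init__(self) -> None:
        if len(self.contig_ids) < 2:
            raise ValueError("a segment group needs at least two contigs")


def cluster_segments(
    tables: CooccurrenceTables,
    r_min: float = 0.87,
    concordance_min: float = 0.9,
    matrix: AbundanceMatrix | None = None,
    linkage: str = "connected",
) -> list[SegmentGroup]:
    """Group contigs into putative segmented genomes.

    An edge joins contigs i, j when r >= ``r_min`` and concordance >=
    ``concordance_min``; groups are the connected components of size >= 2
    (``linkage="complete"`` instead keeps only maximal cliques, a stricter
    alternative).  Each group reports its minimum pairwise r and
    concordance over member pairs, and — when ``matrix`` is given — the
    number of samples in which every member is present.
    """
    ids = list(tables.r.index)
    r = tables.r.values
    conc = tables.concordance.values
    n = len(ids)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    ok = (~np.isnan(r[iu, ju])) & (r[iu, ju] >= r_min) & (conc[iu, ju] >= concordance_min)
    graph.add_edges_from(zip(iu[ok], ju[ok]))

    if linkage == "connected":
        raw_groups = [c for c in nx.connected_components(graph) if len(c) >= 2]
    elif linkage == "complete":
        cliques = [set(c) for c in nx.find_cliques(graph) if len(c) >= 2]
        cliques.sort(key=lambda c: (-len(c), sorted(c)))
        raw_groups, used = [], set()
        for c in cliques:
            if not c & used:
                raw_groups.append(c)
                used |= c
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    groups = []
    for comp in raw_groups:
        members = sorted(comp)
        sub_r = r[np.ix_(members, members)]
        sub_c = conc[np.ix_(members, members)]
        off = ~np.eye(len(members), dtype=bool)
        support = 0
        if matrix is not None:
            member_ids = [ids[m] for m in members]
            support = int(matrix.presence.loc[member_ids].all(axis=0).sum())
        groups.append(
            SegmentGroup(
                contig_ids=tuple(sorted(ids[m] for m in members)),
                min_pairwise_r=float(np.nanmin(sub_r[off])),
                min_concordance=float(sub_c[off].min()),
                support_samples=support,
            )
        )
    groups.sort(key=lambda g: g.contig_ids)
    return groups


def find_candidate_segments(
    seed_group: SegmentGroup | tuple[str, ...],
    matrix: AbundanceMatrix,
    tables: CooccurrenceTables,
) -> list[tuple[str, float]]:
    """Rank non-member contigs as candidate further segments of a group.

    Each candidate is scored by its weakest link to the group — the
    minimum correlation over seed members — so that a high score requires
    co-occurrence with every established segment.  Ties break by mean r,
    then mean concordance with the group, then contig id.  Seed members
    are excluded; NaN correlations (constant vectors) rank last.
    """
    seed_ids = list(
        seed_group.contig_ids if isinstance(seed_group, SegmentGroup) else seed_group
    )
    if not seed_ids:
        raise ValueError("seed group is empty")
    missing = set(seed_ids) - set(tables.r.index)
    if missing:
        raise ValueError(f"seed contigs absent from matrix: {sorted(missing)}")
    candidates = [c for c in tables.r.index if c not in set(seed_ids)]
    r_block = tables.r.loc[candidates, seed_ids].values
    conc_block = tables.concordance.loc[candidates, seed_ids].values
    filled = np.where(np.isnan(r_block), -np.inf, r_block)
    min_r = filled.min(axis=1, initial=np.inf)
    all_nan = np.all(np.isnan(r_block), axis=1)
    mean_r = np.where(all_nan, -np.inf, np.where(np.isnan(r_block), 0.0, r_block).sum(axis=1)
                      / np.maximum((~np.isnan(r_block)).sum(axis=1), 1))
    mean_conc = conc_block.mean(axis=1)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-min_r[i], -mean_r[i], -mean_conc[i], candidates[i]),
    )
    return [(candidates[i], float(min_r[i])) for i in order]
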