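"""Synthetic meta-transcriptomic scenarios with known ground truth.

The generator builds the statistical world the association analysis
assumes: multiple samples (sequencing libraries) in which planted
segmented viruses are either present or absent as a whole — every segment
of a virus shares one Bernoulli presence draw per sample — and, when
present, have a per-sample abundance drawn on a log10 RPKM scale that is
shared across segments up to a within-genome jitter.  Background contigs
(host-transcript-like) get independent presence and abundance, so any
co-occurrence among them is chance.  Strand-specific read counts follow
the genome sense (+ssRNA strongly positive-biased; dsRNA and -ssRNA
weakly biased), and small-RNA profiles follow the source class (viral
replication yields 21 nt, two-stranded, contig-spanning siRNAs; host
transcripts yield broader, essentially single-stranded profiles).

Segment sequences mirror the structure of the real genomes: 1.5-2 kbp,
a single long open reading frame covering most of the segment, a 3'
poly-A tract, and a shared ~150 nt 3'-terminal motif on all but one
segment per genome.  "Sister" virus pairs carry homologous proteins at a
controlled amino-acid identity, produced by point-mutating the protein
and back-translating with uniform random synonymous codons.

Counts are fragments (read pairs) throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .annotate import count_long_orfs
from .signature import SmallRnaProfile

__all__ = [
    "ScenarioConfig",
    "Contig",
    "SegmentRecord",
    "SyntheticScenario",
    "generate_scenario",
    "generate_segment_sequences",
    "simulate_small_rna",
    "generate_biased_sequence",
    "write_scenario",
]

GENOME_SENSES = ("positive_ss", "double_stranded", "negative_ss")

# amino acid -> synonymous DNA codons, standard genetic code
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_AMINO_ACIDS = sorted(_CODONS_BY_AA)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

_DEFAULT_STRAND_FRACTIONS = {
    "positive_ss": 0.998,
    "double_stranded": 0.65,
    "negative_ss": 0.35,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Abundances are on a log10 RPKM scale; ``log10_abundance_mean`` of
    1.25 puts the median virus at ~18 RPKM, in the middle of the range
    seen for real infections.  ``genome_sense`` is a single sense applied
    to every virus or one sense per virus.  Library sizes are fragments
    (read pairs), jittered log-uniformly by a factor of
    ``library_size_jitter`` either way.
    """

    n_samples: int = 30
    n_viruses: int = 2
    segments_per_virus: int = 5
    virus_prevalence: float = 0.5
    log10_abundance_mean: float = 1.25
    log10_abundance_sd: float = 1.0
    segment_rel_abundance_sd: float = 0.3
    genome_sense: str | tuple[str, ...] = "positive_ss"
    strand_fraction_by_sense: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STRAND_FRACTIONS)
    )
    n_background_contigs: int = 200
    background_prevalence: float = 0.5
    background_strand_fraction: float = 0.99
    target_aa_identity: float = 0.64
    segment_length_range: tuple[int, int] = (1500, 2000)
    background_length_range: tuple[int, int] = (800, 3000)
    motif_length: int = 150
    polya_length: int = 15
    orf_coding_fraction: float = 0.72
    library_size: int = 10_000_000
    library_size_jitter: float = 3.0
    srna_depth: int = 10_000
    include_sequences: bool = True
    include_small_rna: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_viruses < 0 or self.n_background_contigs < 0:
            raise ValueError("counts must be non-negative (>=1 sample)")
        if self.segments_per_virus < 1:
            raise ValueError("segments_per_virus must be >= 1")
        for name in ("virus_prevalence", "background_prevalence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for sense, frac in self.strand_fraction_by_sense.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"strand fraction for {sense} must be in [0,1]")
        if not 0.0 <= self.background_strand_fraction <= 1.0:
            raise ValueError("background_strand_fraction must be in [0,1]")
        if not 0.0 < self.target_aa_identity <= 1.0:
            raise ValueError("target_aa_identity must be in (0,1]")
        lo, hi = self.segment_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid segment_length_range")
        if self.motif_length >= lo:
            raise ValueError("motif_length must be shorter than the shortest segment")
        non_coding = (1.0 - self.orf_coding_fraction) * lo
        if self.motif_length + self.polya_length + 12 > non_coding:
            raise ValueError(
                "motif + poly-A tract do not fit in the non-coding share of the "
                "shortest segment"
            )
        for sense in self.senses():
            if sense not in GENOME_SENSES:
                raise ValueError(f"unknown genome sense {sense!r}")
        if self.library_size < 1 or self.library_size_jitter < 1.0:
            raise ValueError("library_size >= 1 and jitter factor >= 1 required")
        if self.srna_depth < 1:
            raise ValueError("srna_depth must be positive")

    def senses(self) -> tuple[str, ...]:
        if isinstance(self.genome_sense, str):
            return (self.genome_sense,) * self.n_viruses
        if len(self.genome_sense) != self.n_viruses:
            raise ValueError("genome_sense must be one sense or one per virus")
        return tuple(self.genome_sense)


@dataclass
class Contig:
    """One contig with its ground-truth label — the pipeline's atom."""

    contig_id: str
    length: int
    label: str  # "virus<i>:seg<j>" or "background"
    sense: str | None = None  # genome sense for virus segments
    sequence: str | None = None
    protein: str | None = None

    @property
    def is_viral(self) -> bool:
        return self.label != "background"


@dataclass(frozen=True)
class SegmentRecord:
    """A generated segment: nucleotide sequence plus encoded protein."""

    virus_index: int
    segment_index: int
    sequence: str
    protein: str
    has_motif: bool


@dataclass
class SyntheticScenario:
    """A generated world plus the observations the pipeline sees."""

    config: ScenarioConfig
    contigs: list[Contig]
    count_table: pd.DataFrame  # contig x sample, fragments
    library_sizes: pd.Series  # per sample, fragments
    strand_pos: pd.DataFrame  # contig x sample
    strand_neg: pd.DataFrame
    small_rna: dict[str, SmallRnaProfile]
    truth: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.count_table.columns)

    def lengths(self) -> pd.Series:
        return pd.Series(
            {c.contig_id: c.length for c in self.contigs}, name="length"
        ).loc[list(self.count_table.index)]

    def truth_labels(self) -> list[str]:
        """Cluster labels for scoring: one class per virus, singleton per
        background contig."""
        out = []
        for c in self.contigs:
            out.append(c.label.split(":")[0] if c.is_viral else f"bg:{c.contig_id}")
        return out

    def strand_counts_long(self) -> pd.DataFrame:
        """Per-contig pooled strand counts (columns contig_id, pos, neg)."""
        return pd.DataFrame(
            {
                "contig_id": list(self.strand_pos.index),
                "pos": self.strand_pos.sum(axis=1).astype(int).values,
                "neg": self.strand_neg.sum(axis=1).astype(int).values,
            }
        )


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _mutate_protein(
    protein: str, target_identity: float, rng: np.random.Generator
) -> str:
    # the initiator methionine is never mutated (it is the start codon)
    n_mut = min(int(round((1.0 - target_identity) * len(protein))), len(protein) - 1)
    sites = 1 + rng.choice(len(protein) - 1, size=n_mut, replace=False)
    residues = list(protein)
    for s in sites:
        choices = [a for a in _AMINO_ACIDS if a != residues[s]]
        residues[s] = choices[rng.integers(len(choices))]
    return "".join(residues)


def _assemble_segment(
    protein: str,
    length: int,
    motif: str | None,
    config: ScenarioConfig,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> str:
    """Lay out 5'UTR | ORF (M...stop) | spacer | motif | poly-A.

    The protein starts with its initiator methionine, whose sole codon is
    the ATG start.  The random parts (UTRs, codon choices) are resampled
    until the segment carries exactly one ORF of >= 300 nt across all six
    frames, matching the single-ORF structure of the real segments.
    """
    if not protein.startswith("M"):
        raise ValueError("segment protein must start with methionine")
    orf_nt = 3 * (len(protein) + 1)
    tail = (motif or "") + "A" * config.polya_length
    non_coding = length - orf_nt - len(tail)
    if non_coding < 5:
        raise ValueError("segment too short for requested ORF and 3' elements")
    from .annotate import find_longest_orf

    for _ in range(max_tries):
        utr5_len = int(rng.integers(4, max(5, non_coding)))
        utr5_len = min(utr5_len, non_coding)
        spacer_len = non_coding - utr5_len
        # in-frame stop at the UTR end blocks upstream extension of the ORF
        utr5 = _random_nt(rng, utr5_len - 3) + "TAA"
        seq = (
            utr5
            + _back_translate(protein, rng)
            + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
            + _random_nt(rng, spacer_len)
            + tail
        )
        if count_long_orfs(seq) == 1:
            best = find_longest_orf(seq)
            if best is not None and best.protein == protein:
                return seq
    raise RuntimeError("could not assemble a single-ORF segment")


def generate_segment_sequences(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[list[SegmentRecord]]:
    """Generate segment sequences for every virus in the scenario.

    Viruses are generated in sister pairs (virus 2k+1 derives from virus
    2k): the pair's proteins are homologous at ``target_aa_identity``,
    realised by mutating a controlled fraction of residues and
    back-translating with uniform synonymous codons.  Within each genome
    all segments but the second carry the genome's shared 3' motif,
    placed between the ORF and the poly-A tract; sister genomes have the
    same motif layout but independent motif sequences.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.segment_length_range
    viruses: list[list[SegmentRecord]] = []
    base_proteins: list[str] | None = None
    base_lengths: list[int] | None = None
    for v in range(config.n_viruses):
        # two non-A final bases keep the motif / poly-A boundary exact even
        # under the tail detector's single-mismatch allowance
        motif = _random_nt(rng, config.motif_length - 2) + "".join(
            rng.choice(list("CGT"), size=2)
        )
        records: list[SegmentRecord] = []
        is_sister = v % 2 == 1 and base_proteins is not None
        proteins: list[str] = []
        lengths: list[int] = []
        for s in range(config.segments_per_virus):
            if is_sister:
                # homologous segments keep their partner's length
                length = base_lengths[s]
                protein = _mutate_protein(
                    base_proteins[s], config.target_aa_identity, rng
                )
            else:
                length = int(rng.integers(lo, hi + 1))
                max_protein = (
                    length
                    - config.motif_length
                    - config.polya_length
                    - 12  # minimal UTR/spacer slack
                ) // 3 - 2
                target_protein = int(
                    round((config.orf_coding_fraction * length - 6) / 3)
                )
                n_aa = min(target_protein, max_protein)
                if n_aa < 2:
                    raise ValueError("segment too short for a coding region")
                protein = "M" + "".join(rng.choice(_AMINO_ACIDS, size=n_aa - 1))
            proteins.append(protein)
            lengths.append(length)
            has_motif = config.segments_per_virus < 2 or s != 1
            seq = _assemble_segment(
                protein, length, motif if has_motif else None, config, rng
            )
            records.append(
                SegmentRecord(
                    virus_index=v,
                    segment_index=s,
                    sequence=seq,
                    protein=protein,
                    has_motif=has_motif,
                )
            )
        if v % 2 == 0:
            base_proteins = proteins
            base_lengths = lengths
        viruses.append(records)
    return viruses


def simulate_small_rna(
    contig_id: str,
    contig_length: int,
    source_class: str,
    depth: int,
    seed: int | np.random.Generator = 0,
    window: int = 100,
) -> SmallRnaProfile:
    """Simulate a small-RNA length x strand histogram for one contig.

    ``viral_replicating`` mimics Dicer-2 processing of replicating viral
    dsRNA: ~80% of reads at 21 nt, both strands near 50/50, read starts
    uniform along the contig.  ``host_transcript`` mimics host mRNA
    degradation/miRNA-like profiles: a broad 18-30 nt length spread, at
    least ~97% of reads on one strand, and starts clustered at a few
    hotspot loci.  Deterministic given the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_windows = max(1, -(-contig_length // window))

    if source_class == "viral_replicating":
        lengths_support = np.array([19, 20, 21, 22, 23])
        length_probs = np.array([0.05, 0.075, 0.8, 0.05, 0.025])
        pos_frac = rng.uniform(0.4, 0.6)
        n_pos = int(rng.binomial(depth, pos_frac))
        starts = {
            "+": rng.integers(0, contig_length, size=n_pos),
            "-": rng.integers(0, contig_length, size=depth - n_pos),
        }
    elif source_class == "host_transcript":
        lengths_support = np.arange(18, 31)
        length_probs = np.full(13, 1 / 13.0)
        minority_frac = rng.uniform(0.0, 0.03)
        n_minor = int(rng.binomial(depth, minority_frac))
        n_loci = max(2, contig_length // 500)
        loci = rng.integers(0, contig_length, size=n_loci)
        def hotspot_starts(n: int) -> np.ndarray:
            picks = loci[rng.integers(0, n_loci, size=n)]
            jitter = rng.integers(-10, 11, size=n)
            return np.clip(picks + jitter, 0, contig_length - 1)
        starts = {"+": hotspot_starts(depth - n_minor), "-": hotspot_starts(n_minor)}
    else:
        raise ValueError(f"unknown source_class {source_class!r}")

    histogram: dict[tuple[int, str], int] = {}
    breadth: dict[str, float] = {}
    for strand in ("+", "-"):
        n_reads = len(starts[strand])
        if n_reads:
            drawn = rng.choice(lengths_support, size=n_reads, p=length_probs)
            lens, counts = np.unique(drawn, return_counts=True)
            for l, c in zip(lens, counts):
                histogram[(int(l), strand)] = int(c)
        hit = np.unique(starts[strand] // window)
        breadth[strand] = len(hit) / n_windows
    return SmallRnaProfile(contig_id=contig_id, histogram=histogram, breadth=breadth)


def generate_biased_sequence(
    length: int,
    gc: float = 0.5,
    cpg_factor: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> str:
    """Random sequence from a first-order Markov chain with tunable
    GC content and CpG enrichment/suppression (``cpg_factor`` multiplies
    the CG transition weight).  Used to plant composition classes."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    nts = np.array(list("ACGT"))
    trans = np.tile(base_p, (4, 1))
    trans[1, 2] *= cpg_factor  # C -> G
    trans /= trans.sum(axis=1, keepdims=True)
    out = np.empty(length, dtype="U1")
    state = rng.choice(4, p=base_p)
    out[0] = nts[state]
    for i in range(1, length):
        state = rng.choice(4, p=trans[state])
        out[i] = nts[state]
    return "".join(out)


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Generate a full scenario: contigs, counts, strand counts, small RNA.

    Per virus and sample a single Bernoulli(prevalence) draw decides
    presence of ALL its segments; present samples draw a virus abundance
    of 10^Normal(mean, sd) RPKM shared by the segments up to a
    10^Normal(0, segment_rel_abundance_sd) per-segment factor.  Fragment
    counts are round(RPKM x length_kb x library_size/1e6).  Strand counts
    are Binomial(total, strand fraction for the genome sense).  If a
    sample's contig fragments would exceed its library size they are
    rescaled proportionally (competition for the sequencer).
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    senses = config.senses()

    contigs: list[Contig] = []
    if config.include_sequences and config.n_viruses > 0:
        seg_seqs = generate_segment_sequences(config, rng)
    else:
        seg_seqs = None
    lo, hi = config.segment_length_range
    for v in range(config.n_viruses):
        for s in range(config.segments_per_virus):
            if seg_seqs is not None:
                rec = seg_seqs[v][s]
                seq, prot, length = rec.sequence, rec.protein, len(rec.sequence)
            else:
                seq, prot, length = None, None, int(rng.integers(lo, hi + 1))
            contigs.append(
                Contig(
                    contig_id=f"virus{v}_seg{s}",
                    length=length,
                    label=f"virus{v}:seg{s}",
                    sense=senses[v],
                    sequence=seq,
                    protein=prot,
                )
            )
    blo, bhi = config.background_length_range
    for b in range(config.n_background_contigs):
        length = int(rng.integers(blo, bhi + 1))
        seq = None
        if config.include_sequences:
            seq = _random_nt(rng, length - config.polya_length) + "A" * config.polya_length
        contigs.append(
            Contig(contig_id=f"bg{b:04d}", length=length, label="background", sequence=seq)
        )

    sample_ids = [f"sample{s:03d}" for s in range(config.n_samples)]
    library_sizes = pd.Series(
        np.round(
            config.library_size
            * config.library_size_jitter
            ** rng.uniform(-1.0, 1.0, size=config.n_samples)
        ).astype(np.int64),
        index=sample_ids,
        name="fragments",
    )

    contig_ids = [c.contig_id for c in contigs]
    lengths_kb = np.array([c.length / 1000.0 for c in contigs])
    per_million = library_sizes.values / 1e6

    rpkm = np.zeros((len(contigs), config.n_samples))
    row = 0
    for v in range(config.n_viruses):
        present = rng.random(config.n_samples) < config.virus_prevalence
        virus_ab = np.where(
            present,
            10.0
            ** rng.normal(
                config.log10_abundance_mean,
                config.log10_abundance_sd,
                size=config.n_samples,
            ),
            0.0,
        )
        for s in range(config.segments_per_virus):
            jitter = 10.0 ** rng.normal(
                0.0, config.segment_rel_abundance_sd, size=config.n_samples
            )
            rpkm[row] = virus_ab * jitter
            row += 1
    for b in range(config.n_background_contigs):
        present = rng.random(config.n_samples) < config.background_prevalence
        rpkm[row] = np.where(
            present,
            10.0
            ** rng.normal(
                config.log10_abundance_mean,
                config.log10_abundance_sd,
                size=config.n_samples,
            ),
            0.0,
        )
        row += 1

    counts = np.round(rpkm * lengths_kb[:, None] * per_million[None, :]).astype(np.int64)
    # competition for the library: never exceed the sample's total fragments
    totals = counts.sum(axis=0)
    over = totals > library_sizes.values
    if over.any():
        scale = library_sizes.values[over] / totals[over]
        counts[:, over] = np.floor(counts[:, over] * scale[None, :]).astype(np.int64)

    strand_frac = np.array(
        [
            config.strand_fraction_by_sense[c.sense]
            if c.is_viral
            else config.background_strand_fraction
            for c in contigs
        ]
    )
    pos = rng.binomial(counts, strand_frac[:, None])
    neg = counts - pos

    small_rna: dict[str, SmallRnaProfile] = {}
    if config.include_small_rna:
        for c in contigs:
            source = "viral_replicating" if c.is_viral else "host_transcript"
            small_rna[c.contig_id] = simulate_small_rna(
                c.contig_id, c.length, source, config.srna_depth, rng
            )

    count_table = pd.DataFrame(counts, index=contig_ids, columns=sample_ids)
    return SyntheticScenario(
        config=config,
        contigs=contigs,
        count_table=count_table,
        library_sizes=library_sizes,
        strand_pos=pd.DataFrame(pos, index=contig_ids, columns=sample_ids),
        strand_neg=pd.DataFrame(neg, index=contig_ids, columns=sample_ids),
        small_rna=small_rna,
        truth={c.contig_id: c.label for c in contigs},
    )


def write_scenario(scenario: SyntheticScenario, outdir) -> None:
    """Write a scenario in the pipeline's on-disk formats.

    contigs.fasta, counts.tsv (long, non-zero rows), libsizes.tsv,
    strand.tsv, srna/<contig>.tsv (with per-strand breadth in comment
    headers), truth.tsv.
    """
    from pathlib import Path

    from . import io as stio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if any(c.sequence for c in scenario.contigs):
        with open(out / "contigs.fasta", "w") as fh:
            for c in scenario.contigs:
                if c.sequence:
                    fh.write(f">{c.contig_id}\n")
                    for i in range(0, len(c.sequence), 70):
                        fh.write(c.sequence[i : i + 70] + "\n")
    long = (
        scenario.count_table.stack()
        .rename_axis(["contig_id", "sample_id"])
        .rename("fragments")
        .reset_index()
    )
    stio.write_counts_table(long[long["fragments"] > 0], out / "counts.tsv")
    scenario.library_sizes.rename_axis("sample_id").reset_index().to_csv(
        out / "libsizes.tsv", sep="\t", index=False
    )
    pos = scenario.strand_pos.stack().rename("pos")
    neg = scenario.strand_neg.stack().rename("neg")
    strand = pd.concat([pos, neg], axis=1).rename_axis(["contig_id", "sample_id"]).reset_index()
    strand[(strand["pos"] > 0) | (strand["neg"] > 0)].to_csv(
        out / "strand.tsv", sep="\t", index=False
    )
    if scenario.small_rna:
        srna_dir = out / "srna"
        srna_dir.mkdir(exist_ok=True)
        for cid, profile in scenario.small_rna.items():
            stio.write_srna_profile(profile, srna_dir / f"{cid}.tsv")
    truth = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in scenario.contigs],
            "label": [c.label for c in scenario.contigs],
            "sense": [c.sense or "" for c in scenario.contigs],
            "length": [c.length for c in scenario.contigs],
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
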