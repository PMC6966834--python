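"""Tab-separated input/output formats used across the pipeline.

All tables are UTF-8 TSV with headers.  Counts are fragments (read
pairs) and must be non-negative integers; duplicate (contig, sample)
keys are rejected rather than silently summed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .signature import SmallRnaProfile

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_library_sizes",
    "read_strand_table",
    "read_srna_profile",
    "write_srna_profile",
    "read_fasta_lengths",
    "read_homology_flags",
]


def read_counts_table(path) -> pd.DataFrame:
    """Read a long-format count table (contig_id, sample_id, fragments)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    required = {"contig_id", "sample_id", "fragments"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    frag = pd.to_numeric(df["fragments"], errors="coerce")
    if frag.isna().any() or not (frag == frag.round()).all():
        bad = df.loc[frag.isna() | (frag != frag.round())].index.tolist()
        raise ValueError(f"{path}: non-integer fragment counts at rows {bad}")
    df["fragments"] = frag.astype(int)
    if (df["fragments"] < 0).any():
        bad = df.loc[df["fragments"] < 0].index.tolist()
        raise ValueError(f"{path}: negative fragment counts at rows {bad}")
    dup = df.duplicated(subset=["contig_id", "sample_id"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["contig_id", "sample_id"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise ValueError(
            f"{path}: duplicate (contig, sample) rows: "
            + ", ".join(f"({k.contig_id}, {k.sample_id})" for k in keys)
        )
    return df


def write_counts_table(counts: pd.DataFrame, path) -> None:
    if (counts["fragments"] < 0).any():
        raise ValueError("negative fragment counts")
    counts[["contig_id", "sample_id", "fragments"]].to_csv(path, sep="\t", index=False)


def read_library_sizes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "fragments"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, fragments")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    sizes = df.set_index("sample_id")["fragments"].astype(int)
    if (sizes <= 0).any():
        raise ValueError(f"{path}: library sizes must be positive")
    return sizes


def read_strand_table(path) -> pd.DataFrame:
    """Read per-contig (optionally per-sample) strand counts.

    Columns contig_id, [sample_id,] pos, neg; returns pooled per-contig
    counts with columns (contig_id, pos, neg).
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    if not {"contig_id", "pos", "neg"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns contig_id, pos, neg")
    if (df[["pos", "neg"]] < 0).any().any():
        raise ValueError(f"{path}: negative strand counts")
    pooled = df.groupby("contig_id", as_index=False)[["pos", "neg"]].sum()
    return pooled


def write_srna_profile(profile: SmallRnaProfile, path) -> None:
    with open(path, "w") as fh:
        for strand in ("+", "-"):
            fh.write(f"# breadth_{'pos' if strand == '+' else 'neg'}\t"
                     f"{profile.breadth.get(strand, 0.0):.6g}\n")
        fh.write("length\tstrand\tcount\n")
        for (length, strand), count in sorted(profile.histogram.items()):
            fh.write(f"{length}\t{strand}\t{count}\n")


def read_srna_profile(path, contig_id: str | None = None) -> SmallRnaProfile:
    path = Path(path)
    breadth = {"+": 0.0, "-": 0.0}
    rows: list[tuple[int, str, int]] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                strand = "+" if key.strip().endswith("pos") else "-"
                breadth[strand] = float(val)
                continue
            if not header_seen:
                if line.split("\t") != ["length", "strand", "count"]:
                    raise ValueError(f"{path}: expected header length/strand/count")
                header_seen = True
                continue
            length_s, strand, count_s = line.split("\t")
            rows.append((int(length_s), strand, int(count_s)))
    histogram = {(l, s): c for l, s, c in rows}
    if len(histogram) != len(rows):
        raise ValueError(f"{path}: duplicate (length, strand) rows")
    return SmallRnaProfile(
        contig_id=contig_id or path.stem, histogram=histogram, breadth=breadth
    )


def read_fasta_lengths(path) -> tuple[dict[str, str], pd.Series]:
    """Read FASTA; returns ({id: sequence}, lengths Series)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    lengths = pd.Series({k: len(v) for k, v in seqs.items()}, name="length")
    return seqs, lengths


def read_homology_flags(path) -> pd.DataFrame:
    """Optional per-contig flags (contig_id, has_homology, present_in_dna)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    if "contig_id" not in df.columns:
        raise ValueError(f"{path}: expected a contig_id column")
    for col in ("has_homology", "present_in_dna"):
        if col not in df.columns:
            df[col] = False
        else:
            df[col] = df[col].astype(bool)
    if df["contig_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate contig ids")
    return df.set_index("contig_id")[["has_homology", "present_in_dna"]]
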