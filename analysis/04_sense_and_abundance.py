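#!/usr/bin/env python
"""Infer genome sense per segment group and summarise abundance.

Pools strand-specific fragment counts over each group's members, calls
the genome sense from the Clopper-Pearson interval of the
positive-strand fraction, and summarises per-sample group RPKM.
"""

from pathlib import Path

import pandas as pd

from segtangle import io as stio
from segtangle.cooccur import build_abundance_matrix
from segtangle.strandsense import abundance_summary, call_group_sense

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scenario = BASE / "scenario"
    strand = stio.read_strand_table(scenario / "strand.tsv")
    groups_df = pd.read_csv(BASE / "groups.tsv", sep="\t")
    counts = stio.read_counts_table(scenario / "counts.tsv")
    libsizes = stio.read_library_sizes(scenario / "libsizes.tsv")
    _, lengths = stio.read_fasta_lengths(scenario / "contigs.fasta")
    matrix = build_abundance_matrix(counts, lengths, libsizes)

    groups = [tuple(sub["contig_id"]) for _, sub in groups_df.groupby("group_id")]
    rows = []
    for gi, members in enumerate(groups):
        call = call_group_sense(members, strand, group_id=f"group{gi}")
        rows.append({
            "id": call.id,
            "pos_frac": round(call.positive_fraction, 4),
            "ci_low": round(call.ci_low, 4),
            "ci_high": round(call.ci_high, 4),
            "n_fragments": call.n_fragments,
            "call": call.call,
        })
        print(f"group {gi}: {100 * call.positive_fraction:.1f}% positive-strand "
              f"reads over {call.n_fragments:,} fragments -> {call.call}")
    pd.DataFrame(rows).to_csv(BASE / "sense.tsv", sep="\t", index=False)

    summary = abundance_summary(matrix, groups)
    summary.to_csv(BASE / "abundance.tsv", sep="\t", index=False)
    for row in summary.itertuples(index=False):
        print(f"group {row.group_id}: RPKM {row.min_rpkm:.2f} - {row.max_rpkm:.1f} "
              f"(median {row.median_rpkm:.1f}) over {row.n_support_samples} samples; "
              f"up to {100 * row.max_library_fraction:.2f}% of a library")
    print(f"wrote {BASE / 'sense.tsv'} and {BASE / 'abundance.tsv'}")


if __name__ == "__main__":
    main()
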