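#!/usr/bin/env python
"""Apply the dark-virus candidate filter to the simulated world.

For every contig: score its small-RNA profile against the viRNA signature
(21 nt peak, both strands, contig-spanning) and apply the presence rules
(>= 1 kbp, RNA-only, long ORF, no homology).  Writes per-contig decisions
and reports sensitivity/specificity against ground truth.
"""

from pathlib import Path

import pandas as pd

from segtangle import io as stio
from segtangle.annotate import find_longest_orf
from segtangle.signature import classify_dark_candidate, score_small_rna

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scenario = BASE / "scenario"
    seqs, _ = stio.read_fasta_lengths(scenario / "contigs.fasta")
    truth = pd.read_csv(scenario / "truth.tsv", sep="\t").set_index("contig_id")

    rows = []
    for cid, seq in seqs.items():
        sig = score_small_rna(stio.read_srna_profile(scenario / "srna" / f"{cid}.tsv", cid))
        dec = classify_dark_candidate(
            cid, len(seq), present_in_dna=False, has_homology=False,
            orf=find_longest_orf(seq), sig=sig,
        )
        rows.append({
            "contig_id": cid,
            "passed": dec.passed,
            "reasons": ";".join(dec.reasons),
            "frac_21nt": round(sig.frac_21nt, 4),
            "minority_strand_frac": round(sig.minority_strand_frac, 4),
            "min_strand_breadth": round(sig.min_strand_breadth, 4),
            "is_viral_truth": truth.loc[cid, "label"] != "background",
        })
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "decisions.tsv", sep="\t", index=False)

    viral = df[df["is_viral_truth"]]
    background = df[~df["is_viral_truth"]]
    sens = viral["passed"].mean()
    spec = (~background["passed"]).mean()
    print(f"dark filter: {df['passed'].sum()}/{len(df)} contigs passed")
    print(f"sensitivity {sens:.3f} ({viral['passed'].sum()}/{len(viral)} viral segments kept)")
    print(f"specificity {spec:.3f} ({(~background['passed']).sum()}/{len(background)} background rejected)")
    print(f"wrote {BASE / 'decisions.tsv'}")


if __name__ == "__main__":
    main()
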