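#!/usr/bin/env python
"""Generate the study world: two sister 5-segment +ssRNA viruses, 30 samples.

Writes the scenario (contigs.fasta, counts.tsv, libsizes.tsv, strand.tsv,
srna/, truth.tsv) to results/scenario/ for the downstream analysis steps.
"""

from pathlib import Path

from segtangle.synthetic import ScenarioConfig, generate_scenario, write_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "scenario"
SEED = 2020


def main() -> None:
    config = ScenarioConfig(n_viruses=2, n_background_contigs=200, seed=SEED)
    scenario = generate_scenario(config)
    write_scenario(scenario, OUT)

    n_viral = sum(c.is_viral for c in scenario.contigs)
    occupancy = (scenario.count_table > 0).mean(axis=1)
    print(f"world: {len(scenario.contigs)} contigs "
          f"({n_viral} viral segments, {len(scenario.contigs) - n_viral} background), "
          f"{config.n_samples} samples")
    print(f"library sizes: {scenario.library_sizes.min():,} - "
          f"{scenario.library_sizes.max():,} fragments")
    print(f"viral segment sample-occupancy: "
          f"{occupancy[[c.contig_id for c in scenario.contigs if c.is_viral]].mean():.2f} "
          f"(prevalence {config.virus_prevalence})")
    print(f"wrote scenario to {OUT}")


if __name__ == "__main__":
    main()
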