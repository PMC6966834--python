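import numpy as np
import pytest

from segtangle.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def one_virus_scenario():
    """A planted one-virus world: 5 segments + 30 background, 30 samples."""
    config = ScenarioConfig(
        n_viruses=1,
        n_background_contigs=30,
        n_samples=30,
        seed=11,
    )
    return generate_scenario(config)


@pytest.fixture(scope="session")
def lean_scenario_factory():
    """Factory for scenarios without sequences/small RNA (fast, counts only)."""

    def make(seed: int, **overrides) -> object:
        kwargs = dict(
            n_viruses=1,
            n_samples=30,
            virus_prevalence=0.5,
            log10_abundance_sd=1.0,
            n_background_contigs=200,
            include_sequences=False,
            include_small_rna=False,
            seed=seed,
        )
        kwargs.update(overrides)
        return generate_scenario(ScenarioConfig(**kwargs))

    return make


def counts_long(scenario):
    """Long-format count table for build_abundance_matrix."""
    return (
        scenario.count_table.stack()
        .rename_axis(["contig_id", "sample_id"])
        .rename("fragments")
        .reset_index()
    )
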