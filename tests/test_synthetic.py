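"""The scenario generator: distributions, determinism, sequence structure."""

import numpy as np
import pytest

from segtangle.annotate import find_longest_orf, global_align_identity, polya_tail
from segtangle.signature import score_small_rna
from segtangle.synthetic import (
    ScenarioConfig,
    generate_scenario,
    generate_segment_sequences,
    simulate_small_rna,
)


LEAN = dict(include_sequences=False, include_small_rna=False)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ScenarioConfig(segments_per_virus=0)
    with pytest.raises(ValueError):
        ScenarioConfig(virus_prevalence=1.5)
    with pytest.raises(ValueError):
        ScenarioConfig(target_aa_identity=0.0)
    with pytest.raises(ValueError):
        ScenarioConfig(motif_length=1500, segment_length_range=(1500, 2000))
    with pytest.raises(ValueError):
        ScenarioConfig(genome_sense="circular")


def test_noise_free_scenario_everywhere_identical():
    config = ScenarioConfig(
        n_viruses=1, virus_prevalence=1.0, log10_abundance_sd=0.0,
        segment_rel_abundance_sd=0.0, n_background_contigs=0,
        library_size_jitter=1.0, seed=0, **LEAN,
    )
    sc = generate_scenario(config)
    rpkm = sc.count_table.div(sc.lengths() / 1000, axis=0).div(
        sc.library_sizes / 1e6, axis=1
    )
    # every segment present in all samples at its (rounding-limited) RPKM
    assert (sc.count_table.values > 0).all()
    per_contig_spread = rpkm.max(axis=1) - rpkm.min(axis=1)
    assert (per_contig_spread / rpkm.mean(axis=1) < 0.01).all()


def test_same_seed_identical_different_seed_differs():
    config = ScenarioConfig(seed=42, n_background_contigs=20)
    a = generate_scenario(config)
    b = generate_scenario(config)
    assert a.count_table.equals(b.count_table)
    assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
    c = generate_scenario(ScenarioConfig(seed=43, n_background_contigs=20))
    assert not a.count_table.equals(c.count_table)


def test_presence_fraction_matches_binomial_law():
    n = 10_000
    config = ScenarioConfig(
        n_samples=n, n_viruses=1, virus_prevalence=0.5,
        n_background_contigs=0, seed=77, **LEAN,
    )
    sc = generate_scenario(config)
    present = (sc.count_table.loc["virus0_seg0"] > 0).mean()
    se = np.sqrt(0.25 / n)
    assert abs(present - 0.5) <= 3 * se


def test_segments_share_presence_pattern():
    sc = generate_scenario(ScenarioConfig(n_viruses=2, seed=5, n_background_contigs=0, **LEAN))
    for v in range(2):
        seg_present = (sc.count_table.loc[[f"virus{v}_seg{s}" for s in range(5)]] > 0)
        # a segment can drop to zero fragments by rounding, but never appear
        # in a sample its virus does not infect
        union = seg_present.any(axis=0)
        for s in range(5):
            assert not (seg_present.iloc[s] & ~union).any()


def test_log_abundance_recovers_config_mean():
    config = ScenarioConfig(
        n_samples=2000, n_viruses=1, segments_per_virus=1,
        virus_prevalence=1.0, log10_abundance_mean=1.25,
        log10_abundance_sd=1.0, segment_rel_abundance_sd=0.0,
        n_background_contigs=0, seed=3, **LEAN,
    )
    sc = generate_scenario(config)
    rpkm = sc.count_table.div(sc.lengths() / 1000, axis=0).div(
        sc.library_sizes / 1e6, axis=1
    )
    vals = np.log10(rpkm.values[rpkm.values > 0])
    se = 1.0 / np.sqrt(len(vals))
    assert abs(vals.mean() - 1.25) <= 3.5 * se  # slight upward censoring at 0


def test_count_conservation_and_library_bound(one_virus_scenario):
    sc = one_virus_scenario
    assert ((sc.strand_pos + sc.strand_neg) == sc.count_table).all().all()
    assert (sc.count_table.sum(axis=0) <= sc.library_sizes).all()


def test_every_contig_labelled(one_virus_scenario):
    sc = one_virus_scenario
    assert set(sc.truth) == set(sc.count_table.index)
    assert all(v == "background" or v.startswith("virus") for v in sc.truth.values())


# ------------------------------------------------------------- sequences


def test_segment_structure_single_orf_polya_motif():
    config = ScenarioConfig(n_viruses=2, seed=1, include_small_rna=False,
                            n_background_contigs=0)
    viruses = generate_segment_sequences(config)
    for segments in viruses:
        for rec in segments:
            orf = find_longest_orf(rec.sequence)
            assert orf is not None and orf.n_long_orfs == 1
            assert orf.coding_fraction >= 0.70
            assert orf.protein == rec.protein
            present, tail = polya_tail(rec.sequence)
            assert present and tail >= config.polya_length
        assert [r.has_motif for r in segments] == [True, False, True, True, True]
        # shared motif: all motif-bearing segments end identically before the tail
        cores = [
            r.sequence[: len(r.sequence) - polya_tail(r.sequence)[1]]
            for r in segments
            if r.has_motif
        ]
        motifs = {c[-config.motif_length:] for c in cores}
        assert len(motifs) == 1


def test_identity_one_gives_identical_sisters():
    config = ScenarioConfig(n_viruses=2, target_aa_identity=1.0, seed=2,
                            include_small_rna=False, n_background_contigs=0)
    viruses = generate_segment_sequences(config)
    for a, b in zip(viruses[0], viruses[1]):
        assert a.protein == b.protein


def test_sister_identity_near_target():
    vals = []
    for seed in range(6):
        config = ScenarioConfig(n_viruses=2, target_aa_identity=0.64, seed=seed,
                                include_small_rna=False, n_background_contigs=0)
        viruses = generate_segment_sequences(config)
        for a, b in zip(viruses[0], viruses[1]):
            vals.append(global_align_identity(a.protein, b.protein).percent_identity)
    assert abs(np.mean(vals) - 64.0) <= 3.0


# ------------------------------------------------------------- small RNA


def test_viral_srna_profile_properties():
    p = simulate_small_rna("c", 1600, "viral_replicating", 10_000, seed=0)
    sig = score_small_rna(p)
    assert sig.frac_21nt >= 0.7
    assert sig.minority_strand_frac >= 0.2
    assert sig.min_strand_breadth >= 0.9  # uniform starts cover both strands


def test_host_srna_profile_properties():
    p = simulate_small_rna("c", 1600, "host_transcript", 10_000, seed=0)
    sig = score_small_rna(p)
    assert sig.minority_strand_frac <= 0.05
    assert sig.frac_21nt < 0.5


def test_srna_deterministic_and_validated():
    a = simulate_small_rna("c", 1600, "viral_replicating", 5000, seed=9)
    b = simulate_small_rna("c", 1600, "viral_replicating", 5000, seed=9)
    assert a.histogram == b.histogram and a.breadth == b.breadth
    with pytest.raises(ValueError):
        simulate_small_rna("c", 1600, "mystery_class", 100)
    with pytest.raises(ValueError):
        simulate_small_rna("c", 1600, "host_transcript", 0)
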