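"""RPKM arithmetic, co-occurrence tables, clustering and candidate ranking."""

import numpy as np
import pandas as pd
import pytest

from segtangle.cooccur import (
    build_abundance_matrix,
    cluster_segments,
    find_candidate_segments,
    pairwise_cooccurrence,
    rpkm,
)

RNG = np.random.default_rng(77)


# ---------------------------------------------------------------- rpkm


@pytest.mark.parametrize(
    "fragments,length,library,expected",
    [
        (1000, 1000, 10**6, 1000.0),
        (6, 2000, 18_750_000, 0.16),
        (0, 1234, 5_000_000, 0.0),
    ],
)
def test_rpkm_values(fragments, length, library, expected):
    assert rpkm(fragments, length, library) == pytest.approx(expected)


def test_rpkm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        rpkm(1, 0, 10**6)
    with pytest.raises(ValueError):
        rpkm(1, 1000, 0)
    with pytest.raises(ValueError):
        rpkm(-1, 1000, 10**6)


# ------------------------------------------------------ abundance matrix


def _toy_inputs(n_contigs=20, n_samples=6, seed=0):
    rng = np.random.default_rng(seed)
    contigs = [f"c{i}" for i in range(n_contigs)]
    samples = [f"s{j}" for j in range(n_samples)]
    rows = [
        {"contig_id": c, "sample_id": s, "fragments": int(rng.integers(0, 50))}
        for c in contigs
        for s in samples
    ]
    lengths = pd.Series(rng.integers(500, 3000, n_contigs), index=contigs)
    libs = pd.Series(rng.integers(10**6, 10**7, n_samples), index=samples)
    return pd.DataFrame(rows), lengths, libs


def test_empty_counts_yield_zero_matrix():
    counts, lengths, libs = _toy_inputs()
    empty = counts.iloc[0:0]
    m = build_abundance_matrix(empty, lengths, libs)
    assert (m.rpkm.values == 0).all()
    assert not m.presence.values.any()


def test_single_cell_matches_rpkm():
    counts = pd.DataFrame(
        [{"contig_id": "c", "sample_id": "s", "fragments": 6}]
    )
    m = build_abundance_matrix(
        counts, pd.Series({"c": 2000}), pd.Series({"s": 18_750_000})
    )
    assert m.rpkm.loc["c", "s"] == pytest.approx(0.16)


def test_matrix_cells_match_per_cell_recomputation():
    counts, lengths, libs = _toy_inputs(seed=3)
    m = build_abundance_matrix(counts, lengths, libs)
    for row in counts.itertuples(index=False):
        expected = rpkm(row.fragments, lengths[row.contig_id], libs[row.sample_id])
        assert m.rpkm.loc[row.contig_id, row.sample_id] == pytest.approx(expected)
        assert m.presence.loc[row.contig_id, row.sample_id] == (row.fragments >= 5)


def test_unknown_ids_rejected():
    counts, lengths, libs = _toy_inputs()
    with pytest.raises(ValueError, match="lengths"):
        build_abundance_matrix(counts, lengths.drop("c0"), libs)
    with pytest.raises(ValueError, match="library"):
        build_abundance_matrix(counts, lengths, libs.drop("s0"))


# --------------------------------------------------------- co-occurrence


def _matrix_from_rpkm(rpkm_values, presence_min=5):
    contigs = [f"c{i}" for i in range(rpkm_values.shape[0])]
    samples = [f"s{j}" for j in range(rpkm_values.shape[1])]
    lengths = pd.Series(1000.0, index=contigs)
    libs = pd.Series(1e6, index=samples)
    frag = np.round(rpkm_values).astype(int)  # length 1 kb, lib 1 M -> rpkm == fragments
    counts = pd.DataFrame(
        [
            {"contig_id": c, "sample_id": s, "fragments": int(frag[i, j])}
            for i, c in enumerate(contigs)
            for j, s in enumerate(samples)
        ]
    )
    return build_abundance_matrix(counts, lengths, libs, presence_min)


def test_identical_vectors_r_one():
    vals = np.tile([10.0, 100.0, 0.0, 40.0], (2, 1))
    t = pairwise_cooccurrence(_matrix_from_rpkm(vals))
    assert t.r.iloc[0, 1] == pytest.approx(1.0)
    assert t.concordance.iloc[0, 1] == 1.0


def test_log_scale_anticorrelation():
    eps = 0.01
    vals = np.array([[10.0, 100.0, 1000.0], [1000.0, 100.0, 10.0]]) - eps
    t = pairwise_cooccurrence(_matrix_from_rpkm(np.vstack([vals, vals[0] * 0 + 1])))
    assert t.r.iloc[0, 1] == pytest.approx(-1.0, abs=1e-6)


def test_pairwise_matches_textbook_pearson():
    vals = RNG.lognormal(1, 2, size=(20, 8))
    m = _matrix_from_rpkm(vals)
    t = pairwise_cooccurrence(m)
    log_ab = np.log10(m.rpkm.values + 0.01)
    for i in range(0, 20, 3):
        for j in range(i + 1, 20, 3):
            x, y = log_ab[i], log_ab[j]
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            if den == 0:
                continue
            assert t.r.iloc[i, j] == pytest.approx(num / den, abs=1e-10)


def test_symmetry_and_diagonal():
    vals = RNG.lognormal(1, 2, size=(10, 6))
    t = pairwise_cooccurrence(_matrix_from_rpkm(vals))
    assert np.allclose(t.r.values, t.r.values.T, equal_nan=True)
    assert np.allclose(t.concordance.values, t.concordance.values.T)
    nonconst = ~t.constant.values
    assert np.allclose(np.diag(t.r.values)[nonconst], 1.0)


def test_constant_vector_flagged_nan():
    vals = np.vstack([np.full(5, 10.0), RNG.lognormal(1, 1, 5), RNG.lognormal(1, 1, 5)])
    t = pairwise_cooccurrence(_matrix_from_rpkm(vals))
    assert t.constant.iloc[0]
    assert np.isnan(t.r.iloc[0, 1])


def test_requires_three_samples():
    with pytest.raises(ValueError, match="3 samples"):
        pairwise_cooccurrence(_matrix_from_rpkm(np.ones((2, 2))))


# ------------------------------------------------------------ clustering


def _two_virus_matrix():
    """Two 5-segment viruses with disjoint noise-free presence patterns."""
    n_samples = 12
    pattern_a = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 0, 0], dtype=float)
    pattern_b = 1.0 - pattern_a
    rows = []
    for k in range(5):
        rows.append(pattern_a * 100 * (k + 1))
    for k in range(5):
        rows.append(pattern_b * 80 * (k + 1))
    return _matrix_from_rpkm(np.array(rows))


def test_two_planted_viruses_recovered_exactly():
    m = _two_virus_matrix()
    t = pairwise_cooccurrence(m)
    groups = cluster_segments(t, matrix=m)
    assert len(groups) == 2
    assert {g.contig_ids for g in groups} == {
        tuple(f"c{i}" for i in range(5)),
        tuple(f"c{i}" for i in range(5, 10)),
    }
    for g in groups:
        assert g.min_pairwise_r >= 0.87
        assert g.support_samples > 0


def test_unreachable_threshold_gives_no_groups(lean_scenario_factory):
    from tests.conftest import counts_long

    sc = lean_scenario_factory(5)
    m = build_abundance_matrix(counts_long(sc), sc.lengths(), sc.library_sizes)
    t = pairwise_cooccurrence(m)
    assert cluster_segments(t, r_min=1.0 + 1e-9) == []


def test_raising_r_min_only_refines():
    sc_vals = RNG.lognormal(1, 2, size=(15, 10))
    m = _matrix_from_rpkm(sc_vals)
    t = pairwise_cooccurrence(m)
    loose = cluster_segments(t, r_min=0.3, concordance_min=0.0)
    tight = cluster_segments(t, r_min=0.8, concordance_min=0.0)
    loose_sets = [set(g.contig_ids) for g in loose]
    for g in tight:
        assert any(set(g.contig_ids) <= s for s in loose_sets)


def test_clustering_invariant_to_input_order():
    m = _two_virus_matrix()
    t = pairwise_cooccurrence(m)
    groups = cluster_segments(t, matrix=m)
    perm = RNG.permutation(len(t.r))
    t.r = t.r.iloc[perm, perm]
    t.concordance = t.concordance.iloc[perm, perm]
    t.constant = t.constant.iloc[perm]
    shuffled = cluster_segments(t, matrix=m)
    assert {g.contig_ids for g in shuffled} == {g.contig_ids for g in groups}


# ------------------------------------------------------------ candidates


def test_withheld_segment_ranks_first(lean_scenario_factory):
    from tests.conftest import counts_long

    sc = lean_scenario_factory(21)
    m = build_abundance_matrix(counts_long(sc), sc.lengths(), sc.library_sizes)
    t = pairwise_cooccurrence(m)
    seed_ids = tuple(f"virus0_seg{s}" for s in range(4))
    ranked = find_candidate_segments(seed_ids, m, t)
    assert ranked[0][0] == "virus0_seg4"
    assert all(cid not in seed_ids for cid, _ in ranked)


def test_anticorrelated_candidate_scores_nonpositive():
    pattern = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    rows = [pattern * 100, pattern * 90, (1 - pattern) * 100]
    m = _matrix_from_rpkm(np.array(rows))
    t = pairwise_cooccurrence(m)
    ranked = dict(find_candidate_segments(("c0", "c1"), m, t))
    assert ranked["c2"] <= 0


def test_missing_seed_contig_rejected():
    m = _two_virus_matrix()
    t = pairwise_cooccurrence(m)
    with pytest.raises(ValueError, match="absent"):
        find_candidate_segments(("nope",), m, t)
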