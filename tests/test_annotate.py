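"""ORF finding, poly-A tails, 3' motifs and alignment identity."""

import itertools
import math

import numpy as np
import pytest

from segtangle.annotate import (
    IdentityResult,
    find_longest_orf,
    count_long_orfs,
    global_align_identity,
    polya_tail,
    reverse_complement,
    shared_terminal_motif,
    _build_aligner,
)

RNG = np.random.default_rng(20240917)


# ---------------------------------------------------------------- ORFs


def test_minimal_orf():
    orf = find_longest_orf("ATGAAATAA")
    assert orf.protein == "MK"
    assert (orf.frame, orf.start, orf.end) == (0, 0, 9)
    assert orf.coding_fraction == 1.0


def test_no_start_codon_gives_none():
    assert find_longest_orf("CCCCCCTAACCC") is None


def _orf_oracle(seq):
    """Exhaustive six-frame scan, written independently: slide a codon
    window over every frame of both strands and enumerate ATG..stop runs."""
    stops = {"TAA", "TAG", "TGA"}
    results = []
    for frame in range(6):
        strand = seq if frame < 3 else reverse_complement(seq)
        off = frame % 3
        codons = [strand[i : i + 3] for i in range(off, len(strand) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                j = i
                while j < len(codons) and codons[j] not in stops:
                    j += 1
                if j < len(codons):
                    results.append((frame, off + 3 * i, off + 3 * (j + 1)))
                    i = j
                else:
                    break
            i += 1
    return results


@pytest.mark.parametrize("trial", range(50))
def test_longest_orf_matches_exhaustive_scan(trial):
    seq = "".join(RNG.choice(list("ACGT"), size=600))
    expected = _orf_oracle(seq)
    got = find_longest_orf(seq)
    if not expected:
        assert got is None
        return
    best = max(expected, key=lambda o: (o[2] - o[1], -o[0], -o[1]))
    assert (got.frame, got.start, got.end) == best
    assert got.n_long_orfs == sum(1 for _, s, e in expected if e - s >= 300)


def test_reverse_complement_mirror():
    seq = "".join(RNG.choice(list("ACGT"), size=400))
    fwd = find_longest_orf(seq)
    rev = find_longest_orf(reverse_complement(seq))
    if fwd is None:
        assert rev is None
        return
    assert rev.protein == fwd.protein
    assert rev.nt_length == fwd.nt_length
    assert (rev.frame < 3) == (fwd.frame >= 3)


# ---------------------------------------------------------------- poly-A


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CCG" + "A" * 10, (True, 10)),
        ("CCGACGT", (False, 0)),
        ("CCG" + "AAAAGAAAA", (True, 9)),
        ("CCG" + "A" * 7, (False, 7)),
        ("A" * 8, (True, 8)),
    ],
)
def test_polya_tail_rule(seq, expected):
    assert polya_tail(seq) == expected


def test_polya_mismatch_budget():
    # two interior mismatches exceed the budget of one
    assert polya_tail("C" + "AAAGAAAGAAA") == (False, 7)
    assert polya_tail("C" + "AAAGAAAGAAA", max_mismatch=2) == (True, 11)


# ---------------------------------------------------------------- motifs


def _random_seq(n):
    return "".join(RNG.choice(list("ACGT"), size=n))


def test_motif_four_of_five():
    motif = _random_seq(150)
    seqs = {f"s{i}": _random_seq(400) + motif + "A" * 12 for i in range(4)}
    seqs["odd"] = _random_seq(550) + "A" * 12
    report = shared_terminal_motif(seqs)
    assert set(report.member_ids) == {"s0", "s1", "s2", "s3"}
    assert report.motif_length >= 150


def test_motif_identical_pair_spans_window():
    s = _random_seq(400)
    report = shared_terminal_motif({"a": s, "b": s}, window=200)
    assert report.member_ids == ("a", "b")
    assert report.motif_length == 200
    assert report.consensus == s[-200:]


def test_motif_unrelated_sequences_find_no_group():
    hits = 0
    for _ in range(10):
        seqs = {f"r{i}": _random_seq(400) for i in range(5)}
        if shared_terminal_motif(seqs) is not None:
            hits += 1
    # ungapped identity of unrelated windows is ~0.25, far below 0.7
    assert hits == 0


def test_motif_short_sequences_excluded():
    report = shared_terminal_motif(
        {"a": _random_seq(400), "b": _random_seq(400), "tiny": _random_seq(50)}
    )
    assert "tiny" in (report.excluded_ids if report else ("tiny",))


# ---------------------------------------------------------------- identity


def test_identity_identical():
    res = global_align_identity("MKVLWAALLVT", "MKVLWAALLVT")
    assert res.percent_identity == 100.0


def test_identity_single_substitution():
    res = global_align_identity("MKV", "MRV")
    assert res.percent_identity == pytest.approx(100 * 2 / 3)
    assert res.aligned_columns == 3


def test_identity_symmetric():
    a, b = "MKVAWQEN", "MKAWEND"
    r1 = global_align_identity(a, b)
    r2 = global_align_identity(b, a)
    assert r1.percent_identity == r2.percent_identity
    assert r1.aligned_columns == r2.aligned_columns


def test_identity_rejects_illegal_residues():
    with pytest.raises(ValueError, match="positions"):
        global_align_identity("MKO", "MKV")
    with pytest.raises(ValueError):
        global_align_identity("", "MKV")


def _brute_force_score(a, b, matrix, open_=-11.0, ext=-1.0):
    """Enumerate every monotone alignment path and score it with affine
    gaps (length-k gap = open + (k-1)*extend); independent of the DP."""
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score + (ext if last == "X" else open_), "X")
        if j < len(b):
            rec(i, j + 1, score + (ext if last == "Y" else open_), "Y")

    rec(0, 0, 0.0, "")
    return best


def test_alignment_score_equals_enumeration_small_exhaustive():
    """All pairs over a 2-letter reduced alphabet up to length 3."""
    matrix = _build_aligner("BLOSUM62", 11, 1).substitution_matrix
    seqs = [
        "".join(p)
        for n in (1, 2, 3)
        for p in itertools.product("AC", repeat=n)
    ]
    for a in seqs:
        for b in seqs:
            res = global_align_identity(a, b)
            assert res.score == pytest.approx(_brute_force_score(a, b, matrix))


@pytest.mark.parametrize("trial", range(20))
def test_alignment_score_equals_enumeration_random(trial):
    """Random pairs up to length 6 over a 4-letter reduced alphabet."""
    rng = np.random.default_rng(500 + trial)
    matrix = _build_aligner("BLOSUM62", 11, 1).substitution_matrix
    a = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
    b = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
    res = global_align_identity(a, b)
    assert res.score == pytest.approx(_brute_force_score(a, b, matrix))
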