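"""Pair features: 5' anchors, candidate windows, overlap arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncgene.errors import ConfigError
from ncgene.features import (
    FEATURE_NAMES,
    candidate_pairs,
    compute_features,
    exon_overlap_stats,
    five_prime_anchor,
)

from conftest import make_set, make_transcript


@pytest.mark.parametrize(
    "strand, exons, expected",
    [
        ("+", [(100, 200), (300, 400)], (100, 200)),
        ("-", [(100, 200), (300, 400)], (400, 300)),
        ("+", [(50, 90)], (50, 90)),
        ("-", [(50, 90)], (90, 50)),
    ],
)
def test_five_prime_anchor(strand, exons, expected):
    assert five_prime_anchor(make_transcript("t", exons, strand)) == expected


def test_candidate_window_boundary_inclusive():
    ts = make_set(
        [make_transcript("a", [(100, 150)]), make_transcript("b", [(1100, 1150)])]
    )
    assert candidate_pairs(ts) == [("a", "b")]  # distance exactly 1000


def test_candidate_window_exceeded():
    ts = make_set([make_transcript("a", [(100, 150)]), make_transcript("b", [(1101, 1150)])])
    assert candidate_pairs(ts) == []


def test_candidate_pairs_respect_chromosome():
    ts = make_set(
        [
            make_transcript("a", [(100, 150)], chromosome="chr1"),
            make_transcript("b", [(100, 150)], chromosome="chr2"),
        ]
    )
    assert candidate_pairs(ts) == []


def test_negative_window_is_config_error():
    with pytest.raises(ConfigError):
        candidate_pairs(make_set([make_transcript("a", [(1, 10)])]), window=-1)


def _brute_force_pairs(ts, window):
    out = set()
    for a in ts.transcripts:
        for b in ts.transcripts:
            if a.transcript_id >= b.transcript_id or a.chromosome != b.chromosome:
                continue
            if abs(five_prime_anchor(a)[0] - five_prime_anchor(b)[0]) <= window:
                out.add((a.transcript_id, b.transcript_id))
    return sorted(out)


def test_candidate_pairs_match_brute_force_random():
    rng = np.random.default_rng(11)
    for trial in range(10):
        n = int(rng.integers(5, 120))
        transcripts = []
        for i in range(n):
            start = int(rng.integers(1, 20_000))
            transcripts.append(
                make_transcript(
                    f"t{i:03d}",
                    [(start, start + int(rng.integers(50, 400)))],
                    strand="+-"[int(rng.integers(2))],
                    chromosome=f"chr{int(rng.integers(1, 4))}",
                )
            )
        ts = make_set(transcripts)
        assert candidate_pairs(ts) == _brute_force_pairs(ts, 1000)


def _per_base_overlap_oracle(a, b):
    """Per-base enumeration of Jaccard of the 5' exons and >90% reciprocal pairs."""
    ea = a.exons[0] if a.strand == "+" else a.exons[-1]
    eb = b.exons[0] if b.strand == "+" else b.exons[-1]
    sa, sb = set(range(ea.start, ea.end + 1)), set(range(eb.start, eb.end + 1))
    frac = len(sa & sb) / len(sa | sb)
    cands = []
    for i, xa in enumerate(a.exons):
        for j, xb in enumerate(b.exons):
            pa, pb = set(range(xa.start, xa.end + 1)), set(range(xb.start, xb.end + 1))
            ov = len(pa & pb)
            if ov > 0.9 * len(pa) and ov > 0.9 * len(pb):
                cands.append((-ov, i, j))
    cands.sort()
    ua, ub, count = set(), set(), 0
    for _, i, j in cands:
        if i not in ua and j not in ub:
            ua.add(i)
            ub.add(j)
            count += 1
    return frac, count


@pytest.mark.parametrize(
    "exons_a, exons_b, expected",
    [
        (([(100, 200)], [(100, 200)]), None, (1.0, 1)),
        (([(100, 200), (300, 400), (500, 600)], [(100, 200), (300, 400), (500, 600)]), None, (1.0, 3)),
        (([(100, 200)], [(300, 400)]), None, (0.0, 0)),
        # intersection 51 nt, union 151 nt; overlap is 50.5% of each 101-nt exon
        (([(100, 200)], [(150, 250)]), None, (51 / 151, 0)),
    ],
)
def test_exon_overlap_examples(exons_a, exons_b, expected):
    del exons_b
    ea, eb = exons_a
    a, b = make_transcript("a", ea), make_transcript("b", eb)
    frac, n90 = exon_overlap_stats(a, b)
    exp_frac, exp_n = expected
    assert frac == pytest.approx(exp_frac)
    assert n90 == exp_n
    assert (frac, n90) == pytest.approx(_per_base_overlap_oracle(a, b))


def test_overlap_stats_match_per_base_oracle_random():
    rng = np.random.default_rng(5)
    for _ in range(50):
        def rand_exons():
            exons, pos = [], int(rng.integers(1, 500))
            for _ in range(int(rng.integers(1, 5))):
                end = pos + int(rng.integers(20, 200))
                exons.append((pos, end))
                pos = end + int(rng.integers(1, 150))
            return exons

        a = make_transcript("a", rand_exons(), strand="+-"[int(rng.integers(2))])
        b = make_transcript("b", rand_exons(), strand="+-"[int(rng.integers(2))])
        assert exon_overlap_stats(a, b) == pytest.approx(_per_base_overlap_oracle(a, b))


def test_identity_pair_features(mini_emb):
    a = make_transcript("a", [(100, 200), (300, 400)], so_type="SO:0001877")
    b = make_transcript("b", [(100, 200), (300, 400)], so_type="SO:0001877")
    f = compute_features(a, b, mini_emb)
    assert f.d_start5 == 0 and f.d_end5exon == 0
    assert f.frac_overlap_5exon == 1.0
    assert f.n_exons_overlap90 == 2
    assert f.same_strand == 1.0
    assert f.so_sim == pytest.approx(1.0, abs=1e-9)


def test_opposite_strand_anchor_distance(mini_emb):
    a = make_transcript("a", [(100, 200)], strand="+")
    b = make_transcript("b", [(150, 400)], strand="-")
    f = compute_features(a, b, mini_emb)
    assert f.same_strand == 0.0
    assert f.d_start5 == abs(100 - 400) == 300


def test_unknown_so_type_falls_back_to_zero(mini_emb, caplog):
    a = make_transcript("a", [(100, 200)], so_type="SO:9999999")
    b = make_transcript("b", [(100, 200)], so_type="SO:0001877")
    with caplog.at_level("WARNING"):
        f = compute_features(a, b, mini_emb)
    assert f.so_sim == 0.0
    assert any("falls back" in r.message for r in caplog.records)


@st.composite
def exon_chain(draw):
    """Sorted, disjoint 1-based exon chains."""
    steps = draw(st.lists(st.tuples(st.integers(1, 80), st.integers(20, 200)), min_size=1, max_size=4))
    exons, pos = [], 1
    for gap, length in steps:
        start = pos + gap
        exons.append((start, start + length - 1))
        pos = start + length
    return exons


@settings(max_examples=60, deadline=None)
@given(
    ea=exon_chain(),
    eb=exon_chain(),
    sa=st.sampled_from("+-"),
    sb=st.sampled_from("+-"),
    shift=st.integers(0, 5000),
)
def test_feature_symmetry_and_translation_invariance(mini_emb, ea, eb, sa, sb, shift):
    a = make_transcript("a", [(int(s), int(e)) for s, e in ea], strand=sa)
    b = make_transcript("b", [(int(s) + 40, int(e) + 40) for s, e in eb], strand=sb)
    f_ab = compute_features(a, b, mini_emb)
    f_ba = compute_features(b, a, mini_emb)
    assert f_ab == f_ba
    a2 = make_transcript("a", [(e.start + shift, e.end + shift) for e in a.exons], strand=sa)
    b2 = make_transcript("b", [(e.start + shift, e.end + shift) for e in b.exons], strand=sb)
    assert compute_features(a2, b2, mini_emb) == f_ab
    # structural bounds
    assert f_ab.n_exons_overlap90 <= min(len(a.exons), len(b.exons))
    assert 0.0 <= f_ab.frac_overlap_5exon <= 1.0
    assert np.all(np.isfinite(f_ab.as_array()))


def test_feature_order_contract():
    assert FEATURE_NAMES == (
        "d_start5",
        "d_end5exon",
        "frac_overlap_5exon",
        "n_exons_overlap90",
        "same_strand",
        "so_sim",
    )
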