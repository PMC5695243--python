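"""Affine-gap aligner: oracle equivalence, determinism, canonical gaps."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndhscan.align import (AlignParams, Transcript, global_align, local_align,
                           percent_identity)

P_DEF = AlignParams()


def brute_force_affine(a: str, b: str, p: AlignParams) -> int:
    """Enumerate all alignments recursively; gap(L) = open + L*extend."""

    @lru_cache(maxsize=None)
    def f(i, j, prev):
        if i == len(a) and j == len(b):
            return 0
        best = -(10 ** 9)
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] else -p.mismatch
            best = max(best, s + f(i + 1, j + 1, 0))
        if i < len(a):
            cost = p.gap_extend + (0 if prev == 1 else p.gap_open)
            best = max(best, -cost + f(i + 1, j, 1))
        if j < len(b):
            cost = p.gap_extend + (0 if prev == 2 else p.gap_open)
            best = max(best, -cost + f(i, j + 1, 2))
        return best

    return f(0, 0, 0)


def check_transcript_consistency(t: Transcript, ref: str, query: str):
    """M columns must be equal bases; spans must be fully consumed."""
    rpos, qpos = t.ref_span[0] - 1, t.query_span[0] - 1
    for op, n in t.ops:
        if op == "M":
            assert ref[rpos:rpos + n] == query[qpos:qpos + n]
            rpos += n; qpos += n
        elif op == "X":
            for i in range(n):
                assert ref[rpos + i] != query[qpos + i] or "N" in (
                    ref[rpos + i], query[qpos + i])
            rpos += n; qpos += n
        elif op == "D":
            rpos += n
        else:
            qpos += n
    assert rpos == t.ref_span[1] and qpos == t.query_span[1]


@pytest.mark.parametrize("ref,query,params,score,cigar", [
    ("ACGT", "ACGT", P_DEF, 4, "4M"),
    ("ACGT", "AGT", AlignParams(1, 1, 2, 1), 0, "1M1D2M"),
    ("A", "T", P_DEF, -2, "1X"),
])
def test_global_align_known_cases(ref, query, params, score, cigar):
    t = global_align(ref, query, params)
    assert t.score == score
    assert t.cigar() == cigar
    check_transcript_consistency(t, ref, query)


def test_global_align_rejects_empty():
    with pytest.raises(ValueError):
        global_align("", "ACGT")


@settings(derandomize=True, max_examples=300, deadline=None)
@given(st.text(alphabet="AC", min_size=1, max_size=8),
       st.text(alphabet="AC", min_size=1, max_size=8))
def test_global_score_matches_brute_force(a, b):
    for params in (P_DEF, AlignParams(1, 1, 2, 1), AlignParams(2, 3, 0, 2)):
        assert global_align(a, b, params).score == \
            brute_force_affine(a, b, params)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=30),
       st.text(alphabet="ACGT", min_size=1, max_size=30))
def test_score_symmetry_and_consistency(a, b):
    ta = global_align(a, b)
    tb = global_align(b, a)
    assert ta.score == tb.score
    swapped = [("D" if op == "I" else "I" if op == "D" else op, n)
               for op, n in tb.ops]
    assert sorted(ta.counts().items()) == sorted(
        Transcript(tb.score, swapped, tb.query_span, tb.ref_span)
        .counts().items())
    check_transcript_consistency(ta, a, b)


def test_gaps_are_left_shifted():
    # deletion inside a homopolymer reports the 5'-most placement
    t = global_align("AAAATTTT", "AAATTTT")
    assert t.cigar() == "1D7M"
    t = global_align("CCAAAACC", "CCAAACC")
    assert t.cigar() == "2M1D5M"
    # insertion likewise
    t = global_align("CCAAACC", "CCAAAACC")
    assert t.cigar() == "2M1I5M"


def test_local_align_exact_hit():
    rng = np.random.default_rng(1)
    ref = "".join(rng.choice(list("ACGT"), size=400))
    query = ref[100:150]
    hits = local_align(ref, query, min_score=30)
    assert len(hits) == 1
    h = hits[0]
    assert h.score == 50 and h.ref_span == (101, 150)
    assert percent_identity(h) == 1.0


def test_local_align_disjoint_composition():
    assert local_align("A" * 60, "T" * 60, min_score=10) == []


def test_local_align_planted_mismatches():
    rng = np.random.default_rng(2)
    ref = "".join(rng.choice(list("ACGT"), size=500))
    query = list(ref[200:300])
    for pos in (10, 30, 50, 70, 90):
        query[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[pos]]
    hits = local_align(ref, "".join(query), min_score=50)
    best = max(hits, key=lambda h: h.score)
    assert abs(percent_identity(best) - 0.95) < 0.02


def test_local_hits_do_not_overlap_on_reference():
    rng = np.random.default_rng(3)
    core = "".join(rng.choice(list("ACGT"), size=80))
    ref = core + "".join(rng.choice(list("ACGT"), size=100)) + core
    hits = local_align(ref, core, min_score=40)
    assert len(hits) == 2
    (a, b) = sorted(h.ref_span for h in hits)
    assert a[1] < b[0]


@pytest.mark.parametrize("ops,mode,expect", [
    ([("M", 50)], "aligned-columns", 1.0),
    ([("M", 50)], "reference-length", 1.0),
    ([("M", 99), ("X", 1)], "aligned-columns", 0.99),
])
def test_percent_identity(ops, mode, expect):
    n_ref = sum(n for op, n in ops if op in "MXD")
    n_q = sum(n for op, n in ops if op in "MXI")
    t = Transcript(0, ops, (1, n_ref), (1, n_q))
    assert percent_identity(t, mode) == pytest.approx(expect)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=5, max_size=40),
       st.text(alphabet="ACGT", min_size=5, max_size=40))
def test_percent_identity_matches_recount(a, b):
    t = global_align(a, b)
    c = t.counts()
    total = sum(c.values())
    assert percent_identity(t, "aligned-columns") == pytest.approx(
        c["M"] / total)
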