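"""Structural events: indel calling, repeat/AT mechanisms, periods, inversions."""

from fractions import Fraction

import numpy as np
import pytest

from ndhscan.align import AlignParams, Transcript, global_align
from ndhscan.core import revcomp
from ndhscan.events import StructuralEvent, call_events, detect_inversion, \
    tandem_unit
from ndhscan.events import test_at_rich as at_rich_evidence
from ndhscan.events import test_direct_repeat as direct_repeat_evidence


def _transcript(ops):
    n_ref = sum(n for op, n in ops if op in "MXD")
    n_q = sum(n for op, n in ops if op in "MXI")
    return Transcript(0, ops, (1, n_ref), (1, n_q))


def test_call_events_reads_off_runs():
    ref = "A" * 110
    query = "A" * 100
    t = _transcript([("M", 50), ("D", 10), ("M", 50)])
    (ev,) = call_events(t, ref, query, min_len=5)
    assert ev.kind == "deletion" and ev.ref_interval == (51, 60)
    assert ev.length == 10 and ev.sequence == "A" * 10


def test_call_events_threshold():
    t = _transcript([("M", 30), ("I", 2), ("M", 30)])
    assert call_events(t, "A" * 60, "A" * 62, min_len=5) == []


def _repeat_oracle(ref, s, e, k_min=7, fuzz=3):
    """Exhaustive scan over both placements and all fuzz offsets."""
    best = 0
    n = len(ref)
    for d in range(-fuzz, fuzz + 1):
        ss, ee = s + d, e + d
        if ss < 1 or ee > n:
            continue
        if ss - k_min >= 1:
            for k in range(k_min, min(ss - 1, ee - ss + 1) + 1):
                if ref[ss - 1 - k:ss - 1] == ref[ee - k:ee]:
                    best = max(best, k)
        if ee + k_min <= n:
            for k in range(k_min, min(n - ee, ee - ss + 1) + 1):
                if ref[ss - 1:ss - 1 + k] == ref[ee:ee + k]:
                    best = max(best, k)
    return best


def _deletion(s, e):
    return StructuralEvent("deletion", (s, e), (s, s - 1), e - s + 1, "N" * (e - s + 1))


def test_direct_repeat_finds_planted_12mer():
    rng = np.random.default_rng(5)
    seq = list(rng.choice(list("ACGT"), size=400))
    rep = list("ACGTTGCAAGTC")  # 12-mer
    s, e = 101, 300
    seq[s - 1 - 12:s - 1] = rep
    seq[e - 12:e] = rep
    seq[s - 2 - 12] = "A" if seq[e - 1 - 12] != "A" else "C"
    ref = "".join(seq)
    ev = _deletion(s, e)
    out = direct_repeat_evidence(ev, ref)
    assert out is not None and out.repeat_len >= 12
    assert out.repeat_len == _repeat_oracle(ref, s, e)


def test_direct_repeat_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(6)
    for trial in range(30):
        ref = "".join(rng.choice(list("ACGT"), size=500))
        s = int(rng.integers(30, 300))
        e = s + int(rng.integers(20, 150))
        out = direct_repeat_evidence(_deletion(s, e), ref)
        oracle = _repeat_oracle(ref, s, e)
        if oracle >= 7:
            assert out is not None and out.repeat_len == oracle
        else:
            assert out is None


def test_direct_repeat_boundary_below_kmin():
    # exactly k_min-1 planted -> no evidence
    rng = np.random.default_rng(7)
    base = list(rng.choice(list("ACGT"), size=300))
    rep = list("GATCGA")  # 6-mer, below default k_min 7
    s, e = 51, 150
    base[s - 1 - 6:s - 1] = rep
    base[e - 6:e] = rep
    ref = "".join(base)
    out = direct_repeat_evidence(_deletion(s, e), ref)
    assert out is None or out.repeat_len == _repeat_oracle(ref, s, e)


def test_direct_repeat_rejects_non_deletions():
    ins = StructuralEvent("insertion", (10, 9), (10, 19), 10, "A" * 10)
    with pytest.raises(ValueError):
        direct_repeat_evidence(ins, "A" * 100)


@pytest.mark.parametrize("ref,expect", [
    ("A" * 120, True),
    ("GC" * 60, False),
    ("ATGC" * 30, False),  # 50% AT below the 0.85 threshold
])
def test_at_rich_windows(ref, expect):
    ev = _deletion(41, 80)
    out = at_rich_evidence(ev, ref)
    assert (out is not None) == expect
    if out:
        assert out.at_fraction_left == 1.0 and out.at_fraction_right == 1.0


def test_at_rich_window_validation():
    with pytest.raises(ValueError):
        at_rich_evidence(_deletion(5, 10), "A" * 50, window=2)


@pytest.mark.parametrize("seq,unit,copies", [
    ("ATGATGATG", 3, Fraction(3)),
    ("AAAA", 1, Fraction(4)),
    ("ATATA", 2, Fraction(5, 2)),
])
def test_tandem_unit_periodic(seq, unit, copies):
    out = tandem_unit(seq)
    assert out.unit_len == unit and out.copies == copies
    # minimality: no divisor of the period is itself a period
    for p in range(1, out.unit_len):
        assert any(seq[i] != seq[i + p] for i in range(len(seq) - p))


def test_tandem_unit_aperiodic():
    assert tandem_unit("ACGT") is None


def test_tandem_unit_matches_bruteforce_on_random():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(2, 40))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        out = tandem_unit(seq)
        periods = [p for p in range(1, n)
                   if all(seq[i] == seq[i + p] for i in range(n - p))]
        if periods:
            assert out is not None and out.unit_len == periods[0]
        else:
            assert out is None


def test_tandem_28bp_unit_length_variation():
    """Two insertions built from the same 28-bp unit differ by its multiple."""
    rng = np.random.default_rng(9)
    unit = "".join(rng.choice(list("ACGT"), size=28))
    ins2, ins4 = unit * 2, unit * 4
    a, b = tandem_unit(ins2), tandem_unit(ins4)
    assert a.unit_len == b.unit_len == 28
    assert (len(ins4) - len(ins2)) % 28 == 0


def test_detect_inversion_planted_central_segment():
    rng = np.random.default_rng(10)
    ref = "".join(rng.choice(list("ACGT"), size=2500))
    q = ref[:1000] + revcomp(ref[1000:1500]) + ref[1500:]
    (ev,) = detect_inversion(ref, q, min_len=100)
    assert ev.ref_interval == (1001, 1500)
    assert ev.query_interval == (1001, 1500)


def test_detect_inversion_negative_cases():
    rng = np.random.default_rng(11)
    ref = "".join(rng.choice(list("ACGT"), size=1500))
    assert detect_inversion(ref, ref, min_len=100) == []
    # wholesale revcomp is an orientation flip, not an internal inversion
    assert detect_inversion(ref, revcomp(ref), min_len=100) == []


def test_events_coordinates_canonical_after_left_shift():
    """Repeat-flanked deletions get canonical (5'-most) coordinates."""
    rng = np.random.default_rng(12)
    left = "".join(rng.choice(list("ACGT"), size=100))
    right = "".join(rng.choice(list("ACGT"), size=100))
    rep = "ACGTTGCAAGTC"
    tract = "".join(rng.choice(list("ACGT"), size=50))
    ref = left + rep + tract + rep + right
    query = left + rep + right  # one copy + tract removed
    t = global_align(ref, query, AlignParams(1, 2, 30, 1))
    dels = [e for e in call_events(t, ref, query, 20) if e.kind == "deletion"]
    assert len(dels) == 1
    # 5'-most equivalent placement starts right at the first repeat copy
    assert dels[0].ref_interval == (101, 162)
    out = direct_repeat_evidence(dels[0], ref)
    assert out is not None and out.repeat_len == 12
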