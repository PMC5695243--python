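"""Trimming, bait recruitment and strict zero-mismatch assembly."""

import numpy as np
import pytest

from ndhscan.assemble import (bait_map, iterative_extend, mott_trim,
                              strict_denovo, trim_reads)
from ndhscan.core import ReadPair, SeqRecord, revcomp
from ndhscan.simulate import simulate_reads


def _pair(seq1, q1, seq2=None, q2=None, name="p"):
    seq2 = seq2 or revcomp(seq1)
    q2 = q2 or q1
    return ReadPair(name,
                    SeqRecord(name + "/1", seq1, quality=list(q1)),
                    SeqRecord(name + "/2", seq2, quality=list(q2)))


def test_mott_trim_high_quality_untouched():
    assert mott_trim([40] * 50) == (0, 50)


def test_mott_trim_all_low_quality_empty():
    s, e = mott_trim([2] * 50)
    assert e - s == 0


def test_mott_trim_keeps_central_segment():
    qual = [2] * 10 + [40] * 30 + [2] * 10
    assert mott_trim(qual) == (10, 40)


def test_trim_reads_drops_pair_when_either_mate_short():
    good = [40] * 60
    shortq = [40] * 39 + [2] * 21  # trims to 39 bp < 40
    pairs = [_pair("A" * 60, good, "C" * 60, good, "keep"),
             _pair("A" * 60, good, "C" * 39 + "G" * 21, shortq, "drop")]
    out = trim_reads(pairs)
    assert [p.name for p in out.pairs] == ["keep"]
    assert out.stats["pairs_dropped_by_length"] == 1


def test_bait_map_recruits_bait_reads_and_chimeric_pairs():
    rng = np.random.default_rng(0)
    bait = SeqRecord("bait", "".join(rng.choice(list("ACGT"), size=500)))
    other = "".join(rng.choice(list("ACGT"), size=500))
    q = [40] * 60
    on = _pair(bait.seq[100:160], q, revcomp(bait.seq[300:360]), q, "on")
    off = _pair(other[100:160], q, revcomp(other[300:360]), q, "off")
    chim = _pair(bait.seq[200:260], q, other[10:70], q, "chimeric")
    from ndhscan.assemble import TrimmedReadSet
    out = bait_map(TrimmedReadSet([on, off, chim]), bait)
    assert sorted(p.name for p in out.pairs) == ["chimeric", "on"]


def test_strict_denovo_reconstructs_template_exactly():
    rng = np.random.default_rng(1)
    template = "".join(rng.choice(list("ACGT"), size=2000))
    starts = list(range(0, 1901, 40)) + [1900]
    reads = [SeqRecord(f"r{i}", template[s:s + 100], quality=[40] * 100)
             for i, s in enumerate(starts)]
    contigs = strict_denovo(reads, min_overlap=25)
    seqs = [c.seq for c in contigs]
    assert any(s == template or revcomp(s) == template for s in seqs)


def test_strict_denovo_breaks_at_snp_branch():
    """Two templates differing by one SNP cannot merge across it."""
    rng = np.random.default_rng(2)
    a = "".join(rng.choice(list("ACGT"), size=1000))
    mid = 500
    b = a[:mid] + ("A" if a[mid] != "A" else "C") + a[mid + 1:]
    reads = []
    for t, tag in ((a, "a"), (b, "b")):
        reads += [SeqRecord(f"{tag}{i}", t[s:s + 100], quality=[40] * 100)
                  for i, s in enumerate(range(0, 901, 30))]
    contigs = strict_denovo(reads, min_overlap=25)
    for c in contigs:
        # zero-mismatch soundness: every contig is a substring of one
        # haplotype, never chimeric across the SNP
        assert (c.seq in a or c.seq in b
                or revcomp(c.seq) in a or revcomp(c.seq) in b)


def test_strict_denovo_single_read():
    r = SeqRecord("r", "ACGTACGTACGTACGTACGTACGTACGT", quality=[40] * 28)
    contigs = strict_denovo([r], min_overlap=15)
    assert len(contigs) == 1
    assert contigs[0].seq in (r.seq, revcomp(r.seq))


def test_strict_denovo_min_overlap_validation():
    with pytest.raises(ValueError):
        strict_denovo([], min_overlap=10)


def test_strict_denovo_determinism():
    rng = np.random.default_rng(3)
    template = "".join(rng.choice(list("ACGT"), size=800))
    reads = [SeqRecord(f"r{i}", template[s:s + 80], quality=[40] * 80)
             for i, s in enumerate(range(0, 721, 35))]
    c1 = strict_denovo(reads, 25)
    c2 = strict_denovo(list(reversed(reads)), 25)
    assert [c.seq for c in c1] == [c.seq for c in c2]


def test_iterative_extend_fixed_point(preset):
    """With no overhanging reads the contig set is unchanged."""
    rng = np.random.default_rng(4)
    template = "".join(rng.choice(list("ACGT"), size=600))
    pairs, _ = simulate_reads([(SeqRecord("t", template), 1.0)],
                              n_pairs=150, seed=4)
    from ndhscan.assemble import TrimmedReadSet, trim_reads
    trimmed = trim_reads(pairs)
    seed_reads = [r for p in trimmed.pairs for r in (p.read1, p.read2)]
    contigs = strict_denovo(seed_reads, 25)
    extended = iterative_extend(contigs, trimmed, inner_iters=5,
                                min_overlap=25)
    total_before = sum(len(c) for c in contigs)
    total_after = sum(len(c) for c in extended)
    assert total_after >= total_before  # never shrinks
    again = iterative_extend(extended, trimmed, inner_iters=5,
                             min_overlap=25)
    assert sorted(c.seq for c in again) == sorted(c.seq for c in extended)


def test_iterative_extend_recovers_flanks_of_partial_bait():
    """A 500-bp bait window grows to the full planted 2-kb template."""
    rng = np.random.default_rng(5)
    template = "".join(rng.choice(list("ACGT"), size=2000))
    pairs, _ = simulate_reads([(SeqRecord("t", template), 1.0)],
                              n_pairs=400, seed=5)
    from ndhscan.assemble import bait_and_extend
    bait = SeqRecord("bait", template[700:1200])
    contigs, _ = bait_and_extend(pairs, bait)
    longest = max(contigs, key=len)
    assert template[20:-20] in longest.seq or \
        revcomp(longest.seq).find(template[20:-20]) >= 0


def test_contig_depth_soundness():
    rng = np.random.default_rng(6)
    template = "".join(rng.choice(list("ACGT"), size=1000))
    reads = [SeqRecord(f"r{i}", template[s:s + 100], quality=[40] * 100)
             for i, s in enumerate(range(0, 901, 20))]
    contigs = strict_denovo(reads, 25)
    big = max(contigs, key=len)
    assert (big.depth > 0).all()  # every base covered by >= 1 exact read
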