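"""Iterative bait-and-extend organellar assembly.

The procedure mirrors a conservative read-recruitment workflow:

1. quality-trim read ends (modified-Mott, error-probability limit 0.01) and
   drop pairs in which either mate falls under 40 bp;
2. recruit pairs in which either mate aligns to a bait sequence;
3. strictly de-novo assemble the recruited reads -- exact suffix/prefix
   overlaps only, zero mismatches, zero gaps;
4. extend contig ends over 25 inner iterations with reads that align
   exactly and overhang, re-merge contigs, and repeat the whole cycle until
   the total contig length stops growing.

A read may extend a contig end only when its mate aligns exactly within the
contig at insert-size distance from that end (the paired-read consistency
constraint), which is what keeps chimeric extensions out under zero-mismatch
semantics.  Contigs never vote: any disagreement between overhanging reads
stops extension at the first conflicting base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import heappush, heappop

import edlib
import numpy as np

from .core import ReadPair, SeqRecord, revcomp

log = logging.getLogger("ndhscan")

DEFAULT_P_LIMIT = 0.01
DEFAULT_MIN_READ_LEN = 40
DEFAULT_MIN_OVERLAP = 25
DEFAULT_MIN_IDENTITY = 0.95
OUTER_CYCLE_CAP = 50


@dataclass
class TrimmedReadSet:
    pairs: list[ReadPair]
    stats: dict = field(default_factory=dict)


@dataclass
class Contig:
    id: str
    seq: str
    depth: np.ndarray
    support: list[str] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self):
        if len(self.depth) != len(self.seq):
            raise ValueError("depth vector length != sequence length")

    def __len__(self):
        return len(self.seq)


def mott_trim(quality: list[int], p_limit: float = DEFAULT_P_LIMIT
              ) -> tuple[int, int]:
    """Maximal-sum contiguous segment under weights p_limit - 10^(-Q/10).

    Returns (start, end) as a 0-based half-open interval; empty when every
    weight is negative.  Ties resolve to the leftmost, then longest segment.
    """
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for i, q in enumerate(quality):
        w = p_limit - 10.0 ** (-q / 10.0)
        if run_sum <= 0:
            run_sum = w
            run_start = i
        else:
            run_sum += w
        if run_sum > best_sum + 1e-12:
            best_sum = run_sum
            best = (run_start, i + 1)
    return best


def trim_reads(pairs: list[ReadPair], p_limit: float = DEFAULT_P_LIMIT,
               min_len: int = DEFAULT_MIN_READ_LEN) -> TrimmedReadSet:
    """Mott-trim both mates; drop the pair when either mate ends < min_len."""
    kept: list[ReadPair] = []
    trimmed_bases = 0
    dropped = 0
    for pair in pairs:
        mates = []
        for r in (pair.read1, pair.read2):
            s, e = mott_trim(r.quality, p_limit)
            trimmed_bases += len(r.seq) - (e - s)
            if e - s < min_len:
                mates = None
                break
            mates.append(SeqRecord(r.id, r.seq[s:e], r.description,
                                   quality=r.quality[s:e]))
        if mates is None:
            dropped += 1
            continue
        kept.append(ReadPair(pair.name, mates[0], mates[1]))
    return TrimmedReadSet(kept, {
        "input_pairs": len(pairs), "trimmed_bases": trimmed_bases,
        "pairs_dropped_by_length": dropped})


def _infix_identity(read: str, target: str) -> float:
    """Best infix alignment identity of the whole read inside target."""
    res = edlib.align(read, target, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(read)


def bait_map(reads: TrimmedReadSet, bait: SeqRecord,
             min_identity: float = DEFAULT_MIN_IDENTITY,
             min_overlap: int = DEFAULT_MIN_OVERLAP) -> TrimmedReadSet:
    """Pairs in which either mate infix-aligns to the bait, both strands."""
    if not bait.seq:
        raise ValueError("empty bait")
    kept = []
    for pair in reads.pairs:
        hit = False
        for r in (pair.read1, pair.read2):
            if len(r.seq) < min_overlap:
                continue
            max_dist = int((1.0 - min_identity) * len(r.seq))
            for seq in (r.seq, revcomp(r.seq)):
                res = edlib.align(seq, bait.seq, mode="HW", task="distance",
                                  k=max_dist)
                if res["editDistance"] >= 0:
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append(pair)
    return TrimmedReadSet(kept, {"input_pairs": len(reads.pairs),
                                 "recruited_pairs": len(kept)})


# ---------------------------------------------------------------------------
# strict zero-mismatch de novo assembly
# ---------------------------------------------------------------------------

def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def _greedy_merge(seqs: list[str], min_overlap: int) -> list[str]:
    """Greedy exact suffix-prefix merging, longest overlap first.

    Ties break lexicographically on (left sequence, right sequence), which
    makes the output independent of input order.
    """
    k = min_overlap
    alive: dict[int, str] = {}
    next_id = 0
    # dedupe and drop substrings
    uniq = sorted(set(seqs), key=len, reverse=True)
    kept: list[str] = []
    for s in uniq:
        if len(s) >= k and not any(s in t for t in kept):
            kept.append(s)
    for s in sorted(kept):
        alive[next_id] = s
        next_id += 1
    head: dict[str, set[int]] = {}
    for i, s in alive.items():
        head.setdefault(s[:k], set()).add(i)

    def best_out(i: int):
        """Longest exact suffix->prefix overlap from alive[i].

        Returns None when no partner exists or when two partners at the
        same (longest) overlap disagree on the extension content -- a
        branch conflict, at which zero-mismatch merging stops.
        """
        a = alive[i]
        max_ov = len(a) - 1
        for ov in range(max_ov, k - 1, -1):
            key = a[len(a) - ov:len(a) - ov + k]
            cands = head.get(key)
            if not cands:
                continue
            suffix = a[len(a) - ov:]
            matches = [j for j in cands
                       if j != i and j in alive
                       and len(alive[j]) > ov
                       and alive[j].startswith(suffix)]
            if matches:
                exts = sorted(alive[j][ov:] for j in matches)
                for x, y in zip(exts, exts[1:]):
                    if not y.startswith(x):
                        return None  # two distinct extensions: branch point
                j = min(matches, key=lambda x: alive[x])
                return ov, j
        return None

    heap: list[tuple[int, str, str, int, int]] = []

    def push(i: int):
        res = best_out(i)
        if res:
            ov, j = res
            heappush(heap, (-ov, alive[i], alive[j], i, j))

    for i in list(alive):
        push(i)

    def kill(i: int):
        s = alive.pop(i)
        grp = head.get(s[:k])
        if grp:
            grp.discard(i)

    while heap:
        negov, sa, sb, i, j = heappop(heap)
        ov = -negov
        if i not in alive or j not in alive:
            if i in alive:
                push(i)
            continue
        a, b = alive[i], alive[j]
        if a != sa or b != sb or a[len(a) - ov:] != b[:ov]:
            push(i)
            continue
        merged = a + b[ov:]
        kill(i); kill(j)
        # remove sequences now contained in the merged contig
        for t in [t for t, s in alive.items() if s in merged]:
            kill(t)
        alive[next_id] = merged
        head.setdefault(merged[:k], set()).add(next_id)
        push(next_id)
        next_id += 1
    return sorted(alive.values())


def strict_denovo(reads: list[SeqRecord],
                  min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[Contig]:
    """Zero-mismatch, zero-gap greedy overlap assembly.

    Both orientations of every N-free read enter the merge; the resulting
    contig set is deduplicated to canonical orientation.  Depth is
    recomputed by exact read placement afterwards.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    seqs = []
    for r in reads:
        if "N" in r.seq or len(r.seq) < min_overlap:
            continue
        seqs.append(r.seq)
        seqs.append(revcomp(r.seq))
    if not seqs:
        return []
    merged = _greedy_merge(seqs, min_overlap)
    uniq = sorted({_canonical(s) for s in merged}, key=lambda s: (-len(s), s))
    contigs = [Contig(f"contig{i + 1}", s, np.zeros(len(s)))
               for i, s in enumerate(uniq)]
    recompute_depth(contigs, reads)
    return contigs


def recompute_depth(contigs: list[Contig], reads: list[SeqRecord]) -> None:
    """Exact-placement depth: each read counted once, first contig match."""
    for c in contigs:
        c.depth = np.zeros(len(c.seq))
        c.support = []
    for r in reads:
        for seq in (r.seq, revcomp(r.seq)):
            placed = False
            for c in contigs:
                pos = c.seq.find(seq)
                if pos >= 0:
                    c.depth[pos:pos + len(seq)] += 1
                    c.support.append(r.id)
                    placed = True
                    break
            if placed:
                break


# ---------------------------------------------------------------------------
# iterative extension with the paired-read constraint
# ---------------------------------------------------------------------------

class _ReadIndex:
    """Prefix k-mer index over both orientations of the read set."""

    def __init__(self, pairs: list[ReadPair], k: int):
        self.k = k
        self.prefix: dict[str, list[int]] = {}
        self.reads: list[str] = []
        self.mates: list[str] = []
        self.max_read_len = 0
        for pair in pairs:
            for r, m in ((pair.read1, pair.read2), (pair.read2, pair.read1)):
                if "N" in r.seq or len(r.seq) <= k:
                    continue
                self.max_read_len = max(self.max_read_len, len(r.seq))
                for seq in (r.seq, revcomp(r.seq)):
                    idx = len(self.reads)
                    self.reads.append(seq)
                    self.mates.append(m.seq)
                    self.prefix.setdefault(seq[:k], []).append(idx)


def _extend_right(seq: str, index: _ReadIndex, insert_max: int) -> str:
    """Consensus-extend the right end; stops at the first disagreement."""
    k = index.k
    n = len(seq)
    overhangs: list[str] = []
    max_ov = min(n, index.max_read_len)
    for ov in range(max_ov - 1, k - 1, -1):
        key = seq[n - ov:n - ov + k]
        for idx in index.prefix.get(key, ()):
            read = index.reads[idx]
            if len(read) <= ov or not seq.endswith(read[:ov]):
                continue
            mate = index.mates[idx]
            mpos = _best_find(seq, mate)
            if mpos < 0 or (n - mpos) > insert_max:
                continue
            overhangs.append(read[ov:])
    if not overhangs:
        return seq
    ext = []
    for i in range(max(len(o) for o in overhangs)):
        bases = {o[i] for o in overhangs if len(o) > i}
        if len(bases) != 1:
            break
        ext.append(bases.pop())
    return seq + "".join(ext)


def _best_find(contig: str, mate: str) -> int:
    for seq in (mate, revcomp(mate)):
        pos = contig.find(seq)
        if pos >= 0:
            return pos
    return -1


def iterative_extend(contigs: list[Contig], reads: TrimmedReadSet,
                     inner_iters: int = 25,
                     min_overlap: int = DEFAULT_MIN_OVERLAP,
                     insert_range: tuple[float, float] | None = None,
                     outer_cap: int = OUTER_CYCLE_CAP) -> list[Contig]:
    """Extend contig ends with exactly-aligning overhanging paired reads.

    Each outer cycle runs ``inner_iters`` end-extension sweeps and then
    re-merges contigs with the strict assembler; cycles repeat until the
    total assembled length is unchanged (with a hard cap and warning).
    """
    if not contigs:
        return []
    index = _ReadIndex(reads.pairs, min_overlap)
    if insert_range is None:
        insert_max = _estimate_insert_max(contigs, reads)
    else:
        insert_max = insert_range[1]
    seqs = [c.seq for c in contigs]
    prev_total = -1
    cycles = 0
    while cycles < outer_cap:
        cycles += 1
        for _ in range(inner_iters):
            new_seqs = []
            for s in seqs:
                s = _extend_right(s, index, insert_max)
                s = revcomp(_extend_right(revcomp(s), index, insert_max))
                new_seqs.append(s)
            if new_seqs == seqs:
                break
            seqs = new_seqs
        merged = _greedy_merge([s for s in seqs] + [revcomp(s) for s in seqs],
                               min_overlap)
        seqs = sorted({_canonical(s) for s in merged},
                      key=lambda s: (-len(s), s))
        total = sum(len(s) for s in seqs)
        if total == prev_total:
            break
        prev_total = total
    else:
        log.warning("iterative_extend: outer cycle cap %d reached", outer_cap)
    all_reads = [r for p in reads.pairs for r in (p.read1, p.read2)]
    out = [Contig(f"contig{i + 1}", s, np.zeros(len(s)),
                  converged=cycles < outer_cap)
           for i, s in enumerate(seqs)]
    recompute_depth(out, all_reads)
    return out


def _estimate_insert_max(contigs, reads: TrimmedReadSet,
                         n_sample: int = 2000) -> float:
    """Mean + 3 SD of insert sizes of pairs placing exactly on one contig."""
    sizes = []
    for pair in reads.pairs[:n_sample]:
        for c in contigs:
            p1 = _best_find(c.seq, pair.read1.seq)
            p2 = _best_find(c.seq, pair.read2.seq)
            if p1 >= 0 and p2 >= 0:
                sizes.append(abs(p2 - p1) + len(pair.read2.seq))
                break
    if len(sizes) < 10:
        return 1000.0
    arr = np.asarray(sizes, dtype=float)
    return float(arr.mean() + 3 * arr.std())


def bait_and_extend(pairs: list[ReadPair], bait: SeqRecord,
                    p_limit: float = DEFAULT_P_LIMIT,
                    min_len: int = DEFAULT_MIN_READ_LEN,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_overlap: int = DEFAULT_MIN_OVERLAP,
                    inner_iters: int = 25) -> tuple[list[Contig], TrimmedReadSet]:
    """The full pipeline: trim, recruit on bait, assemble, extend."""
    trimmed = trim_reads(pairs, p_limit, min_len)
    recruited = bait_map(trimmed, bait, min_identity, min_overlap)
    seed_reads = [r for p in recruited.pairs for r in (p.read1, p.read2)]
    contigs = strict_denovo(seed_reads, min_overlap)
    contigs = iterative_extend(contigs, trimmed, inner_iters, min_overlap)
    return contigs, trimmed
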