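"""Affine-gap global and local DNA alignment with explicit edit transcripts.

This is the workhorse behind gene annotation, breakpoint extraction and
region typing, so it is deliberately exact (full Gotoh / Smith-Waterman
dynamic programming, no heuristics) and deterministic:

* a gap of length L costs ``gap_open + L * gap_extend``;
* at equal score the traceback prefers match/mismatch over a deletion over
  an insertion;
* after traceback every indel run is shifted to its 5'-most equivalent
  placement, so repeat-mediated deletions always report canonical
  breakpoints regardless of where the DP happened to place the gap.

Op codes follow the query-vs-reference convention: M match, X mismatch,
I insertion in the query, D deletion from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

from .core import revcomp

NEG = -(10 ** 9)

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = 2
    gap_open: int = 5
    gap_extend: int = 1

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class Transcript:
    """An alignment as (op, length) runs plus 1-based inclusive spans."""

    score: int
    ops: list[tuple[str, int]]
    ref_span: tuple[int, int]
    query_span: tuple[int, int]

    def __post_init__(self):
        self.ops = _merge_ops(self.ops)
        rlen = sum(n for op, n in self.ops if op in "MXD")
        qlen = sum(n for op, n in self.ops if op in "MXI")
        if rlen != self.ref_span[1] - self.ref_span[0] + 1:
            raise ValueError("ops do not cover ref_span")
        if qlen != self.query_span[1] - self.query_span[0] + 1:
            raise ValueError("ops do not cover query_span")

    def counts(self) -> dict[str, int]:
        c = {"M": 0, "X": 0, "I": 0, "D": 0}
        for op, n in self.ops:
            c[op] += n
        return c

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def apply(self, ref: str) -> str:
        """Reconstruct the aligned query segment from the reference.

        Mismatch and insertion columns need the query, which the transcript
        does not carry, so they are rendered as 'N' placeholders unless the
        transcript is pure M/D; mainly used by tests via
        :func:`reconstruct_query`.
        """
        out, pos = [], self.ref_span[0] - 1
        for op, n in self.ops:
            if op == "M":
                out.append(ref[pos:pos + n]); pos += n
            elif op == "X":
                out.append("N" * n); pos += n
            elif op == "D":
                pos += n
            else:
                out.append("N" * n)
        return "".join(out)


def _merge_ops(ops):
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


@njit(cache=True)
def _gotoh_fill(x, y, match, mismatch, gopen, gext):
    n, m = x.shape[0], y.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)  # ends with D (consumes ref)
    F = np.empty((n + 1, m + 1), dtype=np.int64)  # ends with I (consumes query)
    # pointers: tb_h 0=diag 1=from E 2=from F; tb_e/tb_f 0=open 1=extend
    tb_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    H[0, 0] = 0
    E[0, 0] = F[0, 0] = NEG
    for i in range(1, n + 1):
        E[i, 0] = -gopen - gext * i
        H[i, 0] = E[i, 0]
        F[i, 0] = NEG
        tb_h[i, 0] = 1
        tb_e[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        F[0, j] = -gopen - gext * j
        H[0, j] = F[0, j]
        E[0, j] = NEG
        tb_h[0, j] = 2
        tb_f[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = match if (xi == y[j - 1] and xi < 4) else -mismatch
            e_open = H[i - 1, j] - gopen - gext
            e_ext = E[i - 1, j] - gext
            if e_open >= e_ext:
                E[i, j] = e_open; tb_e[i, j] = 0
            else:
                E[i, j] = e_ext; tb_e[i, j] = 1
            f_open = H[i, j - 1] - gopen - gext
            f_ext = F[i, j - 1] - gext
            if f_open >= f_ext:
                F[i, j] = f_open; tb_f[i, j] = 0
            else:
                F[i, j] = f_ext; tb_f[i, j] = 1
            diag = H[i - 1, j - 1] + s
            # tie-break: diagonal (M/X) > D > I
            best = diag; ptr = 0
            if E[i, j] > best:
                best = E[i, j]; ptr = 1
            if F[i, j] > best:
                best = F[i, j]; ptr = 2
            H[i, j] = best; tb_h[i, j] = ptr
    return H, E, F, tb_h, tb_e, tb_f


@njit(cache=True)
def _sw_fill(x, y, match, mismatch, gopen, gext, mask):
    n, m = x.shape[0], y.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    tb_h = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop 1 diag 2 E 3 F
    tb_e = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tb_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        if mask[i - 1]:
            continue  # banned ref row: H stays 0, E/F stay NEG
        for j in range(1, m + 1):
            s = match if (xi == y[j - 1] and xi < 4) else -mismatch
            e_open = H[i - 1, j] - gopen - gext
            e_ext = E[i - 1, j] - gext
            if e_open >= e_ext:
                E[i, j] = e_open; tb_e[i, j] = 0
            else:
                E[i, j] = e_ext; tb_e[i, j] = 1
            f_open = H[i, j - 1] - gopen - gext
            f_ext = F[i, j - 1] - gext
            if f_open >= f_ext:
                F[i, j] = f_open; tb_f[i, j] = 0
            else:
                F[i, j] = f_ext; tb_f[i, j] = 1
            diag = H[i - 1, j - 1] + s
            h = diag; ptr = 1
            if E[i, j] > h:
                h = E[i, j]; ptr = 2
            if F[i, j] > h:
                h = F[i, j]; ptr = 3
            if h <= 0:
                h = 0; ptr = 0
            H[i, j] = h; tb_h[i, j] = ptr
            if h > best:
                best = h; bi = i; bj = j
    return H, E, F, tb_h, tb_e, tb_f, best, bi, bj


def _traceback_global(x, y, tb_h, tb_e, tb_f):
    ops = []
    i, j = len(x), len(y)
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            ptr = tb_h[i, j]
            if ptr == 0 and (i > 0 and j > 0):
                ops.append(("M" if x[i - 1] == y[j - 1] and x[i - 1] < 4
                            else "X", 1))
                i -= 1; j -= 1
            elif ptr == 1 or (j == 0):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append(("D", 1))
            state = "H" if tb_e[i, j] == 0 else "E"
            i -= 1
        else:
            ops.append(("I", 1))
            state = "H" if tb_f[i, j] == 0 else "F"
            j -= 1
    ops.reverse()
    return ops


def _traceback_local(x, y, tb_h, tb_e, tb_f, bi, bj):
    ops = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            ptr = tb_h[i, j]
            if ptr == 0:
                break
            if ptr == 1:
                ops.append(("M" if x[i - 1] == y[j - 1] and x[i - 1] < 4
                            else "X", 1))
                i -= 1; j -= 1
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append(("D", 1))
            state = "H" if tb_e[i, j] == 0 else "E"
            i -= 1
        else:
            ops.append(("I", 1))
            state = "H" if tb_f[i, j] == 0 else "F"
            j -= 1
    ops.reverse()
    return ops, i, j  # (i, j) = 0-based start offsets


def left_shift_ops(ops, ref: str, query: str, ref_start: int = 1,
                   query_start: int = 1):
    """Shift every indel run to its 5'-most equivalent placement.

    ``ref_start``/``query_start`` are the 1-based positions of the first
    aligned bases.  Works on expanded columns then re-merges runs.
    """
    cols: list[str] = []
    for op, n in ops:
        cols.extend([op] * n)
    changed = True
    while changed:
        changed = False
        rpos = ref_start - 1   # 0-based index of next ref base consumed
        qpos = query_start - 1
        consumed = []  # (op, rpos, qpos) per column
        for op in cols:
            consumed.append((op, rpos, qpos))
            if op in "MXD":
                rpos += 1
            if op in "MXI":
                qpos += 1
        for k in range(len(cols)):
            op = cols[k]
            if op not in "ID":
                continue
            # find start of this gap run
            run_start = k
            if run_start > 0 and cols[run_start - 1] == op:
                continue  # only handle runs at their first column
            run_end = run_start
            while run_end + 1 < len(cols) and cols[run_end + 1] == op:
                run_end += 1
            # try shifting the whole run left across a preceding M column
            if run_start == 0 or cols[run_start - 1] != "M":
                continue
            prev = run_start - 1
            _, pr, pq = consumed[prev]
            _, lr, lq = consumed[run_end]
            if op == "D":
                # deletion of ref[first..last]; can shift if ref[prev] == ref[last]
                first_r = consumed[run_start][1]
                if ref[pr] == ref[lr]:
                    cols[prev], cols[run_start:run_end + 1] = (
                        "D", ["D"] * (run_end - run_start))
                    cols.insert(run_end, "M")
                    changed = True
                    break
            else:
                if query[pq] == query[lq]:
                    cols[prev], cols[run_start:run_end + 1] = (
                        "I", ["I"] * (run_end - run_start))
                    cols.insert(run_end, "M")
                    changed = True
                    break
    return _merge_ops([(c, 1) for c in cols])


def global_align(ref: str, query: str, params: AlignParams | None = None
                 ) -> Transcript:
    """Optimal affine-gap global alignment (Needleman-Wunsch-Gotoh)."""
    if not ref or not query:
        raise ValueError("global_align requires non-empty sequences")
    params = params or AlignParams()
    x, y = encode(ref), encode(query)
    H, E, F, tb_h, tb_e, tb_f = _gotoh_fill(
        x, y, params.match, params.mismatch, params.gap_open,
        params.gap_extend)
    ops = _traceback_global(x, y, tb_h, tb_e, tb_f)
    ops = left_shift_ops(_merge_ops(ops), ref, query)
    return Transcript(int(H[len(ref), len(query)]), ops,
                      (1, len(ref)), (1, len(query)))


def local_align(ref: str, query: str, params: AlignParams | None = None,
                min_score: int = 1, max_hits: int = 50) -> list[Transcript]:
    """Non-overlapping best local hits, greedy by score.

    Hits never overlap on the reference; the search repeats with previously
    hit reference rows masked until the best remaining score drops below
    ``min_score``.
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    if not ref or not query:
        return []
    params = params or AlignParams()
    x, y = encode(ref), encode(query)
    mask = np.zeros(len(ref), dtype=np.uint8)
    hits: list[Transcript] = []
    for _ in range(max_hits):
        H, E, F, tb_h, tb_e, tb_f, best, bi, bj = _sw_fill(
            x, y, params.match, params.mismatch, params.gap_open,
            params.gap_extend, mask)
        if best < min_score:
            break
        ops, i0, j0 = _traceback_local(x, y, tb_h, tb_e, tb_f, bi, bj)
        ops = left_shift_ops(_merge_ops(ops), ref, query, i0 + 1, j0 + 1)
        t = Transcript(int(best), ops, (i0 + 1, bi), (j0 + 1, bj))
        hits.append(t)
        mask[i0:bi] = 1
    hits.sort(key=lambda t: t.ref_span)
    return hits


def percent_identity(t: Transcript, mode: str = "aligned-columns",
                     ref_length: int | None = None) -> float:
    c = t.counts()
    if mode == "aligned-columns":
        total = c["M"] + c["X"] + c["I"] + c["D"]
        return c["M"] / total if total else 0.0
    if mode == "reference-length":
        n = ref_length if ref_length is not None \
            else t.ref_span[1] - t.ref_span[0] + 1
        return c["M"] / n if n else 0.0
    raise ValueError(f"unknown identity mode {mode!r}")


def reconstruct_query(t: Transcript, ref: str, query: str) -> str:
    """Rebuild the aligned query segment from ref + transcript ops."""
    out = []
    rpos = t.ref_span[0] - 1
    qpos = t.query_span[0] - 1
    for op, n in t.ops:
        if op in "MX":
            out.append(query[qpos:qpos + n])
            rpos += n; qpos += n
        elif op == "D":
            rpos += n
        else:
            out.append(query[qpos:qpos + n])
            qpos += n
    return "".join(out)


def align_revcomp(ref: str, query: str, params: AlignParams | None = None
                  ) -> Transcript:
    return global_align(ref, revcomp(query), params)


def locate_window(target: str, pattern: str, chunk: int = 150,
                  max_norm_dist: float = 0.35, pad: int = 300
                  ) -> tuple[int, int] | None:
    """Approximate location of ``pattern`` (or parts of it) in ``target``.

    Chunks of the pattern are placed by fast edit-distance infix search;
    the hull of placed chunks, padded, is returned as a 0-based half-open
    window for exact DP.  None when no chunk places -- the pattern is
    effectively absent.  Used to keep the exact aligner off genome-scale
    problems without changing its results on the window.
    """
    spans = []
    off = 0
    while off < len(pattern):
        sub = pattern[off:off + chunk]
        if len(sub) < 40 and spans:
            break
        res = edlib.align(sub, target, mode="HW", task="locations",
                          k=int(len(sub) * max_norm_dist))
        if res["editDistance"] >= 0:
            loc = res["locations"][0]
            spans.append((loc[0], loc[1] + 1))
        off += chunk
    if not spans:
        return None
    # chunks of low-complexity patterns can place promiscuously; keep the
    # densest proximity cluster rather than the raw hull
    spans.sort()
    reach = max(2 * len(pattern), 1000)
    clusters: list[list[tuple[int, int]]] = []
    for sp in spans:
        if clusters and sp[0] - clusters[-1][-1][1] <= reach:
            clusters[-1].append(sp)
        else:
            clusters.append([sp])
    best = max(clusters, key=len)
    lo = max(0, min(s for s, _ in best) - pad)
    hi = min(len(target), max(e for _, e in best) + pad)
    return lo, hi


def lift_window(target: str, ref: str, ref_interval: tuple[int, int],
                pad: int = 500, anchor: int = 300,
                max_norm_dist: float = 0.30) -> tuple[int, int] | None:
    """Locate the target window homologous to a padded reference interval.

    Anchors the two flanks of ``ref_interval`` (1-based inclusive on
    ``ref``) by infix edit-distance search, so structural change inside the
    interval cannot mislead the lift.  Returns
    ``((target_lo, target_hi), (ref_lo, ref_hi))`` as 0-based half-open
    windows, or None when either flank fails to place.
    """
    s, e = ref_interval
    lo = max(0, s - 1 - pad)
    hi = min(len(ref), e + pad)
    left = ref[lo:lo + anchor]
    right = ref[hi - anchor:hi]
    locs = []
    for a in (left, right):
        res = edlib.align(a, target, mode="HW", task="locations",
                          k=int(len(a) * max_norm_dist))
        if res["editDistance"] < 0:
            return None
        locs.append(res["locations"][0])
    w_lo, w_hi = locs[0][0], locs[1][1] + 1
    if w_hi <= w_lo:
        return None
    return (w_lo, w_hi), (lo, hi)


def shift_transcript(t: Transcript, ref_offset: int = 0,
                     query_offset: int = 0) -> Transcript:
    return Transcript(t.score, list(t.ops),
                      (t.ref_span[0] + ref_offset, t.ref_span[1] + ref_offset),
                      (t.query_span[0] + query_offset,
                       t.query_span[1] + query_offset))
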