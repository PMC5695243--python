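"""Structural-event extraction and deletion-mechanism evidence.

Two breakpoint mechanisms recur in degraded plastid *ndh* regions:

* direct-repeat-mediated deletion (intramolecular recombination between two
  identical repeats, retaining one copy and removing the other together
  with the intervening tract), and
* illegitimate recombination in extremely AT-rich regions, leaving both
  deletion endpoints inside high-AT windows.

Insertions are additionally tested for tandem periodicity (the smallest
string period of the inserted sequence), which explains length variation
between otherwise homologous insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .align import (AlignParams, Transcript, global_align, lift_window,
                    local_align)
from .core import revcomp

DEFAULT_MIN_EVENT = 5   # bp, minimum indel length for mechanism testing
#: parameters for structural-event alignment: the heavy gap-open keeps a
#: large deletion in one run instead of fragmenting it across chance
#: match islands inside the deleted tract
EVENT_PARAMS = AlignParams(match=1, mismatch=2, gap_open=30, gap_extend=1)
DEFAULT_K_MIN = 7       # bp, minimum direct-repeat length
DEFAULT_FUZZ = 3        # bp, breakpoint placement scan radius
DEFAULT_AT_WINDOW = 20  # bp, breakpoint window for AT-richness
DEFAULT_AT_THRESHOLD = 0.85
INVERSION_MARGIN = 0.10  # revcomp score advantage per bp of segment


@dataclass
class RepeatEvidence:
    repeat_len: int
    repeat_seq: str
    left_copy: tuple[int, int]
    right_copy: tuple[int, int]
    offset_tolerance: int


@dataclass
class ATEvidence:
    window: int
    at_fraction_left: float
    at_fraction_right: float
    threshold: float
    clipped: bool = False


@dataclass
class TandemEvidence:
    unit_len: int
    unit_seq: str
    copies: Fraction


@dataclass
class StructuralEvent:
    kind: str  # deletion | insertion | inversion
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    length: int
    sequence: str  # deleted bases (from ref) or inserted bases (from query)
    #: RepeatEvidence / ATEvidence / TandemEvidence; analyze_interval fills
    #: a list because several mechanisms can hold for one event
    mechanism_evidence: object | None = None

    def __post_init__(self):
        span = {"deletion": self.ref_interval, "insertion": self.query_interval,
                "inversion": self.ref_interval}[self.kind]
        if self.length != span[1] - span[0] + 1:
            raise ValueError(f"{self.kind} length != interval span")


def call_events(t: Transcript, ref: str, query: str,
                min_len: int = DEFAULT_MIN_EVENT) -> list[StructuralEvent]:
    """One deletion/insertion event per I/D run of length >= min_len.

    Transcripts are already 5'-left-shifted by the aligner, so coordinates
    are canonical.  Events are sorted by reference position.
    """
    events = []
    rpos = t.ref_span[0] - 1
    qpos = t.query_span[0] - 1
    for op, n in t.ops:
        if op in "MX":
            rpos += n; qpos += n
        elif op == "D":
            if n >= min_len:
                events.append(StructuralEvent(
                    "deletion", (rpos + 1, rpos + n), (qpos + 1, qpos),
                    n, ref[rpos:rpos + n]))
            rpos += n
        else:
            if n >= min_len:
                events.append(StructuralEvent(
                    "insertion", (rpos + 1, rpos), (qpos + 1, qpos + n),
                    n, query[qpos:qpos + n]))
            qpos += n
    events.sort(key=lambda e: e.ref_interval)
    return events


def test_direct_repeat(ev: StructuralEvent, ref: str,
                       k_min: int = DEFAULT_K_MIN,
                       fuzz: int = DEFAULT_FUZZ) -> RepeatEvidence | None:
    """Longest exact direct repeat flanking a deletion, or None.

    For deletion bounds (s, e) two equivalent placements are tested:
    ``ref[s-k..s-1] == ref[e-k+1..e]`` (the retained copy precedes the
    deletion) and ``ref[s..s+k-1] == ref[e+1..e+k]`` (the retained copy
    follows it; this is what a 5'-left-shifted deletion looks like, since a
    repeat-mediated deletion is placement-ambiguous by exactly the repeat
    length).  Breakpoint placements are additionally scanned within +-fuzz
    to absorb residual aligner ambiguity.
    """
    if ev.kind != "deletion":
        raise ValueError("direct-repeat test applies to deletions only")
    n = len(ref)
    best: RepeatEvidence | None = None
    for delta in range(-fuzz, fuzz + 1):
        s = ev.ref_interval[0] + delta
        e = ev.ref_interval[1] + delta
        if s < 1 or e > n:
            continue
        # upstream copy retained: ref[s-k..s-1] vs ref[e-k+1..e]
        if s - k_min >= 1:
            k_cap = min(s - 1, e - s + 1)
            k = 0
            while k < k_cap and ref[s - 2 - k] == ref[e - 1 - k]:
                k += 1
            if k >= k_min and (best is None or k > best.repeat_len):
                best = RepeatEvidence(k, ref[s - 1 - k:s - 1],
                                      (s - k, s - 1), (e - k + 1, e), fuzz)
        # downstream copy retained: ref[s..s+k-1] vs ref[e+1..e+k]
        if e + k_min <= n:
            k_cap = min(n - e, e - s + 1)
            k = 0
            while k < k_cap and ref[s - 1 + k] == ref[e + k]:
                k += 1
            if k >= k_min and (best is None or k > best.repeat_len):
                best = RepeatEvidence(k, ref[s - 1:s - 1 + k],
                                      (s, s + k - 1), (e + 1, e + k), fuzz)
    return best


def test_at_rich(ev: StructuralEvent, ref: str,
                 window: int = DEFAULT_AT_WINDOW,
                 threshold: float = DEFAULT_AT_THRESHOLD) -> ATEvidence | None:
    """AT-rich breakpoint evidence: both endpoint windows >= threshold AT."""
    if window < 4:
        raise ValueError("window must be >= 4")
    half = window // 2
    fracs = []
    clipped = False
    for bp in ev.ref_interval:
        lo = max(bp - half, 1)
        hi = min(bp + half - 1, len(ref))
        clipped |= (hi - lo + 1) < window
        win = ref[lo - 1:hi]
        fracs.append((win.count("A") + win.count("T")) / len(win))
    if all(f >= threshold for f in fracs):
        return ATEvidence(window, fracs[0], fracs[1], threshold, clipped)
    return None


def tandem_unit(insertion_seq: str) -> TandemEvidence | None:
    """Smallest string period of an insertion, or None if aperiodic."""
    if len(insertion_seq) < 2:
        raise ValueError("insertion too short for periodicity test")
    L = len(insertion_seq)
    for p in range(1, L):
        if all(insertion_seq[i] == insertion_seq[i + p] for i in range(L - p)):
            return TandemEvidence(p, insertion_seq[:p], Fraction(L, p))
    return None


def detect_inversion(ref: str, query: str, params: AlignParams | None = None,
                     min_len: int = DEFAULT_MIN_EVENT * 10
                     ) -> list[StructuralEvent]:
    """Segments aligning better in reverse-complement orientation.

    A segment is called an inversion when its reverse-complement local
    alignment outscores any forward alignment over the same reference
    interval by at least ``INVERSION_MARGIN * segment_length * match`` and
    colinear forward alignments flank it on both sides (a wholesale
    reverse-complemented query is an orientation flip, not an inversion).
    """
    if not ref or not query:
        raise ValueError("detect_inversion requires non-empty sequences")
    params = params or AlignParams()
    min_score = max(min_len * params.match // 2, 10)
    fwd = local_align(ref, query, params, min_score=min_score)
    rev = local_align(ref, revcomp(query), params, min_score=min_score)
    # forward alignments can bridge an inverted segment as mismatch soup,
    # so compare against per-reference-position forward match coverage
    # rather than whole-hit scores
    fwd_match = [0] * (len(ref) + 1)
    for h in fwd:
        rpos = h.ref_span[0] - 1
        for op, n in h.ops:
            if op == "M":
                for i in range(rpos, rpos + n):
                    fwd_match[i] = 1
            if op in "MXD":
                rpos += n
    cum = [0]
    for v in fwd_match[:-1]:
        cum.append(cum[-1] + v)

    def fwd_matches(a: int, b: int) -> int:  # 1-based inclusive
        return cum[b] - cum[a - 1]

    events = []
    qlen = len(query)
    flank_w = max(min_len // 2, 100)
    for hit in rev:
        seg_len = hit.ref_span[1] - hit.ref_span[0] + 1
        if seg_len < min_len:
            continue
        margin = INVERSION_MARGIN * seg_len * params.match
        fwd_support = fwd_matches(*hit.ref_span) * params.match
        if hit.score < fwd_support + margin:
            continue
        # colinear forward flanks: well-matched forward sequence on both
        # sides (a wholesale reverse-complemented query has none)
        ls = max(1, hit.ref_span[0] - flank_w)
        rs = min(len(ref), hit.ref_span[1] + flank_w)
        left_ok = (hit.ref_span[0] > 1 and
                   fwd_matches(ls, hit.ref_span[0] - 1)
                   >= 0.5 * (hit.ref_span[0] - ls))
        right_ok = (hit.ref_span[1] < len(ref) and
                    fwd_matches(hit.ref_span[1] + 1, rs)
                    >= 0.5 * (rs - hit.ref_span[1]))
        if not (left_ok and right_ok):
            continue
        qs = qlen - hit.query_span[1] + 1
        qe = qlen - hit.query_span[0] + 1
        events.append(StructuralEvent(
            "inversion", hit.ref_span, (qs, qe), seg_len,
            query[qs - 1:qe]))
    events.sort(key=lambda e: e.ref_interval)
    return events


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def analyze_interval(ref_genome: str, query_genome: str,
                     ref_interval: tuple[int, int],
                     params: AlignParams = EVENT_PARAMS,
                     min_len: int = DEFAULT_MIN_EVENT,
                     pad: int = 300, anchor: int = 200,
                     k_min: int = DEFAULT_K_MIN,
                     fuzz: int = DEFAULT_FUZZ,
                     at_window: int = DEFAULT_AT_WINDOW,
                     at_threshold: float = DEFAULT_AT_THRESHOLD
                     ) -> list[StructuralEvent] | None:
    """Lift a reference interval into the query, align, and call events.

    Flank anchors place the homologous query window (robust to structural
    change inside the interval); events come back in absolute reference
    coordinates with repeat/AT/tandem mechanism evidence attached.  None
    when the window cannot be lifted.
    """
    lifted = lift_window(query_genome, ref_genome, ref_interval,
                         pad=pad, anchor=anchor)
    if lifted is None:
        return None
    (wl, wh), (rl, rh) = lifted
    ref_win = ref_genome[rl:rh]
    q_win = query_genome[wl:wh]
    t = global_align(ref_win, q_win, params)
    events = call_events(t, ref_win, q_win, min_len)
    for ev in events:
        if ev.kind == "deletion":
            # a deletion can carry both signatures (AT-rich breakpoints
            # often contain short AT microhomologies); report every
            # mechanism whose evidence holds
            found = []
            rep = test_direct_repeat(ev, ref_win, k_min, fuzz)
            if rep is not None:
                found.append(RepeatEvidence(
                    rep.repeat_len, rep.repeat_seq,
                    (rep.left_copy[0] + rl, rep.left_copy[1] + rl),
                    (rep.right_copy[0] + rl, rep.right_copy[1] + rl),
                    rep.offset_tolerance))
            at = test_at_rich(ev, ref_win, at_window, at_threshold)
            if at is not None:
                found.append(at)
            ev.mechanism_evidence = found or None
        elif ev.kind == "insertion" and ev.length >= 2:
            unit = tandem_unit(ev.sequence)
            ev.mechanism_evidence = [unit] if unit else None
        ev.ref_interval = (ev.ref_interval[0] + rl, ev.ref_interval[1] + rl)
        ev.query_interval = (ev.query_interval[0] + wl,
                             ev.query_interval[1] + wl)
    return events
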