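"""Typing of the *ycf1-ndhF-rpl32* region and gene-conversion breakpoints.

The region between *ycf1* and *rpl32* near the IR/SSC junction occurs in
four configurations:

* **A** - *ndhF* full length and similar to the intact reference;
* **B** - *ndhF* full length in span, but a 3'-terminal tract has been
  replaced by *ycf1* sequence (IR expansion via gene conversion produces a
  chimeric *ndhF*);
* **C** - the chimeric 3' tract is deleted, truncating *ndhF*; the deletion
  endpoint characteristically coincides with the type-B replacement
  endpoint;
* **D** - *ndhF* completely deleted, together with an intergenic deletion
  between the *ndhF* locus and *rpl32*.

Typing is anchored on the *ndhF* reference coordinate frame so calls are
comparable across species with different spacer lengths.  The endpoint
coincidence of types B and C is reported as evidence, not used as the
classification criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, global_align, local_align, percent_identity
from .core import GeneModel, SeqRecord
from .events import call_events

T_DEL = 0.10          # ndhF M-coverage below this => completely deleted
ANCHOR_MIN_LEN = 60   # bp of ycf1/rpl32 anchor alignment required
MIN_TRACT = 100       # bp, minimum ycf1-like tract for a type B call
IDENTITY_MARGIN = 0.10
ENDPOINT_TOL = 10     # bp


@dataclass
class RegionRefs:
    type_a: SeqRecord           # intact exemplar spanning ycf1..rpl32
    ndhF: GeneModel
    ycf1: GeneModel
    rpl32: GeneModel
    known_type_b_breakpoint: int | None = None  # 1-based on the ndhF CDS


@dataclass
class RegionTypeCall:
    rtype: str  # A | B | C | D | untypable
    ndhF_status: str  # full | chimeric | truncated | absent | unknown
    replaced_tract: tuple[int, int] | None = None  # on the ndhF CDS
    replaced_len: int | None = None
    deletion_endpoints: tuple[int, int] | None = None
    conversion_breakpoint: int | None = None
    endpoint_matches_type_b: bool | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rtype == "B" and self.replaced_tract is None:
            raise ValueError("type B requires a replaced tract")
        if self.rtype == "D" and self.ndhF_status != "absent":
            raise ValueError("type D requires absent ndhF")


def _anchor(query: str, gene: GeneModel | str, params: AlignParams,
            min_len: int = ANCHOR_MIN_LEN):
    cds = gene if isinstance(gene, str) else gene.cds
    hits = local_align(query, cds, params,
                       min_score=max(min_len * params.match // 2, 10))
    hits = [h for h in hits
            if h.ref_span[1] - h.ref_span[0] + 1 >= min_len]
    return hits


def type_region(query: SeqRecord, refs: RegionRefs,
                params: AlignParams | None = None) -> RegionTypeCall:
    """Classify one ycf1..rpl32 query into types A-D (or untypable)."""
    params = params or AlignParams()
    q = query.seq
    ycf1_hits = _anchor(q, refs.ycf1, params)
    rpl32_hits = _anchor(q, refs.rpl32, params, min_len=40)
    if not ycf1_hits or not rpl32_hits:
        return RegionTypeCall("untypable", "unknown",
                              notes=["ycf1/rpl32 anchors not located"])
    ndhF = refs.ndhF
    L = len(ndhF.cds)
    f_hits = _anchor(q, ndhF.cds, params, min_len=30)
    covered = np.zeros(L, dtype=bool)
    m_f = np.zeros(len(q))          # per-query-position ndhF match indicator
    gpos_at = np.zeros(len(q), dtype=int)  # gene position aligned at query pos
    for h in f_hits:
        rpos = h.ref_span[0] - 1  # on query
        gpos = h.query_span[0] - 1  # on ndhF CDS
        for op, n in h.ops:
            if op in "MX":
                if op == "M":
                    covered[gpos:gpos + n] = True
                    m_f[rpos:rpos + n] = 1.0
                    gpos_at[rpos:rpos + n] = np.arange(gpos + 1, gpos + n + 1)
                rpos += n; gpos += n
            elif op == "D":
                rpos += n
            else:
                gpos += n
    cov = covered.mean()
    if cov < T_DEL:
        # type D: ndhF gone; also report the intergenic deletion vs exemplar
        dels = _large_deletions(refs.type_a.seq, q, params)
        notes = [f"intergenic deletion {d}" for d in dels]
        return RegionTypeCall("D", "absent",
                              deletion_endpoints=dels[0] if dels else None,
                              notes=notes or ["ndhF absent"])
    g_end = int(np.nonzero(covered)[0].max()) + 1  # last ndhF CDS base found
    r_end = max(h.ref_span[1] for h in f_hits
                if h.query_span[1] >= g_end - ENDPOINT_TOL)
    if g_end >= L - ENDPOINT_TOL:
        return RegionTypeCall("A", "full")
    # ndhF 3' tract missing from the gene frame: chimeric (B) or deleted (C)?
    tract = _adjacent_ycf1_tract(q, r_end, ycf1_hits, ndhF, g_end, params)
    if tract is not None:
        # column-level refinement of the conversion boundary: maximize ndhF
        # matches in the prefix plus ycf1 matches in the suffix, so chance
        # matches just past the junction cannot drag the breakpoint
        m_y = np.zeros(len(q))
        for h in ycf1_hits:
            if h.ref_span != tract and (h.ref_span[0], h.ref_span[1]) != tract:
                continue
            rpos = h.ref_span[0] - 1
            for op, n in h.ops:
                if op == "M":
                    m_y[rpos:rpos + n] = 1.0
                if op in "MXD":
                    rpos += n
        pre = np.concatenate([[0.0], np.cumsum(m_f)])
        suf = np.concatenate([np.cumsum(m_y[::-1])[::-1], [0.0]])
        b = int(np.argmax(pre + suf))  # query prefix length at the junction
        prefix_m = np.nonzero(m_f[:b])[0]
        if prefix_m.size:
            g_end = int(gpos_at[prefix_m.max()])
        bp = g_end + 1
        return RegionTypeCall(
            "B", "chimeric", replaced_tract=(bp, L), replaced_len=L - bp + 1,
            conversion_breakpoint=bp,
            endpoint_matches_type_b=None,
            notes=[f"ycf1-like tract on query {tract}"])
    bp = g_end + 1
    matches = None
    if refs.known_type_b_breakpoint is not None:
        matches = abs(bp - refs.known_type_b_breakpoint) <= ENDPOINT_TOL
    return RegionTypeCall("C", "truncated", deletion_endpoints=(bp, L),
                          endpoint_matches_type_b=matches)


def _adjacent_ycf1_tract(q: str, r_end: int, ycf1_hits, ndhF: GeneModel,
                         g_end: int, params: AlignParams):
    """A ycf1-like query tract starting right after the ndhF prefix.

    Required for a type B call: length >= MIN_TRACT and identity to ycf1
    exceeding identity of the same query tract to the missing ndhF 3'
    remainder by IDENTITY_MARGIN.
    """
    for h in ycf1_hits:
        s, e = h.ref_span  # on query
        if abs(s - (r_end + 1)) > 2 * ENDPOINT_TOL:
            continue
        if e - s + 1 < MIN_TRACT:
            continue
        tract_seq = q[s - 1:e]
        id_ycf1 = percent_identity(h)
        remainder = ndhF.cds[g_end:]
        if remainder:
            id_ndhF = percent_identity(global_align(remainder, tract_seq,
                                                    params))
        else:
            id_ndhF = 0.0
        if id_ycf1 >= id_ndhF + IDENTITY_MARGIN:
            return (s, e)
    return None


def _large_deletions(ref_region: str, q: str, params: AlignParams,
                     min_len: int = 50):
    t = global_align(ref_region, q, params)
    return [d.ref_interval for d in call_events(t, ref_region, q, min_len)
            if d.kind == "deletion"]


def conversion_breakpoint(ndhF_query: str, ndhF_ref: str, ycf1_ref: str,
                          win: int = 100, params: AlignParams | None = None):
    """Sliding-window identity crossover between ndhF- and ycf1-likeness.

    Returns ``(breakpoint, profile)`` where breakpoint is the 5'-most query
    position from which ycf1 identity exceeds ndhF identity through the 3'
    end (refined to the column-level optimum), and profile is a DataFrame-
    friendly dict of per-window identities; ``(None, profile)`` if the query
    never becomes ycf1-like.
    """
    if win < 20:
        raise ValueError("window must be >= 20")
    if win > len(ndhF_query):
        raise ValueError("window larger than query")
    params = params or AlignParams()
    n = len(ndhF_query)
    m_ndhF = _match_profile(ndhF_query, ndhF_ref, params, mode="global")
    m_ycf1 = _match_profile(ndhF_query, ycf1_ref, params, mode="local")
    kernel = np.ones(win) / win
    prof_ndhF = np.convolve(m_ndhF, kernel, mode="same")
    prof_ycf1 = np.convolve(m_ycf1, kernel, mode="same")
    profile = {"position": np.arange(1, n + 1),
               "ndhF_identity": prof_ndhF, "ycf1_identity": prof_ycf1}
    above = prof_ycf1 > prof_ndhF
    # 5'-most window position where ycf1 wins and keeps winning to the end
    idx = None
    for i in range(n - 1, -1, -1):
        if above[i]:
            idx = i
        else:
            break
    if idx is None or idx == 0:
        return None, profile
    # column-level refinement: maximize prefix ndhF matches + suffix ycf1
    pre = np.concatenate([[0], np.cumsum(m_ndhF)])
    suf = np.concatenate([np.cumsum(m_ycf1[::-1])[::-1], [0]])
    b = int(np.argmax(pre[:n + 1] + suf[:n + 1]))  # query prefix length
    return b + 1, profile


def _match_profile(query: str, ref: str, params: AlignParams,
                   mode: str) -> np.ndarray:
    """Per-query-position match indicator against a reference."""
    out = np.zeros(len(query))
    if mode == "global":
        transcripts = [global_align(ref, query, params)]
    else:
        transcripts = local_align(query, ref, params,
                                  min_score=20)
        transcripts = [_flip_roles(t) for t in transcripts]
    for t in transcripts:
        qpos = t.query_span[0] - 1
        for op, n in t.ops:
            if op == "M":
                out[qpos:qpos + n] = 1.0
                qpos += n
            elif op in "XI":
                qpos += n
    return out


def _flip_roles(t):
    from .align import Transcript
    ops = [("D" if op == "I" else "I" if op == "D" else op, n)
           for op, n in t.ops]
    return Transcript(t.score, ops, t.query_span, t.ref_span)
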