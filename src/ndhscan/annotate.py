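"""Reference-guided *ndh* gene annotation and 4-class degradation scoring.

Each gene of a query plastome is scored into one of four classes:

1. in-frame gene;
2. pseudogene (frameshifting indel, premature stop or lost start);
3. highly truncated gene (reference CDS coverage in ``[t_del, t_trunc)``);
4. completely deleted gene (coverage below ``t_del``).

The class 3/4 boundary is a declared convention (the survey literature never
quantifies "highly truncated" vs "deleted"); both thresholds are parameters
and are echoed into every report.  Frameshift detection operates on
CDS-projected indels only, so intron indels never pseudogenize a gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import (AlignParams, Transcript, global_align, local_align,
                    locate_window, shift_transcript)
from .core import GeneModel, ReferenceGeneSet, SeqRecord, revcomp, translate

DEFAULT_T_DEL = 0.10
DEFAULT_T_TRUNC = 0.50
STOP_TAIL_FRACTION = 0.05  # stops in the final 5% of codons are ignored
HOMOPOLYMER_MIN = 8


@dataclass
class ExonPlacement:
    ref_interval: tuple[int, int]          # on the reference CDS, 1-based
    query_interval: tuple[int, int] | None  # on the query forward strand
    transcript: Transcript | None           # ref = exon seq, query = segment

    @property
    def absent(self) -> bool:
        return self.query_interval is None


@dataclass
class AnnotatedRegion:
    gene: str
    query_interval: tuple[int, int] | None
    strand: str
    exon_map: list[ExonPlacement]
    coverage: float      # fraction of reference CDS columns aligned (M or X)
    query_cds: str       # query bases projected onto the CDS, 5'->3'
    indels: list[tuple[int, int]]  # (CDS offset of last base before indel, +/-len)

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0 + 1e-9:
            raise ValueError("coverage outside [0,1]")


@dataclass
class Evidence:
    kind: str            # frameshift | premature_stop | truncation | absent | lost_start
    detail: dict = field(default_factory=dict)

    def __str__(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.detail.items())
        return f"{self.kind}({inner})"


@dataclass
class DegradationCall:
    gene: str
    cls: int
    evidence: list[Evidence]
    notes: str = ""

    def __post_init__(self):
        if self.cls not in (1, 2, 3, 4):
            raise ValueError("class must be 1-4")
        if self.cls == 1 and self.evidence:
            raise ValueError("class 1 calls carry no evidence")


@dataclass
class DegradationPattern:
    sample: str
    pattern: str  # 11 class digits ordered ndhA..ndhK

    def __post_init__(self):
        if len(self.pattern) != 11 or set(self.pattern) - set("1234"):
            raise ValueError("pattern must be 11 digits in 1-4")


def _min_exon_score(exon_len: int, params: AlignParams) -> int:
    # an exon placement must beat a quarter of its perfect score
    return max(params.match * max(exon_len // 4, 10), 1)


def annotate_gene(query: SeqRecord, model: GeneModel,
                  params: AlignParams | None = None) -> AnnotatedRegion:
    """Best colinear placement of each reference exon on either strand.

    Exons are located by local alignment of the query against each exon
    sequence, chained colinearly; absent exons are recorded.  Coverage is
    the fraction of reference CDS positions aligned as match or mismatch.
    """
    params = params or AlignParams()
    best = None
    for strand in "+-":
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        placements = _place_exons(qseq, model, params)
        cov = sum(_aligned_cols(p) for p in placements) / len(model.cds)
        score = sum(p.transcript.score for p in placements if p.transcript)
        if best is None or score > best[0]:
            best = (score, strand, placements, cov, qseq)
    score, strand, placements, cov, qseq = best
    # project query CDS and indel list from the chained exon transcripts
    query_cds, indels = _project_cds(placements, qseq, model)
    # map query intervals back to the forward strand
    if strand == "-":
        L = len(query.seq)
        for p in placements:
            if p.query_interval is not None:
                s, e = p.query_interval
                p.query_interval = (L - e + 1, L - s + 1)
    spans = [p.query_interval for p in placements if p.query_interval]
    qiv = (min(s for s, _ in spans), max(e for _, e in spans)) if spans else None
    return AnnotatedRegion(model.gene, qiv, strand, placements,
                           min(cov, 1.0), query_cds, indels)


def _aligned_cols(p: ExonPlacement) -> int:
    if p.transcript is None:
        return 0
    c = p.transcript.counts()
    return c["M"] + c["X"]


def _place_exons(qseq: str, model: GeneModel,
                 params: AlignParams) -> list[ExonPlacement]:
    offsets = []
    pos = 0
    for seq in model.exon_seqs:
        offsets.append(pos)
        pos += len(seq)
    chosen: list[ExonPlacement] = []
    last_end = 0
    for off, eseq in zip(offsets, model.exon_seqs):
        window = locate_window(qseq, eseq)
        if window is None:
            chosen.append(ExonPlacement((off + 1, off + len(eseq)), None, None))
            continue
        lo, hi = window
        hits = [shift_transcript(h, ref_offset=lo)
                for h in local_align(qseq[lo:hi], eseq, params,
                                     min_score=_min_exon_score(len(eseq),
                                                               params))]
        # colinear chaining: best hit starting after the previous exon's end
        hits = [h for h in hits if h.ref_span[0] > last_end]
        if not hits:
            chosen.append(ExonPlacement((off + 1, off + len(eseq)), None, None))
            continue
        hit = max(hits, key=lambda h: h.score)
        # transcript roles: ref = query sequence, query = exon; flip to
        # exon-as-reference for downstream CDS projection
        flipped = _flip(hit)
        flipped = _rescue_clipped_ends(flipped, eseq, qseq, params)
        chosen.append(ExonPlacement((off + 1, off + len(eseq)),
                                    flipped.query_span, flipped))
        last_end = flipped.query_span[1]
    return chosen


def _rescue_clipped_ends(t: Transcript, exon: str, qseq: str,
                         params: AlignParams,
                         min_identity: float = 0.75) -> Transcript:
    """Re-attach exon ends that local alignment trimmed around an indel.

    Smith-Waterman drops a short terminal exon piece when an adjacent long
    insertion costs more than the piece scores.  If the clipped reference
    piece aligns well to the immediately adjacent query sequence, merge it
    back so coverage and start-codon checks see the full placement.
    """
    from .align import percent_identity
    r0, r1 = t.ref_span        # on the exon
    q0, q1 = t.query_span      # on the query sequence
    ops = list(t.ops)
    score = t.score
    if r0 > 1 and q0 > r0 - 1:
        piece = exon[:r0 - 1]
        qpiece = qseq[q0 - 1 - len(piece):q0 - 1]
        pt = global_align(piece, qpiece, params)
        if percent_identity(pt) >= min_identity:
            ops = list(pt.ops) + ops
            score += pt.score
            r0, q0 = 1, q0 - len(piece)
        else:
            reloc = _relocate_piece(piece, qseq, max(0, q0 - 1 - len(piece)
                                                     - 150), q0 - 1, params)
            if reloc is not None:
                p_ops, p_r0, p_q0, p_rend, p_qend = reloc
                gap_r = (r0 - 1) - p_rend
                gap_q = (q0 - 1) - p_qend
                ops = (p_ops + ([("D", gap_r)] if gap_r else [])
                       + ([("I", gap_q)] if gap_q else []) + ops)
                r0, q0 = p_r0, p_q0
    if r1 < len(exon) and len(qseq) - q1 >= len(exon) - r1:
        piece = exon[r1:]
        qpiece = qseq[q1:q1 + len(piece)]
        pt = global_align(piece, qpiece, params)
        if percent_identity(pt) >= min_identity:
            ops = ops + list(pt.ops)
            score += pt.score
            r1, q1 = len(exon), q1 + len(piece)
        else:
            reloc = _relocate_piece(piece, qseq, q1,
                                    min(len(qseq), q1 + len(piece) + 150),
                                    params)
            if reloc is not None:
                p_ops, p_r0, p_q0, p_rend, p_qend = reloc
                gap_r = (p_r0 - 1)
                gap_q = (p_q0 - 1) - q1
                ops = (ops + ([("D", gap_r)] if gap_r else [])
                       + ([("I", gap_q)] if gap_q else []) + p_ops)
                r1 = r1 + p_rend
                q1 = p_qend
    if (r0, r1) == t.ref_span:
        return t
    try:
        return Transcript(score, ops, (r0, r1), (q0, q1))
    except ValueError:
        return t


def _relocate_piece(piece: str, qseq: str, w_lo: int, w_hi: int,
                    params: AlignParams):
    """Find a clipped exon piece nearby (e.g. across a long insertion).

    Searches the 0-based query window [w_lo, w_hi) for the piece; accepts
    a near-complete, high-identity hit.  Returns
    (ops, ref_start, query_start, ref_end, query_end) with ref coordinates
    local to the piece and query coordinates on the full sequence (1-based),
    or None.
    """
    from .align import percent_identity
    if len(piece) < 15 or w_hi - w_lo < len(piece):
        return None
    window = qseq[w_lo:w_hi]
    hits = local_align(window, piece, params,
                       min_score=max(10, len(piece) // 2))
    if not hits:
        return None
    h = max(hits, key=lambda x: x.score)
    f = _flip(h)  # ref = piece, query = window
    if percent_identity(f) < 0.85:
        return None
    covered = f.ref_span[1] - f.ref_span[0] + 1
    if covered < 0.8 * len(piece):
        return None
    return (list(f.ops), f.ref_span[0], w_lo + f.query_span[0],
            f.ref_span[1], w_lo + f.query_span[1])


def _flip(t: Transcript) -> Transcript:
    ops = [("D" if op == "I" else "I" if op == "D" else op, n)
           for op, n in t.ops]
    return Transcript(t.score, ops, t.query_span, t.ref_span)


def _project_cds(placements: list[ExonPlacement], qseq: str,
                 model: GeneModel) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate query bases over the CDS and list CDS-projected indels."""
    parts: list[str] = []
    indels: list[tuple[int, int]] = []
    cds_consumed = 0
    for p in placements:
        exon_len = p.ref_interval[1] - p.ref_interval[0] + 1
        if p.transcript is None:
            cds_consumed += exon_len
            continue
        t = p.transcript  # ref = exon, query = query segment
        qpos = t.query_span[0] - 1
        rpos = t.ref_span[0] - 1  # within exon
        for op, n in t.ops:
            cds_off = p.ref_interval[0] - 1 + rpos
            if op in "MX":
                parts.append(qseq[qpos:qpos + n])
                qpos += n
                rpos += n
            elif op == "D":
                indels.append((cds_off, -n))
                rpos += n
            else:
                indels.append((cds_off, +n))
                parts.append(qseq[qpos:qpos + n])
                qpos += n
        cds_consumed += exon_len
    return "".join(parts), indels


def _in_homopolymer(cds: str, offset: int) -> bool:
    i = max(offset - 1, 0)
    b = cds[i]
    run = 1
    j = i - 1
    while j >= 0 and cds[j] == b:
        run += 1; j -= 1
    j = i + 1
    while j < len(cds) and cds[j] == b:
        run += 1; j += 1
    return run >= HOMOPOLYMER_MIN


def classify_degradation(region: AnnotatedRegion, model: GeneModel,
                         t_del: float = DEFAULT_T_DEL,
                         t_trunc: float = DEFAULT_T_TRUNC) -> DegradationCall:
    """Score one annotated gene into degradation classes 1-4."""
    if not (0.0 < t_del < 1.0 and 0.0 < t_trunc < 1.0) or t_del >= t_trunc:
        raise ValueError("thresholds must satisfy 0 < t_del < t_trunc < 1")
    gene = model.gene
    if region.coverage < t_del:
        return DegradationCall(gene, 4, [Evidence("absent",
                                                  {"coverage": round(region.coverage, 3)})])
    if region.coverage < t_trunc:
        return DegradationCall(gene, 3, [Evidence("truncation",
                                                  {"coverage": round(region.coverage, 3)})])
    evidence: list[Evidence] = []
    notes: list[str] = []
    net = 0
    shifted = False
    for off, delta in region.indels:
        net += delta
        if delta % 3 != 0:
            shifted = True
            if abs(delta) == 1 and _in_homopolymer(model.cds, off):
                notes.append(f"possible sequencing artifact: 1-bp indel in "
                             f"homopolymer at CDS {off}")
    if shifted and net % 3 != 0:
        first = next((off, d) for off, d in region.indels if d % 3 != 0)
        evidence.append(Evidence("frameshift",
                                 {"offset": first[0], "net_indel": net}))
    elif shifted:
        notes.append("compensating indels restore reading frame")
    # premature stop scan on the reconstructed query CDS
    qcds = region.query_cds
    if len(qcds) >= 3:
        prot = translate(qcds)
        n_cod = len(prot)
        cutoff = int(n_cod * (1 - STOP_TAIL_FRACTION))
        stop = prot.find("*")
        if 0 <= stop < cutoff - 1:
            evidence.append(Evidence("premature_stop", {"codon": stop + 1}))
        start_ok = qcds[:3] in ("ATG", "GTG", "TTG")
        first_ref_aligned = next(
            (p.ref_interval[0] + (p.transcript.ref_span[0] - 1)
             for p in region.exon_map if p.transcript is not None), None)
        if not start_ok or (first_ref_aligned or 1) > 3:
            evidence.append(Evidence("lost_start", {}))
    cls = 2 if evidence else 1
    return DegradationCall(gene, cls, evidence, "; ".join(notes))


def classify_sample(query: SeqRecord, refs: ReferenceGeneSet,
                    params: AlignParams | None = None,
                    t_del: float = DEFAULT_T_DEL,
                    t_trunc: float = DEFAULT_T_TRUNC
                    ) -> dict[str, DegradationCall]:
    """Annotate and score every ndh gene model present in ``refs``."""
    calls = {}
    for gene, model in sorted(refs.models.items()):
        if not gene.startswith("ndh"):
            continue
        region = annotate_gene(query, model, params)
        calls[gene] = classify_degradation(region, model, t_del, t_trunc)
    return calls


def pattern_from_calls(sample: str,
                       calls: dict[str, DegradationCall]) -> DegradationPattern:
    order = [f"ndh{c}" for c in "ABCDEFGHIJK"]
    return DegradationPattern(
        sample, "".join(str(calls[g].cls) for g in order))


def aggregate_survey(records: list[tuple[str, DegradationPattern]]
                     ) -> pd.DataFrame:
    """Per-group pattern counts, distinct-pattern percentage and group share.

    Mirrors the survey view of degradation patterns across orders: one row
    per group plus a totals row whose share column sums to 100%.
    """
    if not records:
        raise ValueError("aggregate_survey needs at least one record")
    total = len(records)
    rows = []
    groups: dict[str, list[str]] = {}
    for group, pat in records:
        groups.setdefault(group, []).append(pat.pattern)
    for group in sorted(groups):
        pats = groups[group]
        n = len(pats)
        distinct = len(set(pats))
        rows.append({
            "group": group, "n": n,
            "share_pct": 100.0 * n / total,
            "distinct_patterns": distinct,
            "distinct_pct": 100.0 * distinct / n,
        })
    df = pd.DataFrame(rows)
    totals = {
        "group": "TOTAL", "n": total, "share_pct": df["share_pct"].sum(),
        "distinct_patterns": len({p.pattern for _, p in records}),
        "distinct_pct": 100.0 * len({p.pattern for _, p in records}) / total,
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
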