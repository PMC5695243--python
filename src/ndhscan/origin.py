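"""Depth-ratio organelle assignment and plastome-like segment reporting.

A contig assembled from total-DNA reads is assigned to the plastid or
mitochondrial genome by comparing its mean read depth with that of the
plastome: plastid DNA is present at many more copies per cell, so a
mitochondrial contig shows a plastome/contig depth ratio well above 1
(observed around 5-15 in orchid data sets), while a plastid contig sits
near 1.  Contigs outside both bands are honestly ambiguous unless local
alignment of their flanks to a mitochondrial reference rescues them.

Plastome-like intervals inside mitochondrial contigs (intracellular gene
transfer evidence) are reported by a windowed identity scan against the
plastome reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .assemble import Contig, TrimmedReadSet
from .core import SeqRecord, revcomp

R_LO = 4.0
R_HI = 20.0
R_PLASTID_TOL = 2.0
PLASTOME_MAP_IDENTITY = 0.98
IGT_WINDOW = 500
IGT_STEP = 250
IGT_MIN_IDENTITY = 0.80
FLANK_MIN_IDENTITY = 0.80


@dataclass
class DepthProfile:
    contig_id: str
    mean_depth: float
    plastome_mean_depth: float

    @property
    def ratio(self) -> float | None:
        if self.mean_depth <= 0:
            return None
        return self.plastome_mean_depth / self.mean_depth


@dataclass
class IgtSegment:
    contig_interval: tuple[int, int]
    plastome_interval: tuple[int, int]
    identity: float


@dataclass
class OriginCall:
    origin: str  # plastid | mitochondrial | ambiguous
    ratio: float | None
    flank_support: bool
    igt_segments: list[IgtSegment] = field(default_factory=list)
    notes: str = ""


def depth_profile(contig: Contig, reads: TrimmedReadSet,
                  plastome_ref: SeqRecord) -> DepthProfile:
    """Mean exact-placement depth of the contig vs >=98%-identity plastome depth.

    Contig depth uses exact substring placement (consistent with the
    zero-mismatch assembler); plastome depth admits reads mapping at
    identity >= 0.98 (whole-read infix alignment, either strand).
    """
    if not plastome_ref.seq:
        raise ValueError("empty plastome reference")
    contig_bases = 0
    plastome_bases = 0
    pt = plastome_ref.seq
    for pair in reads.pairs:
        for r in (pair.read1, pair.read2):
            s = r.seq
            rc = revcomp(s)
            if s in contig.seq or rc in contig.seq:
                contig_bases += len(s)
            if s in pt or rc in pt:
                plastome_bases += len(s)
                continue
            max_dist = int((1 - PLASTOME_MAP_IDENTITY) * len(s))
            if max_dist > 0:
                for seq in (s, rc):
                    res = edlib.align(seq, pt, mode="HW", task="distance",
                                      k=max_dist)
                    if res["editDistance"] >= 0:
                        plastome_bases += len(s)
                        break
    return DepthProfile(contig.id,
                        contig_bases / len(contig.seq),
                        plastome_bases / len(pt))


def igt_scan(contig_seq: str, plastome_ref: SeqRecord,
             window: int = IGT_WINDOW, step: int = IGT_STEP,
             min_identity: float = IGT_MIN_IDENTITY) -> list[IgtSegment]:
    """Plastome-like contig intervals via a sliding infix-identity scan."""
    pt = plastome_ref.seq
    n = len(contig_seq)
    hits = []  # (start0, end0, identity, pt_interval)
    pos = 0
    while pos < n:
        win = contig_seq[pos:pos + window]
        if len(win) < min(window // 2, n):
            break
        best = None
        for seq in (win, revcomp(win)):
            res = edlib.align(seq, pt, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(win)
            if best is None or ident > best[0]:
                loc = res["locations"][0]
                best = (ident, (loc[0] + 1, loc[1] + 1))
        if best and best[0] >= min_identity:
            hits.append((pos, min(pos + window, n), best[0], best[1]))
        pos += step
    # merge overlapping/adjacent windows
    segments: list[IgtSegment] = []
    for s, e, ident, ptiv in hits:
        if segments and s <= segments[-1].contig_interval[1]:
            last = segments[-1]
            segments[-1] = IgtSegment(
                (last.contig_interval[0], e),
                (min(last.plastome_interval[0], ptiv[0]),
                 max(last.plastome_interval[1], ptiv[1])),
                (last.identity + ident) / 2)
        else:
            segments.append(IgtSegment((s + 1, e), ptiv, ident))
    return segments


def assign_origin(dp: DepthProfile, contig: Contig,
                  plastome_ref: SeqRecord, mt_ref: SeqRecord | None = None,
                  r_lo: float = R_LO, r_hi: float = R_HI,
                  r_plastid_tol: float = R_PLASTID_TOL) -> OriginCall:
    """Assign plastid/mitochondrial/ambiguous origin from the depth ratio."""
    ratio = dp.ratio
    if ratio is None:
        return OriginCall("ambiguous", None, False,
                          notes="no reads placed on contig; ratio undefined")
    segments = igt_scan(contig.seq, plastome_ref)
    if 1.0 / r_plastid_tol <= ratio <= r_plastid_tol:
        return OriginCall("plastid", ratio, False, segments)
    flank = False
    if mt_ref is not None:
        flank = _mt_flank_support(contig.seq, segments, mt_ref)
    if r_lo <= ratio <= r_hi or (ratio > r_plastid_tol and flank):
        return OriginCall("mitochondrial", ratio, flank, segments)
    return OriginCall("ambiguous", ratio, flank, segments,
                      notes=f"ratio {ratio:.2f} outside plastid and mt bands")


def _mt_flank_support(seq: str, segments: list[IgtSegment],
                      mt_ref: SeqRecord,
                      min_identity: float = FLANK_MIN_IDENTITY,
                      min_len: int = 200) -> bool:
    """Do the non-plastome-like flanks align to a mitochondrial reference?"""
    covered = np.zeros(len(seq), dtype=bool)
    for seg in segments:
        covered[seg.contig_interval[0] - 1:seg.contig_interval[1]] = True
    flanks = []
    start = None
    for i, c in enumerate(covered):
        if not c and start is None:
            start = i
        elif c and start is not None:
            flanks.append((start, i)); start = None
    if start is not None:
        flanks.append((start, len(seq)))
    for s, e in flanks:
        if e - s < min_len:
            continue
        win = seq[s:e][:2000]
        for cand in (win, revcomp(win)):
            res = edlib.align(cand, mt_ref.seq, mode="HW", task="distance",
                              k=int((1 - min_identity) * len(win)))
            if res["editDistance"] >= 0:
                return True
    return False
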