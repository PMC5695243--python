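"""Synthetic organellar genomes, engineered degradations and simulated reads.

The generator builds a toy plastome (genes plus spacers, roughly 20 kb, not
a full 150-kb plastome) carrying the 11-gene *ndh* family with introns in
*ndhA* and *ndhB*, *ndhB* inside an inverted repeat, and a
*ycf1-ndhF-rpl32* region at the SSC end; a toy chondriome that receives
plastome segments (optionally inverted and with divergence accumulated
since the transfer); and error-configurable paired-end reads at a chosen
plastome:chondriome copy-number ratio.

Every engineered event is recorded in a :class:`TruthManifest` together
with the degradation class, region type, and organelle origin it implies,
so downstream calls can be scored against construction-time truth that
never touches the alignment pipeline (classes come from survivor masks and
direct translation of the mutated CDS).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (GeneModel, ReadPair, ReferenceGeneSet, SeqRecord, revcomp,
                   translate)

DEFAULT_GENE_LENGTHS = {
    # CDS lengths (bp, divisible by 3); ndhA/ndhB are two-exon genes
    "ndhA": 1080, "ndhB": 1530, "ndhC": 363, "ndhD": 1500, "ndhE": 306,
    "ndhF": 1500, "ndhG": 531, "ndhH": 1182, "ndhI": 501, "ndhJ": 477,
    "ndhK": 678, "ycf1": 900, "rpl32": 171,
}
DEFAULT_INTRONS = {"ndhA": 500, "ndhB": 600}
DEFAULT_EXON1 = {"ndhA": 540, "ndhB": 720}
DEFAULT_SPACER = 300
DEFAULT_GC = 0.37  # plastome-like AT-rich composition
CONVERSION_TRACT = 420

STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in STOP_CODONS]


@dataclass
class Block:
    name: str
    kind: str                 # "spacer" or "gene"
    pieces: list[str]         # gene: [exon1] or [exon1, intron, exon2]
    gene: str | None = None

    @property
    def seq(self) -> str:
        return "".join(self.pieces)

    @property
    def cds(self) -> str:
        if self.kind != "gene":
            raise ValueError("not a gene block")
        if len(self.pieces) == 3:
            return self.pieces[0] + self.pieces[2]
        return self.pieces[0]

    def set_cds(self, cds: str, exon1_len: int | None = None) -> None:
        if len(self.pieces) == 3:
            e1 = exon1_len if exon1_len is not None else len(self.pieces[0])
            e1 = min(e1, len(cds))
            self.pieces[0] = cds[:e1]
            self.pieces[2] = cds[e1:]
        else:
            self.pieces[0] = cds


@dataclass
class SimulatedReference:
    """A toy plastome with its gene models and region exemplar."""

    blocks: dict[str, Block]
    order: list[str]          # block names; "__IRB__" renders the IR mirror
    ir_blocks: list[str]
    seed: int
    plastome: SeqRecord = field(init=False)
    genes: ReferenceGeneSet = field(init=False)
    region: SeqRecord = field(init=False)
    region_interval: tuple[int, int] = field(init=False)

    def __post_init__(self):
        self.rebuild()

    def rebuild(self) -> None:
        seq_parts = []
        offsets = {}
        pos = 0
        for name in self.order:
            if name == "__IRB__":
                ir = "".join(self.blocks[b].seq for b in self.ir_blocks)
                seq_parts.append(revcomp(ir))
                pos += len(ir)
                continue
            block = self.blocks[name]
            offsets[name] = pos
            seq_parts.append(block.seq)
            pos += len(block.seq)
        seq = "".join(seq_parts)
        models = {}
        for name in self.order:
            if name == "__IRB__":
                continue
            block = self.blocks[name]
            if block.kind != "gene" or not block.cds:
                continue
            off = offsets[name]
            if len(block.pieces) == 3:
                e1, intr, e2 = (len(p) for p in block.pieces)
                exons = [(off + 1, off + e1),
                         (off + e1 + intr + 1, off + e1 + intr + e2)]
                exons = [iv for iv in exons if iv[1] >= iv[0]]
            else:
                exons = [(off + 1, off + len(block.pieces[0]))]
            models[block.gene] = GeneModel(block.gene, exons, "+", block.cds)
        self.plastome = SeqRecord(f"toy_plastome_seed{self.seed}", seq)
        self.genes = ReferenceGeneSet(models)
        r_lo = offsets["ycf1"]
        r_hi = offsets["rpl32"] + len(self.blocks["rpl32"].seq)
        self.region_interval = (r_lo + 1, r_hi)
        self.region = SeqRecord("ycf1_rpl32_typeA", seq[r_lo:r_hi])

    def block_offset(self, name: str) -> int:
        pos = 0
        for n in self.order:
            if n == name:
                return pos
            if n == "__IRB__":
                pos += sum(len(self.blocks[b].seq) for b in self.ir_blocks)
            else:
                pos += len(self.blocks[n].seq)
        raise KeyError(name)


def _random_seq(rng: np.random.Generator, n: int, gc: float = DEFAULT_GC
                ) -> str:
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    return "".join(rng.choice(["A", "T", "G", "C"], size=n,
                              p=[p_at, p_at, p_gc, p_gc]))


def _random_cds(rng: np.random.Generator, n: int) -> str:
    assert n % 3 == 0 and n >= 9
    ncod = n // 3 - 2
    body = "".join(rng.choice(_NONSTOP, size=ncod))
    return "ATG" + body + "TAA"


def make_reference(seed: int = 0,
                   gene_lengths: dict[str, int] | None = None,
                   intron_lengths: dict[str, int] | None = None,
                   spacer_len: int = DEFAULT_SPACER,
                   gc: float = DEFAULT_GC,
                   ir: bool = True) -> SimulatedReference:
    """Build a deterministic toy plastome with intact gene models.

    Gene order follows the survey amplicons (ndhJ-K-C, ndhD, ndhB in the
    IR, ndhE-G-I-A-H, then ycf1-ndhF-rpl32 at the SSC end).
    """
    lengths = dict(DEFAULT_GENE_LENGTHS)
    if gene_lengths:
        lengths.update(gene_lengths)
    introns = dict(DEFAULT_INTRONS)
    if intron_lengths:
        introns.update(intron_lengths)
    for g, L in lengths.items():
        if L < 171 or (g != "rpl32" and L < 300) or L % 3:
            raise ValueError(f"invalid CDS length for {g}: {L}")
    rng = np.random.default_rng(seed)

    def spacer(name, n=spacer_len):
        return Block(name, "spacer", [_random_seq(rng, n)])

    def gene(name):
        cds = _random_cds(rng, lengths[name])
        if name in introns:
            e1 = DEFAULT_EXON1[name]
            return Block(name, "gene",
                         [cds[:e1], _random_seq(rng, introns[name]), cds[e1:]],
                         gene=name)
        return Block(name, "gene", [cds], gene=name)

    lsc = ["s0", "ndhJ", "s1", "ndhK", "s2", "ndhC", "s3", "ndhD", "s4"]
    ir_names = ["s5", "ndhB", "s6"]
    ssc = ["s7", "ndhE", "s8", "ndhG", "s9", "ndhI", "s10", "ndhA", "s11",
           "ndhH", "s12", "ycf1", "s13", "ndhF", "s14", "rpl32", "s15"]
    blocks = {}
    for name in lsc + ir_names + ssc:
        blocks[name] = gene(name) if name in lengths else spacer(
            name, spacer_len * 2 if name in ("s1", "s10", "s14") else spacer_len)
    # conversion-junction guards: the first donor base must differ from the
    # ndhF base it replaces, and the bases immediately 5' of the junction
    # must differ between donor context and ndhF, so the chimera boundary
    # is sharply defined (a shared base there would make the tract length
    # genuinely ambiguous)
    t = CONVERSION_TRACT
    while (blocks["ycf1"].cds[-t] == blocks["ndhF"].cds[-t]
           or blocks["ycf1"].cds[-(t + 1)] == blocks["ndhF"].cds[-(t + 1)]):
        cds = blocks["ycf1"].cds
        for i in (len(cds) - t - 1, len(cds) - t):
            cod = i // 3 * 3
            cds = cds[:cod] + str(rng.choice(_NONSTOP)) + cds[cod + 3:]
        blocks["ycf1"].set_cds(cds)
    order = lsc + ir_names + ssc + (["__IRB__"] if ir else [])
    return SimulatedReference(blocks, order, ir_names if ir else [], seed)


# ---------------------------------------------------------------------------
# degradation operators and the truth manifest
# ---------------------------------------------------------------------------

@dataclass
class DegradationSpec:
    gene: str | None           # gene name or spacer block name
    operator: str
    params: dict = field(default_factory=dict)


@dataclass
class TruthManifest:
    events: list[dict] = field(default_factory=list)
    expected_classes: dict[str, int] = field(default_factory=dict)
    expected_region_type: str | None = None
    copy_numbers: dict[str, float] = field(default_factory=dict)
    expected_origins: dict[str, str] = field(default_factory=dict)
    mt_segments: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


def _truth_class(original_len: int, surviving: int, cds: str,
                 net_indel: int, t_del: float = 0.10,
                 t_trunc: float = 0.50) -> int:
    cov = surviving / original_len
    if cov < t_del:
        return 4
    if cov < t_trunc:
        return 3
    if net_indel % 3 != 0:
        return 2
    if len(cds) >= 3:
        prot = translate(cds)
        cutoff = int(len(prot) * 0.95)
        stop = prot.find("*")
        if 0 <= stop < cutoff - 1:
            return 2
        if cds[:3] not in ("ATG", "GTG", "TTG"):
            return 2
    return 1


def apply_degradations(ref: SimulatedReference, specs: list[DegradationSpec],
                       seed: int = 0
                       ) -> tuple[SimulatedReference, SeqRecord, TruthManifest]:
    """Apply engineered degradations; returns (reference, mutated, truth).

    The returned reference differs from the input only by mechanism
    "planting" edits (repeat copies / AT windows written into spacers, in
    both genomes), which is what makes repeat- and AT-evidence detectable
    against the reference frame.  Length-changing edits touch the mutated
    genome only.  Overlapping structural operators on one block are
    rejected.
    """
    rng = np.random.default_rng(seed)
    ref_out = copy.deepcopy(ref)
    mut = copy.deepcopy(ref)
    manifest = TruthManifest()
    structural_blocks: set[str] = set()
    touched: dict[str, dict] = {}  # gene -> {"surviving": int, "net": int}

    def gene_state(g):
        if g not in touched:
            touched[g] = {"surviving": len(ref.genes[g].cds), "net": 0}
        return touched[g]

    for spec in specs:
        op = spec.operator
        p = spec.params
        if op in ("repeat_deletion", "at_deletion"):
            block_name = spec.gene
            if ref_out.blocks[block_name].kind != "spacer":
                raise ValueError(f"{op} must target a spacer block")
            if block_name in structural_blocks:
                raise ValueError(f"overlapping operators on {block_name}")
            structural_blocks.add(block_name)
            _plant_and_delete(ref_out, mut, block_name, op, p, rng, manifest)
            continue
        g = spec.gene
        if g not in ref.genes:
            raise ValueError(f"unknown gene {g}")
        block_r = mut.blocks[g]
        state = gene_state(g)
        cds = block_r.cds
        if op == "substitute":
            cds, ev = _op_substitute(cds, p, rng)
        elif op == "frameshift":
            cds, ev = _op_frameshift(cds, p, rng)
            state["net"] += p.get("delta", 1)
            if p.get("delta", 1) < 0:
                state["surviving"] -= 1
        elif op == "insertion":
            cds, ev = _op_insertion(cds, p, rng)
            state["net"] += ev["length"]
        elif op == "truncate":
            if g in structural_blocks:
                raise ValueError(f"overlapping operators on {g}")
            structural_blocks.add(g)
            cds, ev, removed = _op_truncate(cds, p)
            state["surviving"] -= removed
            state["net"] -= removed
        elif op == "delete_gene":
            structural_blocks.add(g)
            mut.blocks[g].pieces = [""] * len(mut.blocks[g].pieces)
            state["surviving"] = 0
            manifest.events.append({"op": op, "gene": g})
            manifest.expected_classes[g] = 4
            continue
        elif op == "ycf1_conversion":
            t = p.get("tract_len", CONVERSION_TRACT)
            donor = ref.genes["ycf1"].cds[-t:]
            ev = {"op": op, "gene": g, "tract_len": t,
                  "breakpoint": len(cds) - t + 1}
            cds = cds[:-t] + donor
            # the converted tract is no longer reference-derived sequence
            state["surviving"] -= t
        elif op == "delete_tract_3p":
            t = p.get("tract_len", CONVERSION_TRACT)
            structural_blocks.add(g)
            ev = {"op": op, "gene": g, "tract_len": t,
                  "endpoint": len(cds) - t + 1}
            cds = cds[:-t]
            state["surviving"] -= t
            state["net"] -= t
        else:
            raise ValueError(f"unknown operator {op!r}")
        ev.setdefault("gene", g)
        ev.setdefault("op", op)
        manifest.events.append(ev)
        block_r.set_cds(cds)
        manifest.expected_classes[g] = _truth_class(
            len(ref.genes[g].cds), state["surviving"], cds, state["net"])
    # untouched genes are class 1 by construction
    for g in ref.genes.models:
        if g.startswith("ndh"):
            manifest.expected_classes.setdefault(g, 1)
    ref_out.rebuild()
    mut.rebuild()
    mutated = SeqRecord(f"{ref.plastome.id}_mut", mut.plastome.seq)
    return ref_out, mutated, manifest


def _op_substitute(cds: str, p: dict, rng) -> tuple[str, dict]:
    rate = p.get("rate", 0.01)
    ensure_stop = p.get("ensure_stop", False)
    ncod = len(cds) // 3
    n = max(1, round(rate * len(cds)))
    codons = rng.choice(np.arange(2, ncod - 2), size=min(n, ncod - 4),
                        replace=False)
    s = list(cds)
    for ci in sorted(int(c) for c in codons):
        pos = ci * 3 + int(rng.integers(0, 3))
        choices = [b for b in "ACGT" if b != s[pos]]
        for b in rng.permutation(choices):
            s[pos] = b
            if "".join(s[ci * 3:ci * 3 + 3]) not in STOP_CODONS:
                break
        else:
            s[pos] = cds[pos]
    if ensure_stop:
        ci = int(0.4 * ncod)
        s[ci * 3:ci * 3 + 3] = "TAA"
        return "".join(s), {"op": "substitute", "stop_codon": ci + 1,
                            "n_subs": int(len(codons))}
    return "".join(s), {"n_subs": int(len(codons))}


def _op_frameshift(cds: str, p: dict, rng) -> tuple[str, dict]:
    offset = p["offset"]          # 1-based CDS position the indel follows
    delta = p.get("delta", 1)
    if delta == 1:
        base = str(rng.choice(list("ACGT")))
        # avoid creating a homopolymer-extension that the aligner would
        # left-shift to a different offset
        if base == cds[offset - 1]:
            base = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        out = cds[:offset] + base + cds[offset:]
    elif delta == -1:
        out = cds[:offset] + cds[offset + 1:]
    else:
        raise ValueError("frameshift delta must be +-1")
    return out, {"offset": offset, "delta": delta}


def _op_insertion(cds: str, p: dict, rng) -> tuple[str, dict]:
    offset = p["offset"]
    length = p["length"]
    unit_len = p.get("unit_len")
    if unit_len:
        unit = _random_seq(rng, unit_len)
        content = (unit * math.ceil(length / unit_len))[:length]
    else:
        unit = None
        content = _random_seq(rng, length)
    out = cds[:offset] + content + cds[offset:]
    return out, {"offset": offset, "length": length, "unit_len": unit_len,
                 "unit": unit, "content": content}


def _op_truncate(cds: str, p: dict):
    frac = p.get("fraction", 0.6)
    end = p.get("end", "3p")
    k = round(len(cds) * frac)
    if end == "3p":
        out = cds[:-k]
    else:
        out = cds[k:]
    return out, {"fraction": frac, "end": end, "removed": k}, k


def _plant_and_delete(ref_out: SimulatedReference, mut: SimulatedReference,
                      block_name: str, op: str, p: dict, rng,
                      manifest: TruthManifest) -> None:
    """Plant repeat copies or AT windows in a spacer, then delete the tract."""
    block_ref = ref_out.blocks[block_name]
    block_mut = mut.blocks[block_name]
    seq = block_ref.pieces[0]
    if op == "repeat_deletion":
        k = p.get("repeat_len", 12)
        del_len = p.get("del_len", 200)
        margin = k + 2
        if len(seq) < del_len + 2 * margin:
            raise ValueError(f"spacer {block_name} too short for deletion")
        # keep the tract in the spacer's 5' half so it stays well separated
        # from events in the downstream gene
        s_hi = max(margin + 2, min(len(seq) - del_len, len(seq) // 2 - del_len))
        s = int(rng.integers(margin + 1, s_hi))  # 1-based
        e = s + del_len - 1
        copy_seq = _random_seq(rng, k)
        chars = list(seq)
        chars[s - 1 - k:s - 1] = copy_seq           # left copy, retained
        chars[e - k:e] = copy_seq                   # right copy, deleted
        # guard bases on both sides of both copies: the detected repeat
        # length must be exactly the planted one under either equivalent
        # deletion placement
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        if chars[e - 1 - k] == chars[s - 2 - k]:    # 5' of each copy
            chars[e - 1 - k] = alt[chars[e - 1 - k]]
        if chars[e] == chars[s - 1]:                # 3' of each copy
            chars[e] = alt[chars[e]]
        seq_new = "".join(chars)
        block_ref.pieces[0] = seq_new
        block_mut.pieces[0] = seq_new[:s - 1] + seq_new[e:]
        off = ref_out.block_offset(block_name)
        manifest.events.append({
            "op": op, "block": block_name, "repeat_len": k,
            "del_len": del_len, "ref_interval": [off + s, off + e],
            "repeat_seq": copy_seq})
    else:  # at_deletion
        del_len = p.get("del_len", 300)
        window = p.get("window", 20)
        at_frac = p.get("window_at", 1.0)
        half = window // 2
        margin = window + 2
        if len(seq) < del_len + 2 * margin:
            raise ValueError(f"spacer {block_name} too short for deletion")
        s = int(rng.integers(margin + 1, len(seq) - del_len - margin + 1))
        e = s + del_len - 1
        chars = list(seq)
        for bp in (s, e):
            lo = max(bp - half, 1)
            hi = min(bp + half - 1, len(seq))
            for i in range(lo - 1, hi):
                if rng.random() < at_frac:
                    chars[i] = "A" if rng.random() < 0.5 else "T"
        seq_new = "".join(chars)
        block_ref.pieces[0] = seq_new
        block_mut.pieces[0] = seq_new[:s - 1] + seq_new[e:]
        off = ref_out.block_offset(block_name)
        manifest.events.append({
            "op": op, "block": block_name, "del_len": del_len,
            "window": window, "window_at": at_frac,
            "ref_interval": [off + s, off + e]})


# ---------------------------------------------------------------------------
# region variants, chondriome, reads
# ---------------------------------------------------------------------------

def make_region_variants(ref: SimulatedReference,
                         tract_len: int = CONVERSION_TRACT,
                         intergenic_del: int = 150
                         ) -> tuple[dict[str, SeqRecord], dict]:
    """The four canonical ycf1-rpl32 configurations from one reference.

    A: the intact exemplar.  B: the terminal ``tract_len`` of ndhF replaced
    by the ycf1 3' tail.  C: that chimeric tract deleted (B minus tract).
    D: ndhF fully deleted plus an intergenic deletion before rpl32.
    """
    region = ref.region.seq
    r0 = ref.region_interval[0]
    f = ref.genes["ndhF"]
    f_lo = f.exons[0][0] - r0          # 0-based within region
    f_hi = f.exons[-1][1] - r0 + 1
    L = len(f.cds)
    donor = ref.genes["ycf1"].cds[-tract_len:]
    a = region
    b = region[:f_hi - tract_len] + donor + region[f_hi:]
    c = region[:f_hi - tract_len] + region[f_hi:]
    # type D: two deletions -- ndhF itself, and an intergenic tract between
    # the (former) ndhF locus and rpl32
    keep = 80
    d = (region[:f_lo] + region[f_hi:f_hi + keep]
         + region[f_hi + keep + intergenic_del:])
    truth = {
        "breakpoint": L - tract_len + 1,
        "replaced_len": tract_len,
        "types": {"A": "A", "B": "B", "C": "C", "D": "D"},
    }
    recs = {t: SeqRecord(f"region_type{t}", s)
            for t, s in zip("ABCD", (a, b, c, d))}
    return recs, truth


def build_chondriome(plastome: SeqRecord,
                     segments: list[tuple[tuple[int, int], bool]],
                     backbone_len: int = 40000, seed: int = 0,
                     divergence: float = 0.08,
                     gc: float = 0.44) -> tuple[SeqRecord, TruthManifest]:
    """Embed plastome segments into a random mitochondrial backbone.

    ``segments`` are (1-based plastome interval, invert?) pairs; an
    inverted segment carries an *internal* inversion (its central half is
    reverse-complemented between forward-oriented flanks, the way an
    inversion between two gene ends presents inside a transferred tract).
    Each transferred copy accumulates i.i.d. substitutions at
    ``divergence`` (emulating sequence drift since the transfer;
    organellar copies of the same gene are typically ~90% identical).
    Coordinates of every embedded copy are recorded in the manifest.
    """
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, backbone_len, gc)
    manifest = TruthManifest()
    n_seg = len(segments)
    if n_seg == 0:
        rec = SeqRecord(f"toy_chondriome_seed{seed}", backbone)
        return rec, manifest
    gap = backbone_len // (n_seg + 1)
    parts = []
    pos_bb = 0
    pos_out = 0
    for i, ((s, e), invert) in enumerate(segments):
        if not (1 <= s <= e <= len(plastome.seq)):
            raise ValueError(f"segment {s}..{e} outside plastome")
        seg = plastome.seq[s - 1:e]
        inv_local = None
        if invert:
            L = len(seg)
            a, b = L // 4, L // 4 + L // 2   # central half, 0-based half-open
            seg = seg[:a] + revcomp(seg[a:b]) + seg[b:]
            inv_local = [a + 1, b]
        seg = _diverge(seg, divergence, rng)
        chunk = backbone[pos_bb:pos_bb + gap]
        parts.append(chunk)
        pos_out += len(chunk)
        entry = {
            "mt_interval": [pos_out + 1, pos_out + len(seg)],
            "plastome_interval": [s, e],
            "inverted": bool(invert),
            "divergence": divergence,
            "seq": seg,
        }
        if inv_local is not None:
            entry["inversion_plastome_interval"] = [s + inv_local[0] - 1,
                                                    s + inv_local[1] - 1]
            entry["inversion_segment_interval"] = inv_local
        manifest.mt_segments.append(entry)
        parts.append(seg)
        pos_out += len(seg)
        pos_bb += gap
    parts.append(backbone[pos_bb:])
    rec = SeqRecord(f"toy_chondriome_seed{seed}", "".join(parts))
    return rec, manifest


def _diverge(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    n = rng.binomial(len(seq), rate)
    pos = rng.choice(len(seq), size=n, replace=False)
    for i in pos:
        s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


def simulate_reads(genomes: list[tuple[SeqRecord, float]],
                   read_len: int = 100,
                   insert: tuple[float, float] = (300.0, 30.0),
                   n_pairs: int = 10000, error_rate: float = 0.0,
                   seed: int = 0) -> tuple[list[ReadPair], TruthManifest]:
    """Uniform paired-end fragments weighted by copy_number x length.

    Base qualities are Q40; simulated errors carry Q13 so that the Mott
    trimmer sees them the way real miscalls look.  The expected depth ratio
    between two genomes equals their copy-number ratio.
    """
    mean_ins, sd_ins = insert
    if mean_ins <= 2 * read_len:
        raise ValueError("insert mean must exceed 2x read length")
    rng = np.random.default_rng(seed)
    weights = np.array([cn * len(g.seq) for g, cn in genomes], dtype=float)
    probs = weights / weights.sum()
    choices = rng.choice(len(genomes), size=n_pairs, p=probs)
    manifest = TruthManifest(
        copy_numbers={g.id: cn for g, cn in genomes})
    pairs = []
    for i in range(n_pairs):
        g, _ = genomes[int(choices[i])]
        L = len(g.seq)
        ins = int(round(rng.normal(mean_ins, sd_ins)))
        ins = max(2 * read_len, min(ins, L))
        start = int(rng.integers(0, L - ins + 1))
        frag = g.seq[start:start + ins]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        name = f"sim{i:06d}"
        reads = []
        for mate, seq in (("/1", r1), ("/2", r2)):
            qual = [40] * read_len
            if error_rate > 0:
                nerr = rng.binomial(read_len, error_rate)
                if nerr:
                    ep = rng.choice(read_len, size=nerr, replace=False)
                    s = list(seq)
                    for j in ep:
                        s[j] = str(rng.choice(
                            [b for b in "ACGT" if b != s[j]]))
                        qual[j] = 13
                    seq = "".join(s)
            reads.append(SeqRecord(name + mate, seq, quality=qual))
        pairs.append(ReadPair(name, reads[0], reads[1]))
    return pairs, manifest


# ---------------------------------------------------------------------------
# the study-conditions preset
# ---------------------------------------------------------------------------

@dataclass
class Preset:
    reference: SimulatedReference
    mutated: SeqRecord
    manifest: TruthManifest
    chondriome: SeqRecord
    igt_manifest: TruthManifest
    region_variants: dict[str, SeqRecord]
    region_truth: dict


def cymbidium_like(seed: int = 0,
                   igt_len: int = 3000,
                   pt_copy: float = 10.0,
                   mt_copy: float = 1.0) -> Preset:
    """The default study conditions: one gene per degradation class plus
    the canonical class-2 frameshift, repeat- and AT-mediated spacer
    deletions, a tandem insertion, four region variants, and a 3-kb IGT
    segment (plus an inverted one) in the chondriome."""
    ref = make_reference(seed)
    specs = [
        DegradationSpec("ndhB", "frameshift", {"offset": 37, "delta": 1}),
        DegradationSpec("ndhD", "substitute", {"rate": 0.01,
                                               "ensure_stop": True}),
        DegradationSpec("ndhG", "truncate", {"fraction": 0.6, "end": "3p"}),
        DegradationSpec("ndhE", "delete_gene", {}),
        DegradationSpec("ndhK", "insertion", {"offset": 39, "length": 87,
                                              "unit_len": None}),
        DegradationSpec("s1", "repeat_deletion", {"repeat_len": 12,
                                                  "del_len": 200}),
        DegradationSpec("s10", "at_deletion", {"del_len": 300, "window": 20,
                                               "window_at": 1.0}),
    ]
    ref_out, mutated, manifest = apply_degradations(ref, specs, seed)
    # IGT: a 3-kb tract from the SSC (covers ndhE-ndhG) plus an inverted copy
    g = ref.genes
    igt_start = g["ndhE"].exons[0][0] - 200
    segments = [((igt_start, igt_start + igt_len - 1), False),
                ((g["ndhI"].exons[0][0] - 100,
                  g["ndhA"].exons[-1][1] + 100), True)]
    chondriome, igt_manifest = build_chondriome(
        ref.plastome, segments, seed=seed + 1)
    variants, region_truth = make_region_variants(ref)
    manifest.expected_region_type = "A"
    manifest.expected_origins = {ref.plastome.id: "plastid",
                                 chondriome.id: "mitochondrial"}
    manifest.copy_numbers = {ref.plastome.id: pt_copy,
                             chondriome.id: mt_copy}
    return Preset(ref_out, mutated, manifest, chondriome, igt_manifest,
                  variants, region_truth)


def simulate_gene_copies(ref_len: int = 600, n_pt: int = 4, n_mt: int = 4,
                         shared_mt_subs: int = 10, noise_subs: int = 2,
                         seed: int = 0) -> tuple[dict[str, str], set[str]]:
    """Aligned pt/mt copies of one gene: mt copies share derived substitutions.

    Returns (label -> sequence, mt label set).  All sequences have equal
    length (substitutions only), ready for p-distance clustering.
    """
    rng = np.random.default_rng(seed)
    ref_len -= ref_len % 3
    base = _random_cds(rng, ref_len)

    def subs(seq, positions):
        s = list(seq)
        for i in positions:
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        return "".join(s)

    shared = rng.choice(ref_len, size=shared_mt_subs, replace=False)
    mt_base = subs(base, shared)
    out = {}
    for i in range(n_pt):
        pos = rng.choice(ref_len, size=noise_subs, replace=False)
        out[f"pt_{i}"] = subs(base, pos)
    for i in range(n_mt):
        pos = rng.choice(ref_len, size=noise_subs, replace=False)
        out[f"mt_{i}"] = subs(mt_base, pos)
    return out, {k for k in out if k.startswith("mt_")}
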