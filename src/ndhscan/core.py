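"""Sequence, read and gene-model plumbing shared by every pipeline stage.

All coordinates exposed at module interfaces are 1-based inclusive on the
forward strand of the named sequence.  Translation uses the plastid/bacterial
genetic code (NCBI table 11); there is no RNA-editing rescue of stop codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("ndhscan")

NDH_GENES = [
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
    "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK",
]
#: gene order used for 11-character degradation patterns (ndhA..ndhK)
PATTERN_ORDER = list(NDH_GENES)

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed or empty input files."""


def clean_seq(seq: str) -> str:
    """Upcase, map U->T and validate the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ParseError(f"illegal characters in sequence: {sorted(bad)}")
    if not s:
        raise ParseError("empty sequence")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    id: str
    seq: str
    description: str = ""
    quality: list[int] | None = None  # Phred scores, FASTQ only

    def __post_init__(self) -> None:
        self.seq = clean_seq(self.seq)
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ParseError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    name: str
    read1: SeqRecord
    read2: SeqRecord

    def __post_init__(self) -> None:
        for r in (self.read1, self.read2):
            if r.quality is None:
                raise ParseError(f"{self.name}: paired reads need qualities")


@dataclass
class GeneModel:
    """A gene with ordered exons on a source sequence.

    ``exons`` are non-overlapping 1-based inclusive intervals in ascending
    source order; ``cds`` is the concatenated exon sequence in transcript
    orientation (reverse-complemented for '-' strand models).
    """

    gene: str
    exons: list[tuple[int, int]]
    strand: str
    cds: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        last = None
        total = 0
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.gene}: empty exon {s}..{e}")
            if last is not None and s <= last:
                raise ValueError(f"{self.gene}: exons overlap or unordered")
            last = e
            total += e - s + 1
        if total != len(self.cds):
            raise ValueError(
                f"{self.gene}: cds length {len(self.cds)} != exon sum {total}")

    @property
    def exon_seqs(self) -> list[str]:
        """Exon sequences in transcript orientation, sliced from the CDS."""
        lengths = [e - s + 1 for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, pos = [], 0
        for n in lengths:
            out.append(self.cds[pos:pos + n])
            pos += n
        return out


@dataclass
class ReferenceGeneSet:
    """Intact reference gene models keyed by gene name."""

    models: dict[str, GeneModel] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> GeneModel:
        return self.models[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.models


def translate(cds: str, table: int = 11) -> str:
    """Translate frame 0 with stops as '*'; trailing partial codon ignored."""
    if len(cds) < 3:
        raise ValueError("cds shorter than one codon")
    usable = cds[: len(cds) // 3 * 3]
    return str(Seq(usable).translate(table=table))


def load_sequences(path: str | Path, format: str = "fasta"):
    """Load sequences; ``format`` one of fasta, fastq, genbank-lite.

    Returns a list of :class:`SeqRecord`; for genbank-lite returns
    ``(records, gene_models)`` where gene/CDS features (including ``join()``)
    become :class:`GeneModel` entries and all other feature types are ignored
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty input")
    if format == "fasta":
        return _load_fasta(path)
    if format == "fastq":
        return _load_fastq(path)
    if format == "genbank-lite":
        return _load_genbank_lite(path)
    raise ValueError(f"unknown format {format!r}")


def _load_fasta(path: Path) -> list[SeqRecord]:
    recs, seen = [], set()
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise ParseError(f"{path}: line 1: expected '>' header")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description.removeprefix(rec.id).strip()
        recs.append(SeqRecord(rec.id, str(rec.seq), desc))
    if not recs:
        raise ParseError(f"{path}: no records")
    return recs


def _load_fastq(path: Path) -> list[SeqRecord]:
    recs, seen = [], set()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            recs.append(SeqRecord(
                rec.id, str(rec.seq), rec.description,
                quality=list(rec.letter_annotations["phred_quality"])))
    except ValueError as exc:  # Biopython names the offending record
        raise ParseError(f"{path}: {exc}") from exc
    if not recs:
        raise ParseError(f"{path}: no records")
    return recs


def _load_genbank_lite(path: Path):
    records, models = [], []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq)
        records.append(SeqRecord(rec.id, seq, rec.description))
        for feat in rec.features:
            if feat.type not in ("gene", "CDS"):
                if feat.type != "source":
                    log.warning("genbank-lite: ignoring %s feature", feat.type)
                continue
            if feat.type == "gene":
                continue  # gene features duplicate their CDS counterpart
            name = feat.qualifiers.get("gene", ["?"])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            exons = sorted((int(p.start) + 1, int(p.end))
                           for p in feat.location.parts)
            cds = "".join(clean_seq(seq[s - 1:e]) for s, e in exons)
            if strand == "-":
                cds = revcomp(cds)
            models.append(GeneModel(name, exons, strand, cds))
    if not records:
        raise ParseError(f"{path}: no records")
    return records, models


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_genbank_lite(record: SeqRecord, models: Iterable[GeneModel],
                       path: str | Path) -> None:
    """Write a sequence with gene/CDS features in the flat-file subset."""
    from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
    from Bio.SeqRecord import SeqRecord as BioSeqRecord
    features = []
    for m in models:
        strand = 1 if m.strand == "+" else -1
        parts = [SimpleLocation(s - 1, e, strand) for s, e in m.exons]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        features.append(SeqFeature(loc, type="CDS",
                                   qualifiers={"gene": [m.gene]}))
    rec = BioSeqRecord(Seq(record.seq), id=record.id, name=record.id[:16],
                       description=record.description, features=features,
                       annotations={"molecule_type": "DNA"})
    SeqIO.write([rec], str(path), "genbank")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"{rec.id}: no qualities to write")
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
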