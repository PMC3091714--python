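"""Gene-model and sequence I/O.

Internal coordinates are 0-based half-open throughout. GTF I/O converts
to/from the 1-based inclusive convention at the boundary; BED12 is native
0-based. Transcript coordinates always read 5'->3': on the minus strand,
transcript position 0 is the 3'-most genomic exonic base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from gffutils.feature import feature_from_line


class ParseError(ValueError):
    """A malformed input file (GTF/BED/FASTA/TSV)."""


class ModelError(ValueError):
    """A structurally invalid transcript model."""


class CoordinateError(ValueError):
    """A genomic/transcript position outside the model or sequence."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    seqname: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seqname:
            raise ModelError("seqname must be non-empty")
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqname == other.seqname
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A strand-aware ordered exon chain on a named sequence.

    Exons are stored in ascending genomic order regardless of strand; all
    transcript-level accessors (spliced sequence, transcript coordinates)
    are 5'->3' in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    source_tag: str = "alignment"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        seqnames = {e.seqname for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqnames) > 1 or len(strands) > 1:
            raise ModelError(
                f"{self.transcript_id}: exons must share seqname and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ModelError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def seqname(self) -> str:
        return self.exons[0].seqname

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seqname, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) genomic pairs, ascending; empty if single-exon."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def exon_key(self) -> tuple:
        """Canonical hashable identity of the exon chain."""
        return (
            self.seqname,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
        )

    def with_id(self, transcript_id: str, source_tag: str | None = None) -> "TranscriptModel":
        return replace(
            self,
            transcript_id=transcript_id,
            source_tag=source_tag if source_tag is not None else self.source_tag,
        )


class SequenceStore:
    """Uppercase nucleotide sequences keyed by seqname.

    Interval lookups beyond the sequence length are rejected rather than
    silently clipped.
    """

    def __init__(self, sequences: dict[str, str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        for name, seq in (sequences or {}).items():
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise ParseError(f"duplicate sequence name {name!r}")
        if not seq:
            raise ParseError(f"empty sequence record {name!r}")
        up = seq.upper()
        bad = set(up) - set("ACGTN")
        if bad:
            raise ParseError(f"{name}: non-nucleotide characters {sorted(bad)}")
        self._seqs[name] = up

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise CoordinateError(f"unknown sequence {name!r}") from None

    def names(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, seqname: str, start: int, end: int) -> str:
        seq = self[seqname]
        if not (0 <= start < end <= len(seq)):
            raise CoordinateError(
                f"interval [{start},{end}) outside {seqname} (length {len(seq)})"
            )
        return seq[start:end]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def parse_gtf(text: str) -> list[TranscriptModel]:
    """Build transcript models from the exon features of a GTF.

    One model per ``transcript_id``, exons sorted ascending regardless of
    file order; 1-based inclusive GTF coordinates become 0-based half-open.
    Non-exon features are ignored.
    """
    by_tx: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # gffutils raises bare exceptions on bad lines
            raise ParseError(f"line {lineno}: unparseable GTF line ({exc})") from exc
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        if "transcript_id" not in attrs or not attrs["transcript_id"]:
            raise ParseError(f"line {lineno}: exon feature lacks transcript_id")
        tx = attrs["transcript_id"][0]
        gene = attrs["gene_id"][0] if attrs.get("gene_id") else tx
        interval = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, feat.strand
        )
        if tx not in by_tx:
            by_tx[tx] = []
            order.append(tx)
            genes[tx] = gene
        by_tx[tx].append(interval)
    return [
        TranscriptModel(transcript_id=tx, gene_id=genes[tx], exons=by_tx[tx])
        for tx in order
    ]


def write_gtf(models: list[TranscriptModel], source: str = "nmdkit") -> str:
    """Serialize models as exon-only GTF (inverse of :func:`parse_gtf`)."""
    lines = []
    for m in models:
        for e in m.exons:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            if m.source_tag != "alignment":
                attrs += f' source_tag "{m.source_tag}";'
            lines.append(
                "\t".join(
                    [
                        m.seqname,
                        source,
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        m.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def parse_bed12(text: str) -> list[TranscriptModel]:
    """Read transcript models from 12-column BED (native 0-based)."""
    models = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
        chrom, start, _end, name, _score, strand = fields[0:6]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(f"line {lineno}: block count mismatch")
        tx_start = int(start)
        exons = [
            GenomicInterval(chrom, tx_start + s, tx_start + s + sz, strand)
            for s, sz in zip(starts, sizes)
        ]
        models.append(TranscriptModel(transcript_id=name, gene_id=name, exons=exons))
    return models


def write_bed12(models: list[TranscriptModel]) -> str:
    lines = []
    for m in models:
        s = m.span
        sizes = ",".join(str(len(e)) for e in m.exons)
        starts = ",".join(str(e.start - s.start) for e in m.exons)
        lines.append(
            "\t".join(
                [
                    m.seqname,
                    str(s.start),
                    str(s.end),
                    m.transcript_id,
                    "0",
                    m.strand,
                    str(s.start),
                    str(s.end),
                    "0",
                    str(len(m.exons)),
                    sizes,
                    starts,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(text: str) -> SequenceStore:
    """Read a FASTA into a :class:`SequenceStore`.

    Wrapped sequence lines are concatenated, letters uppercased, and the
    header is truncated at the first whitespace. Duplicate names and empty
    records are errors.
    """
    store = SequenceStore()
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        store.add(record.id, str(record.seq))
    return store


def write_fasta(store: SequenceStore, width: int = 60) -> str:
    out = []
    for name in store.names():
        out.append(f">{name}")
        seq = store[name]
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Spliced sequence and coordinate maps
# ---------------------------------------------------------------------------

def spliced_sequence(model: TranscriptModel, store: SequenceStore) -> str:
    """Transcript (5'->3') sequence: exon concatenation, reverse-complemented
    for minus-strand models."""
    parts = [store.fetch(model.seqname, e.start, e.end) for e in model.exons]
    plus = "".join(parts)
    return plus if model.strand == "+" else reverse_complement(plus)


def to_transcript_coord(model: TranscriptModel, genomic_pos: int) -> int:
    """Map an exonic genomic position to its 0-based transcript offset."""
    offset = 0
    plus_offset = None
    for e in model.exons:
        if e.start <= genomic_pos < e.end:
            plus_offset = offset + (genomic_pos - e.start)
            break
        offset += len(e)
    if plus_offset is None:
        raise CoordinateError(
            f"{model.transcript_id}: position {genomic_pos} is not exonic"
        )
    if model.strand == "+":
        return plus_offset
    return model.length - 1 - plus_offset


def to_genomic_coord(model: TranscriptModel, transcript_pos: int) -> int:
    """Inverse of :func:`to_transcript_coord`."""
    if not (0 <= transcript_pos < model.length):
        raise CoordinateError(
            f"{model.transcript_id}: transcript offset {transcript_pos} "
            f"outside [0, {model.length})"
        )
    plus_offset = (
        transcript_pos
        if model.strand == "+"
        else model.length - 1 - transcript_pos
    )
    for e in model.exons:
        if plus_offset < len(e):
            return e.start + plus_offset
        plus_offset -= len(e)
    raise AssertionError("unreachable")


def junction_offsets(model: TranscriptModel) -> tuple[int, ...]:
    """Transcript offsets of exon-exon junctions, 5'->3'.

    A junction's offset is the transcript position of the last base of the
    upstream exon plus one, i.e. the first base of the downstream exon.
    """
    lengths = [len(e) for e in model.exons]
    if model.strand == "-":
        lengths.reverse()
    offsets = []
    acc = 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    return tuple(offsets)


def translate_cds(cds: str) -> str:
    """Translate a CDS (with or without the stop codon); stop excluded."""
    prot = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    return prot.rstrip("*")
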