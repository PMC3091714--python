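"""ORF discovery on spliced transcript sequences.

Only the forward three reading frames of the transcript (5'->3') sequence
are scanned. An ORF runs from an ATG to the first in-frame stop codon;
open-ended reading frames (no stop before the transcript end) are not
ORFs. Codons containing N never act as start or stop codons. The "main"
ORF of a transcript is the largest by codon count, ties going to the
5'-most start — the region upstream of it is taken to be the 5'UTR, and
any ORF starting there is an upstream ORF (uORF).
"""

from __future__ import annotations

from dataclasses import dataclass

from .transcript_io import translate_cds

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class NonCodingError(ValueError):
    """Raised when a transcript contains no ORF at all."""


@dataclass(frozen=True)
class ORFAnnotation:
    """A transcript-relative open reading frame.

    ``start`` is the offset of the A of the ATG; ``stop_end`` is one past
    the last base of the stop codon; ``codons`` counts coding codons
    (including the ATG, excluding the stop).
    """

    start: int
    stop_end: int

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def codons(self) -> int:
        return (self.stop_end - self.start) // 3 - 1

    def validate(self, seq: str) -> None:
        if seq[self.start : self.start + 3] != START_CODON:
            raise ValueError(f"ORF at {self.start} does not begin with ATG")
        if seq[self.stop_end - 3 : self.stop_end] not in STOP_CODONS:
            raise ValueError(f"ORF ending at {self.stop_end} lacks a stop codon")
        if (self.stop_end - self.start) % 3 != 0:
            raise ValueError("ORF length not a multiple of 3")


@dataclass(frozen=True)
class UORF:
    """An ORF upstream of the main ORF; ``overlaps_main`` when its stop
    codon ends past the main ORF's start."""

    orf: ORFAnnotation
    overlaps_main: bool


def find_orfs(seq: str, min_codons: int = 1) -> list[ORFAnnotation]:
    """All ATG-to-first-in-frame-stop ORFs in the forward three frames.

    Nested in-frame ATGs each yield their own ORF (sharing the stop).
    Sorted by start offset, then by end.
    """
    seq = seq.upper()
    orfs: list[ORFAnnotation] = []
    for frame in range(3):
        pending: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == START_CODON:
                pending.append(pos)
            elif codon in STOP_CODONS:
                for start in pending:
                    orf = ORFAnnotation(start=start, stop_end=pos + 3)
                    if orf.codons >= min_codons:
                        orfs.append(orf)
                pending = []
    orfs.sort(key=lambda o: (o.start, o.stop_end))
    return orfs


def largest_orf(seq: str, min_codons: int = 1) -> ORFAnnotation:
    """The ORF with the most codons; ties broken 5'-most."""
    orfs = find_orfs(seq, min_codons=min_codons)
    if not orfs:
        raise NonCodingError("sequence contains no ORF (non-coding)")
    return max(orfs, key=lambda o: (o.codons, -o.start))


def find_uorfs(
    seq: str, main: ORFAnnotation, min_codons: int = 1
) -> list[UORF]:
    """ORFs starting upstream of ``main``; each nested start counts.

    ``overlaps_main`` is set when the uORF's stop codon ends downstream of
    the main start (stop_end > main.start).
    """
    return [
        UORF(orf=o, overlaps_main=o.stop_end > main.start)
        for o in find_orfs(seq, min_codons=min_codons)
        if o.start < main.start
    ]


def orf_protein(seq: str, orf: ORFAnnotation) -> str:
    """Amino-acid translation of an ORF, stop codon excluded."""
    return translate_cds(seq[orf.start : orf.stop_end])
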