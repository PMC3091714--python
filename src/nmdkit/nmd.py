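"""NMD-activating-feature classification and peptide-evidence filtering.

A stop codon is called premature (PTC) when an exon-exon junction lies
more than ``threshold_nt`` (default 50) nucleotides downstream of it —
the positional signature of exon-junction-complex-dependent NMD. A gene
is called AS-NMD when any of its (maximal) transcripts carries a PTC.
Candidate NMD-sensitive isoforms are additionally required to encode, in
the protein of their largest ORF, every peptide identified for the gene
by mass spectrometry: an isoform that fails to encode even one observed
peptide cannot explain the observed protein and is eliminated.

uORFs are reported as features of the transcript but the 50-nt rule is
not applied to their own stop codons; only the termination codon of the
largest ORF is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

from .orf import ORFAnnotation, UORF, find_uorfs, largest_orf, orf_protein, NonCodingError
from .transcript_io import (
    SequenceStore,
    TranscriptModel,
    junction_offsets,
    spliced_sequence,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class NMDReport:
    """Per-transcript NMD feature calls."""

    transcript_id: str
    main_orf: ORFAnnotation | None
    junction_offsets: tuple[int, ...]
    downstream_junction_distances: tuple[int, ...]
    ptc_flag: bool
    utr3_intron_count: int
    uorfs: list[UORF]
    peptide_consistent: bool | None = None  # None: not evaluated
    peptide_match_count: int | None = None


@dataclass
class PeptideEvidence:
    """Mass-spec peptides observed for one gene."""

    gene_id: str
    peptides: list[str]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValueError(f"{self.gene_id}: peptide list must be non-empty")
        for p in self.peptides:
            bad = set(p.upper()) - AMINO_ACIDS
            if not p or bad:
                raise ValueError(
                    f"{self.gene_id}: invalid peptide {p!r} (bad residues {sorted(bad)})"
                )
        if self.scores is not None and len(self.scores) != len(self.peptides):
            raise ValueError("scores must align with peptides")


@dataclass
class GeneNMDCall:
    """Gene-level AS-NMD designation with per-transcript evidence."""

    gene_id: str
    as_nmd: bool
    reports: list[NMDReport] = field(default_factory=list)
    candidate_transcript_ids: list[str] = field(default_factory=list)
    status: str = ""


def classify_transcript(
    model: TranscriptModel,
    store: SequenceStore,
    threshold_nt: int = 50,
    min_uorf_codons: int = 1,
) -> NMDReport:
    """Apply the 50-nt rule and uORF scan to one transcript.

    Junction offsets are transcript positions of the first base of each
    downstream exon; the distance to a junction is ``offset - stop_end``
    and only strictly positive distances (junctions in the 3'UTR) count.
    A transcript with no ORF is reported non-coding and never flagged.
    """
    seq = spliced_sequence(model, store)
    offsets = junction_offsets(model)
    try:
        main = largest_orf(seq)
    except NonCodingError:
        logger.warning("%s: no ORF found; treated as non-coding", model.transcript_id)
        return NMDReport(
            transcript_id=model.transcript_id,
            main_orf=None,
            junction_offsets=offsets,
            downstream_junction_distances=(),
            ptc_flag=False,
            utr3_intron_count=0,
            uorfs=[],
        )
    distances = tuple(off - main.stop_end for off in offsets if off - main.stop_end > 0)
    return NMDReport(
        transcript_id=model.transcript_id,
        main_orf=main,
        junction_offsets=offsets,
        downstream_junction_distances=distances,
        ptc_flag=any(d > threshold_nt for d in distances),
        utr3_intron_count=len(distances),
        uorfs=find_uorfs(seq, main, min_codons=min_uorf_codons),
    )


def classify_gene(reports: list[NMDReport], gene_id: str = "") -> GeneNMDCall:
    """AS-NMD call for a gene: flagged iff any transcript carries a PTC."""
    if not reports:
        raise ValueError("classify_gene requires at least one transcript report")
    flagged = [r.transcript_id for r in reports if r.ptc_flag]
    return GeneNMDCall(
        gene_id=gene_id,
        as_nmd=bool(flagged),
        reports=list(reports),
        candidate_transcript_ids=[
            t for t in flagged
            if next(r for r in reports if r.transcript_id == t).peptide_consistent
            is not False
        ],
    )


def peptide_consistent(
    protein: str, evidence: PeptideEvidence, il_equivalent: bool = False
) -> bool:
    """True iff every observed peptide is a contiguous substring of ``protein``.

    Case-insensitive; with ``il_equivalent`` isoleucine and leucine are
    treated as indistinguishable (mass spectrometry cannot tell them apart).
    """
    if not protein:
        return False
    prot = protein.upper()
    if il_equivalent:
        prot = prot.replace("I", "L")
    for pep in evidence.peptides:
        p = pep.upper()
        if il_equivalent:
            p = p.replace("I", "L")
        if p not in prot:
            return False
    return True


def peptide_match_count(
    protein: str, evidence: PeptideEvidence, il_equivalent: bool = False
) -> int:
    """Number of observed peptides found in ``protein``."""
    if not protein:
        return 0
    prot = protein.upper()
    if il_equivalent:
        prot = prot.replace("I", "L")
    count = 0
    for pep in evidence.peptides:
        p = pep.upper()
        if il_equivalent:
            p = p.replace("I", "L")
        if p in prot:
            count += 1
    return count


def filter_by_peptides(
    gene_call: GeneNMDCall,
    proteins: Mapping[str, str],
    evidence: PeptideEvidence,
    il_equivalent: bool = False,
) -> GeneNMDCall:
    """Restrict candidates to PTC-flagged isoforms encoding all peptides.

    ``proteins`` maps transcript_id to the protein of its largest ORF
    (non-coding transcripts may be absent or map to ""). Isoforms whose
    protein lacks any observed peptide are eliminated — e.g. a poison-exon
    isoform truncating the protein upstream of an observed peptide cannot
    be the source of the identified protein.
    """
    new_reports = []
    for r in gene_call.reports:
        prot = proteins.get(r.transcript_id, "")
        new_reports.append(
            replace(
                r,
                peptide_consistent=peptide_consistent(prot, evidence, il_equivalent),
                peptide_match_count=peptide_match_count(prot, evidence, il_equivalent),
            )
        )
    candidates = [
        r.transcript_id for r in new_reports if r.ptc_flag and r.peptide_consistent
    ]
    status = "" if candidates else "no NMD-flagged isoform encodes all observed peptides"
    return GeneNMDCall(
        gene_id=gene_call.gene_id,
        as_nmd=gene_call.as_nmd,
        reports=new_reports,
        candidate_transcript_ids=candidates,
        status=status,
    )


def transcript_protein(model: TranscriptModel, store: SequenceStore) -> str:
    """Protein of the largest ORF of a transcript ("" if non-coding)."""
    seq = spliced_sequence(model, store)
    try:
        main = largest_orf(seq)
    except NonCodingError:
        return ""
    return orf_protein(seq, main)
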