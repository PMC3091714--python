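"""Subsumption of compatible spliced alignments into maximal transcripts.

EST-assembly style: alignments whose intron chains agree wherever they
overlap are merged, transitively, until the remaining assemblies are
pairwise incompatible. Each output ("maximal transcript") records the ids
of every alignment it subsumed. The compatibility rule here is a
deliberate simplification of full EST-assembly behaviour: it checks intron
chain agreement within the genomic overlap only and treats single-exon
alignments as compatible with anything they share exonic sequence with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .transcript_io import GenomicInterval, TranscriptModel


@dataclass
class MaximalTranscript:
    """A merged assembly plus the ids of the alignments it subsumes."""

    model: TranscriptModel
    supporting_ids: frozenset[str]
    single_exon_only: bool = False

    def __post_init__(self) -> None:
        if not self.supporting_ids:
            raise ValueError("supporting_ids must be non-empty")


def intron_chain(model: TranscriptModel) -> tuple[tuple[int, int], ...]:
    """Ordered (donor, acceptor) pairs; empty for single-exon models."""
    return model.introns


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Number of genomic bases exonic in both models."""
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def compatible(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff the two alignments can be subsumed into one isoform.

    Requires the same seqname and strand and at least one shared exonic
    base, and identical intron sets within the genomic overlap window:
    every intron of either model that intersects the window must be an
    intron of both. A single-exon model lying inside a partner's exonic
    structure is trivially compatible (its empty chain matches); one whose
    exon reaches into a partner's intron conflicts with the splice and is
    not — it stays its own assembly rather than bridging isoforms.
    """
    if a.seqname != b.seqname or a.strand != b.strand:
        return False
    if _exonic_overlap(a, b) < 1:
        return False
    lo = max(a.span.start, b.span.start)
    hi = min(a.span.end, b.span.end)
    in_window_a = {i for i in a.introns if i[0] < hi and i[1] > lo}
    in_window_b = {i for i in b.introns if i[0] < hi and i[1] > lo}
    return in_window_a == in_window_b


def _merge_exons(a: TranscriptModel, b: TranscriptModel) -> list[GenomicInterval]:
    """Union of exonic base coverage; introns are the remaining gaps."""
    ivs = sorted(
        [(e.start, e.end) for e in a.exons] + [(e.start, e.end) for e in b.exons]
    )
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [GenomicInterval(a.seqname, s, e, a.strand) for s, e in merged]


def subsume(alignments: list[TranscriptModel]) -> list[MaximalTranscript]:
    """Greedy transitive merging of compatible alignments to a fixed point.

    Assemblies are scanned in ascending span order; after any merge the
    scan restarts, so the fixed point is independent of input order. The
    outputs are pairwise incompatible, and every input id appears in
    exactly one assembly's ``supporting_ids``.
    """
    if not alignments:
        raise ValueError("subsume requires at least one alignment")

    work: list[tuple[TranscriptModel, frozenset[str]]] = [
        (m, frozenset([m.transcript_id])) for m in alignments
    ]

    def sort_key(item: tuple[TranscriptModel, frozenset[str]]):
        m, ids = item
        return (m.seqname, m.strand, m.span.start, m.span.end, m.exon_key(), sorted(ids))

    work.sort(key=sort_key)
    merged_any = True
    while merged_any:
        merged_any = False
        n = len(work)
        for i in range(n):
            for j in range(i + 1, n):
                mi, ii = work[i]
                mj, ij = work[j]
                if compatible(mi, mj):
                    exons = _merge_exons(mi, mj)
                    merged = TranscriptModel(
                        transcript_id=mi.transcript_id,
                        gene_id=mi.gene_id,
                        exons=exons,
                        source_tag="maximal",
                    )
                    work[i] = (merged, ii | ij)
                    del work[j]
                    work.sort(key=sort_key)
                    merged_any = True
                    break
            if merged_any:
                break

    out = []
    for k, (model, ids) in enumerate(work, start=1):
        single_only = all(
            len(next(m for m in alignments if m.transcript_id == i).exons) == 1
            for i in ids
        )
        out.append(
            MaximalTranscript(
                model=TranscriptModel(
                    transcript_id=f"{model.gene_id}.asm{k}",
                    gene_id=model.gene_id,
                    exons=model.exons,
                    source_tag="maximal",
                ),
                supporting_ids=ids,
                single_exon_only=single_only,
            )
        )
    return out
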