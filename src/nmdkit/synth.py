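"""Fully labelled synthetic inputs for every pipeline stage.

Generates gene loci with planted NMD-activating features (uORFs, 3'UTR
introns at controlled stop-to-junction distances), spot-abundance
matrices with two-knockdowns-vs-control designs, replicate QPCR
quantities with multiplicative noise, and peptide evidence — each a pure
function of its parameters and a seed.

Sequence construction guarantees exact truth labels by keeping the codon
landscape under control rather than relying on probability:

* every planted stop codon is TAA;
* any ATG that was not deliberately planted has its T replaced by C —
  an edit that can never create a new ATG or stop codon (both are C-free);
* introns begin and end with "CC", so no start or stop codon can span an
  exon-intron boundary in any spliced or intron-retained isoform.

As a result the ORF inventory of every generated transcript is exactly
the main ORF plus the planted uORFs, and a transcript's PTC status is
exactly determined by its planted stop-to-junction distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nmd import PeptideEvidence
from .transcript_io import (
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    translate_cds,
)
from .validation import SpotMatrix

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
# codons usable inside a planted reading frame: no stop, no ATG
_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class UORFSpec:
    codons: int
    overlaps_main: bool


@dataclass(frozen=True)
class IsoformTruth:
    transcript_id: str
    ptc_flag: bool
    utr3_distances: tuple[int, ...]
    n_junctions: int


@dataclass
class GeneTruth:
    """Planted features of one synthetic gene."""

    gene_id: str
    strand: str
    protein: str
    uorfs: tuple[UORFSpec, ...]
    isoforms: dict[str, IsoformTruth]
    nmd_isoform: str | None  # transcript carrying a PTC, if any


@dataclass
class ExpressionTruth:
    """Planted per-spot effects behind a synthetic spot matrix."""

    effects: dict[str, np.ndarray]  # condition -> per-spot log effect
    sigma: float
    missing_rate: float
    seed: int


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(_BASES), size=n))


def _safe_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n)]


def _scrub_atg(seq: list[str], protected_starts: set[int]) -> None:
    """Replace the T of every unplanted ATG with C, in place."""
    for i in range(len(seq) - 2):
        if (
            seq[i] == "A"
            and seq[i + 1] == "T"
            and seq[i + 2] == "G"
            and i not in protected_starts
        ):
            seq[i + 1] = "C"


def _scrub_frame_stops(
    seq: list[str], lo: int, hi: int, frame_anchor: int, protected: set[int]
) -> None:
    """Remove stop codons at positions ``p ≡ frame_anchor (mod 3)`` in
    [lo, hi) by editing the first unprotected base of each to C."""
    start = lo + ((frame_anchor - lo) % 3)
    for p in range(start, hi - 2, 3):
        if "".join(seq[p : p + 3]) in _STOPS:
            for q in (p, p + 1, p + 2):
                if q not in protected:
                    seq[q] = "C"
                    break
            else:
                raise AssertionError("stop codon fully inside protected region")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Gene set
# ---------------------------------------------------------------------------

GENE_CLASSES = ("utr3_intron", "uorf", "none")
DEFAULT_FEATURE_MIX = {"utr3_intron": 0.4, "uorf": 0.4, "none": 0.2}


@dataclass
class _UORFPlan:
    codons: int
    overlap: bool
    shift: int = 0      # (u5_len - start) % 3, overlap type only
    back: int = 0       # nt from start to the CDS boundary, overlap type only
    stop_codon_idx: int = 0  # CDS codon carrying the planted stop, overlap only


def synth_gene_set(
    n_genes: int,
    feature_mix: dict[str, float] | None = None,
    seed: int = 0,
    distance_range: tuple[int, int] = (10, 200),
    uorf_codon_range: tuple[int, int] = (1, 30),
) -> tuple[SequenceStore, list[TranscriptModel], list[GeneTruth]]:
    """Generate a chromosome, isoform models, and per-gene truth labels.

    Feature classes: ``utr3_intron`` genes emit a spliced isoform whose
    3'UTR junction lies ``d`` nt past the stop (d drawn from
    ``distance_range``; the first two such genes get the boundary values
    50 and 51) plus an intron-retained isoform; ``uorf`` genes carry one
    or two planted uORFs (codon lengths from ``uorf_codon_range``, the
    last sometimes overlapping the main ORF); ``none`` genes have neither
    feature. About half the genes additionally carry an intron inside the
    CDS, and about 30% lie on the minus strand. Deterministic under
    ``seed``.
    """
    mix = dict(feature_mix or DEFAULT_FEATURE_MIX)
    unknown = set(mix) - set(GENE_CLASSES)
    if unknown or abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
        raise ValueError(
            f"feature_mix must be non-negative proportions over {GENE_CLASSES} summing to 1"
        )
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        GENE_CLASSES, size=n_genes, p=[mix.get(c, 0.0) for c in GENE_CLASSES]
    )

    chrom_parts: list[str] = []
    offset = 0
    models: list[TranscriptModel] = []
    truths: list[GeneTruth] = []
    boundary_queue = [50, 51]  # forced distances for the first utr3_intron genes

    for g_idx in range(n_genes):
        gene_id = f"g{g_idx + 1:04d}"
        gclass = str(classes[g_idx])
        strand = "-" if rng.random() < 0.3 else "+"
        n_codons = int(rng.integers(60, 121))

        # --- plan uORFs -------------------------------------------------
        plans: list[_UORFPlan] = []
        if gclass == "uorf":
            n_uorfs = int(rng.integers(1, 3))
            for u in range(n_uorfs):
                k = int(rng.integers(uorf_codon_range[0], uorf_codon_range[1] + 1))
                if u == n_uorfs - 1 and rng.random() < 0.3:
                    shift = int(rng.integers(1, 3))
                    back = 3 * int(rng.integers(2, 9)) + shift
                    plans.append(
                        _UORFPlan(
                            codons=0,  # filled in below
                            overlap=True,
                            shift=shift,
                            back=back,
                            stop_codon_idx=int(rng.integers(3, 9)),
                        )
                    )
                else:
                    plans.append(_UORFPlan(codons=k, overlap=False))

        gaps = [int(rng.integers(3, 10)) for _ in plans]
        body_total = sum(
            3 * p.codons + 3 + g for p, g in zip(plans, gaps) if not p.overlap
        )
        tail = max((p.back + 6 for p in plans if p.overlap), default=6)
        u5_len = max(int(rng.integers(60, 151)), 3 + body_total + tail)

        # --- build the exonic (fully spliced) sequence E -----------------
        utr5 = _random_seq(rng, u5_len)
        cds_seq = list(
            "ATG" + "".join(_safe_codons(rng, n_codons - 1)) + "TAA"
        )
        cds_start = u5_len
        cds_stop_end = u5_len + len(cds_seq)
        protected_starts: set[int] = {cds_start}
        protected: set[int] = set(range(cds_start, cds_start + 3)) | set(
            range(cds_stop_end - 3, cds_stop_end)
        )

        uorf_specs: list[UORFSpec] = []
        overlap_paths: list[tuple[int, int]] = []  # (uorf start, planted stop pos)
        cursor = 3
        for plan, gap in zip(plans, gaps):
            if plan.overlap:
                p = u5_len - plan.back
                j = plan.stop_codon_idx
                if plan.shift == 1:
                    s = cds_start + 3 * j + 2
                    cds_seq[3 * j : 3 * j + 6] = list("CCTAAA")
                else:
                    s = cds_start + 3 * j + 1
                    cds_seq[3 * j : 3 * j + 6] = list("CTAAAA")
                utr5[p : p + 3] = list("ATG")
                protected_starts.add(p)
                protected |= set(range(p, p + 3)) | set(range(s, s + 3))
                overlap_paths.append((p, s))
                uorf_specs.append(
                    UORFSpec(codons=(s - p) // 3, overlaps_main=True)
                )
            else:
                body = list(
                    "ATG" + "".join(_safe_codons(rng, plan.codons - 1)) + "TAA"
                )
                p = cursor
                utr5[p : p + len(body)] = body
                protected_starts.add(p)
                protected |= set(range(p, p + 3))
                protected |= set(range(p + len(body) - 3, p + len(body)))
                uorf_specs.append(UORFSpec(codons=plan.codons, overlaps_main=False))
                cursor = p + len(body) + gap

        seq = utr5 + cds_seq
        for p, s in overlap_paths:
            _scrub_frame_stops(seq, p + 3, s, p, protected)

        # --- 3' structure ------------------------------------------------
        introns: list[tuple[int, str]] = []  # (transcript insert point, sequence)
        if rng.random() < 0.5:
            cpos = cds_start + 3 * int(rng.integers(10, n_codons - 10))
            introns.append((cpos, _make_intron(rng)))

        if gclass == "utr3_intron":
            d = (
                boundary_queue.pop(0)
                if boundary_queue
                else int(rng.integers(distance_range[0], distance_range[1] + 1))
            )
            seq = seq + _random_seq(rng, d)
            introns.append((len(seq), _make_intron(rng)))
            seq = seq + _random_seq(rng, int(rng.integers(40, 101)))
        else:
            seq = seq + _random_seq(rng, int(rng.integers(40, 151)))

        _scrub_atg(seq, protected_starts)
        introns.sort(key=lambda x: x[0])
        exonic = "".join(seq)

        # --- genomic assembly and isoform exon chains ---------------------
        genomic = _insert_introns(exonic, introns)
        gene_len = len(genomic)
        masks = [[True] * len(introns)]
        if gclass == "utr3_intron" and introns:
            retained = [True] * len(introns)
            retained[-1] = False
            masks.append(retained)

        iso_truths: dict[str, IsoformTruth] = {}
        nmd_isoform = None
        for iso_idx, mask in enumerate(masks, start=1):
            tx_id = f"{gene_id}.t{iso_idx}"
            exons_t = _exons_from_mask(exonic, introns, mask)
            if strand == "-":
                exons_g = [
                    GenomicInterval(
                        "chr1", offset + gene_len - e, offset + gene_len - s, "-"
                    )
                    for s, e in exons_t
                ]
            else:
                exons_g = [
                    GenomicInterval("chr1", offset + s, offset + e, "+")
                    for s, e in exons_t
                ]
            models.append(
                TranscriptModel(transcript_id=tx_id, gene_id=gene_id, exons=exons_g)
            )
            utr3_distances = tuple(
                pos - cds_stop_end
                for k_i, (pos, _) in enumerate(introns)
                if mask[k_i] and pos - cds_stop_end > 0
            )
            ptc = any(dist > 50 for dist in utr3_distances)
            iso_truths[tx_id] = IsoformTruth(
                transcript_id=tx_id,
                ptc_flag=ptc,
                utr3_distances=utr3_distances,
                n_junctions=sum(mask),
            )
            if ptc and nmd_isoform is None:
                nmd_isoform = tx_id

        truths.append(
            GeneTruth(
                gene_id=gene_id,
                strand=strand,
                protein=translate_cds(exonic[cds_start:cds_stop_end]),
                uorfs=tuple(uorf_specs),
                isoforms=iso_truths,
                nmd_isoform=nmd_isoform,
            )
        )

        chrom_parts.append(genomic if strand == "+" else _revcomp(genomic))
        offset += gene_len
        spacer = "".join(_random_seq(rng, int(rng.integers(50, 201))))
        chrom_parts.append(spacer)
        offset += len(spacer)

    store = SequenceStore({"chr1": "".join(chrom_parts)})
    return store, models, truths


def _make_intron(rng: np.random.Generator) -> str:
    ilen = int(rng.integers(80, 151))
    body = _random_seq(rng, ilen - 4)
    _scrub_atg(body, set())
    return "CC" + "".join(body) + "CC"


def _insert_introns(exonic: str, introns: list[tuple[int, str]]) -> str:
    parts = []
    prev = 0
    for pos, iseq in sorted(introns, key=lambda x: x[0]):
        parts.append(exonic[prev:pos])
        parts.append(iseq)
        prev = pos
    parts.append(exonic[prev:])
    return "".join(parts)


def _exons_from_mask(
    exonic: str, introns: list[tuple[int, str]], mask: list[bool]
) -> list[tuple[int, int]]:
    """Locus-relative (plus-strand) exon intervals of one isoform.

    ``mask[k]`` is True when the isoform splices intron k out; a retained
    intron is exonic and merges with its flanks.
    """
    pieces: list[tuple[int, int, bool]] = []
    g = 0
    prev = 0
    for k, (pos, iseq) in enumerate(introns):
        seg = pos - prev
        pieces.append((g, g + seg, True))
        g += seg
        pieces.append((g, g + len(iseq), not mask[k]))
        g += len(iseq)
        prev = pos
    pieces.append((g, g + len(exonic) - prev, True))

    merged: list[list[int]] = []
    for s, e, is_exon in pieces:
        if not is_exon or e == s:
            continue
        if merged and s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Spot matrix
# ---------------------------------------------------------------------------

def synth_spot_matrix(
    n_spots: int,
    n_per_group: int,
    effect_table: dict[str, np.ndarray | float] | None = None,
    sigma: float = 0.15,
    missing_rate: float = 0.1,
    seed: int = 0,
    log_base: float = 2.0,
) -> tuple[SpotMatrix, ExpressionTruth]:
    """Spots x samples log-abundance matrix with planted condition effects.

    ``effect_table`` maps non-control conditions to per-spot log effects
    (scalar broadcast); the default plants no effect in two knockdown
    conditions, emulating a two-siRNAs-vs-control design. Log abundance =
    baseline + effect + N(0, sigma); entries go missing independently at
    ``missing_rate``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    if effect_table is None:
        effect_table = {"kd_a": 0.0, "kd_b": 0.0}
    conditions = ["control"] + list(effect_table)
    effects = {
        cond: np.broadcast_to(np.asarray(eff, dtype=float), (n_spots,)).copy()
        for cond, eff in effect_table.items()
    }
    effects["control"] = np.zeros(n_spots)

    baseline = rng.normal(7.0, 1.0, size=n_spots)
    columns, cond_labels, data = [], [], []
    for cond in conditions:
        for r in range(1, n_per_group + 1):
            name = f"{cond}_{r}"
            columns.append(name)
            cond_labels.append(cond)
            vals = baseline + effects[cond] + rng.normal(0.0, sigma, size=n_spots)
            if missing_rate > 0:
                vals = np.where(rng.random(n_spots) < missing_rate, np.nan, vals)
            data.append(vals)

    values = pd.DataFrame(
        np.column_stack(data),
        index=[f"spot{i + 1:05d}" for i in range(n_spots)],
        columns=columns,
    )
    matrix = SpotMatrix(
        values=values,
        conditions=pd.Series(cond_labels, index=columns),
        log_base=log_base,
    )
    truth = ExpressionTruth(
        effects=effects, sigma=sigma, missing_rate=missing_rate, seed=seed
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# QPCR
# ---------------------------------------------------------------------------

def synth_qpcr(
    genes: list[str],
    true_folds_kd: dict[str, float],
    true_folds_chx: dict[str, float],
    cv: float = 0.10,
    n_reps: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate QPCR quantities with multiplicative log-normal noise.

    For each gene and condition (control / upf1_kd / chx) the
    gene-of-interest quantity is its baseline times the planted fold times
    log-normal noise of coefficient of variation ``cv``; the reference
    gene gets independent noise around a fixed baseline.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for gene in genes:
        base = float(rng.uniform(20.0, 200.0))
        for cond, fold in (
            ("control", 1.0),
            ("upf1_kd", true_folds_kd.get(gene, 1.0)),
            ("chx", true_folds_chx.get(gene, 1.0)),
        ):
            for r in range(1, n_reps + 1):
                goi = base * fold * float(np.exp(rng.normal(0.0, sigma)))
                ref = 100.0 * float(np.exp(rng.normal(0.0, sigma)))
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{cond}_{r}",
                        "condition": cond,
                        "quantity_goi": goi,
                        "quantity_reference": ref,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------

def synth_peptides(
    protein: str,
    n_peptides: int = 5,
    length_range: tuple[int, int] = (8, 15),
    corrupt: bool = False,
    seed: int = 0,
) -> PeptideEvidence:
    """Peptides sampled uniformly as substrings of ``protein``.

    With ``corrupt``, one residue of one peptide is mutated so that the
    peptide-consistency check must fail (unless the mutated string happens
    to occur elsewhere in the protein).
    """
    lo, hi = length_range
    if len(protein) < hi:
        raise ValueError("protein shorter than the maximum peptide length")
    rng = np.random.default_rng(seed)
    peptides = []
    for _ in range(n_peptides):
        ln = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(protein) - ln + 1))
        peptides.append(protein[start : start + ln])
    if corrupt:
        idx = int(rng.integers(0, n_peptides))
        pep = list(peptides[idx])
        pos = int(rng.integers(0, len(pep)))
        alphabet = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != pep[pos]]
        pep[pos] = str(rng.choice(alphabet))
        peptides[idx] = "".join(pep)
    return PeptideEvidence(gene_id="synthetic", peptides=peptides)
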