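# nmdkit

Prediction and expression-based validation of targets of
**nonsense-mediated mRNA decay (NMD)**, with a focus on decay coupled to
alternative splicing (AS-NMD).

In mammals a termination codon is read as premature (a PTC) when splicing
deposits an exon junction complex well downstream of it: one or more
exon–exon junctions **more than 50 nt downstream of the stop codon** mark
the mRNA for degradation. Genes exploit this deliberately — splicing an
intron into the 3'UTR, including a "poison" exon, or carrying upstream
open reading frames (uORFs) — to make particular isoforms NMD-sensitive.
`nmdkit` implements the computational chain used to find such genes from
isoform-level evidence and to confirm them with expression data:

1. **Maximal transcript assembly** — spliced alignments whose intron
   chains agree wherever they overlap are subsumed, transitively, into
   maximal transcripts representing candidate isoforms
   (`nmdkit.assembly.subsume`).
2. **ORF annotation** — for each transcript the largest ORF (most codons,
   ties 5'-most) defines the CDS; the region upstream is the 5'UTR, and
   every ATG-initiated ORF there is a uORF (`nmdkit.orf`).
3. **NMD feature classification** — a transcript is flagged when any
   junction lies > 50 nt (configurable) past the stop of its largest ORF;
   a gene is called AS-NMD when any isoform is flagged (`nmdkit.nmd`).
4. **Peptide-consistency filtering** — candidate isoforms must encode
   *every* mass-spec-identified peptide of their gene in the protein of
   their largest ORF; isoforms truncating the protein upstream of an
   observed peptide are eliminated.
5. **Expression validation** — per-spot equal-variance Student t-tests
   (two-tailed, p < 0.01) on proteomics spot matrices with a 75% presence
   filter and PCA diagnostics; reference-normalized QPCR fold changes;
   and the two-round criterion: a gene is a *bona fide* NMD target only
   if its mRNA increases significantly (one-tailed, p < 0.05) after both
   decay-factor knockdown **and** translation inhibition
   (`nmdkit.validation`).
6. **Synthetic cohorts** — `nmdkit.synth` generates genomes, isoforms
   with planted uORFs and 3'UTR introns at controlled stop-to-junction
   distances, spot matrices, QPCR replicates and peptide evidence with
   exact truth labels, so the whole pipeline is testable without any
   external data.

## Worked example

```python
from nmdkit import synth_gene_set, classify_transcript, classify_gene

store, models, truths = synth_gene_set(6, seed=4)
by_gene = {}
for m in models:
    by_gene.setdefault(m.gene_id, []).append(m)
for gene_id, group in by_gene.items():
    reports = [classify_transcript(m, store) for m in group]
    call = classify_gene(reports, gene_id=gene_id)
    for r in reports:
        print(f"{r.transcript_id}  ptc={r.ptc_flag}  "
              f"utr3_introns={r.utr3_intron_count}  uORFs={len(r.uorfs)}  "
              f"max_downstream={max(r.downstream_junction_distances, default=0)}")
    print(f"{gene_id}: as_nmd={call.as_nmd}")
```

prints

```
g0001.t1  ptc=False  utr3_introns=0  uORFs=0  max_downstream=0
g0001: as_nmd=False
g0002.t1  ptc=False  utr3_introns=0  uORFs=2  max_downstream=0
g0002: as_nmd=False
g0003.t1  ptc=False  utr3_introns=0  uORFs=0  max_downstream=0
g0003: as_nmd=False
g0004.t1  ptc=False  utr3_introns=1  uORFs=0  max_downstream=50
g0004.t2  ptc=False  utr3_introns=0  uORFs=0  max_downstream=0
g0004: as_nmd=False
g0005.t1  ptc=False  utr3_introns=0  uORFs=2  max_downstream=0
g0005: as_nmd=False
g0006.t1  ptc=True  utr3_introns=1  uORFs=0  max_downstream=51
g0006.t2  ptc=False  utr3_introns=0  uORFs=0  max_downstream=0
g0006: as_nmd=True
```

Genes `g0004` and `g0006` both splice a 3'UTR intron, with junctions 50
and 51 nt past the stop respectively: only the 51-nt isoform is flagged —
the rule is strictly "greater than 50 nt". `g0002` and `g0005` carry
planted uORFs (reported as features, but uORFs alone do not flag a gene),
and the `.t2` isoforms retain their 3'UTR intron, so their stop codon
looks normal.

The same steps are available from a shell:

```bash
nmdkit synth -o cohort --n-genes 50 --seed 4
nmdkit assemble cohort.gtf -o cohort.maximal.gtf
nmdkit classify cohort.gtf cohort.fa -o cohort
nmdkit qpcr-validate qpcr.tsv -o outcomes.tsv
```

## Layout

```
src/nmdkit/
  transcript_io.py   GTF/BED12/FASTA I/O, spliced sequences, coordinate maps
  assembly.py        compatibility rule and maximal-transcript subsumption
  orf.py             ORF discovery, largest-ORF and uORF calls
  nmd.py             PTC rule, gene calls, peptide-consistency filter
  validation.py      spot statistics, PCA, QPCR folds, two-round validation
  synth.py           labelled synthetic data generators
  cli.py             click command-line interface
docs/methods.md      models, assumptions, parameter choices, limitations
```
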