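# Methods

This note describes the models and procedures `nmdkit` implements, the
parameters that matter, the choices made where the design was open, and
what the synthetic-data generators do and do not emulate.

## Coordinates and transcript models

All internal coordinates are 0-based half-open. GTF I/O converts to and
from the 1-based inclusive convention at the boundary; BED12 is handled
natively. A transcript is an ordered chain of non-overlapping exons on
one strand of one sequence; transcript coordinates always read 5'→3', so
on the minus strand transcript position 0 is the 3'-most genomic exonic
base. `to_transcript_coord` / `to_genomic_coord` are exact inverses over
exonic positions; intronic positions raise rather than clamp. N bases are
permitted and propagate into spliced sequences; a codon containing N is
never treated as a start or stop codon (conservative ORF calling).

## Maximal transcript assembly

Spliced alignments of one locus are merged into *maximal transcripts*:
repeatedly, any two compatible assemblies are replaced by the union of
their exonic base coverage (introns re-derived as the remaining gaps),
until the set is pairwise incompatible. Assemblies are scanned in a
canonical order (ascending span, then exon chain) and the scan restarts
after every merge, so the fixed point is independent of input order; each
input id ends up in exactly one assembly's `supporting_ids`.

Two alignments are **compatible** when they share a strand and at least
one exonic base, and the introns of either that intersect the genomic
overlap window are identical between the two. This is a deliberate
simplification of full EST-assembly behaviour (no splice-site validation
or annotation comparison). An intronless alignment nested within a
partner's exonic structure is trivially compatible — its empty chain is
contained — but one whose exon reaches into a partner's intron is not:
treating such fragments as compatible with everything they touch lets a
single intron-spanning fragment bridge a spliced isoform and its
intron-retaining sibling and collapse a locus that should yield distinct
isoforms. Assemblies supported only by intronless alignments are flagged
(`single_exon_only`) so users can exclude them.

## ORFs, the largest ORF, and uORFs

ORFs begin at ATG and run to the first in-frame stop codon; only the
forward three frames of the transcript sequence are scanned, and
open-ended reading frames are ignored. Nested in-frame ATGs each count as
a distinct ORF sharing the stop — whether nested starts are one uORF or
several is genuinely ambiguous, and counting each start is the documented
default. The **main ORF** is the one with the most codons, ties broken
5'-most; the region upstream of its start is taken to be the 5'UTR.
Every ORF starting in the 5'UTR is a uORF; `overlaps_main` marks those
whose stop codon ends past the main start. The minimum uORF length is one
codon plus stop (`min_uorf_codons=1`): biologically relevant uORFs can be
as short as three codons, so no length floor is imposed by default.

## NMD feature classification

The positional (exon-junction-complex) model of PTC recognition is
applied operationally: junction offsets are transcript positions of the
first base of each downstream exon; the distance from the stop is
`offset − stop_end`; only strictly positive distances (junctions in the
3'UTR) count as 3'UTR introns, and the transcript is flagged when any
distance **exceeds `threshold_nt` (default 50, strict)**. The threshold
is configurable (`--ptc-threshold`) because the field quotes 50–55 nt.
A gene is AS-NMD when any of its transcripts is flagged. Non-coding
transcripts are reported but never flag a gene — the rule operates on the
termination codon of the largest ORF, which they lack. uORF stop codons
are *not* tested against downstream junctions; uORFs are reported as
features only. Intron retention is represented simply as a transcript
lacking the junction; there is no separate retained-intron call.

Peptide matching is exact, case-insensitive substring search; an optional
`il_equivalent` flag collapses I and L (mass spectrometry cannot
distinguish them) and is off by default. A candidate isoform must match
*all* observed peptides; per-isoform match counts are reported either
way, and a gene whose flagged isoforms all fail the filter gets an
explanatory status instead of candidates.

## Expression statistics

* **Presence filter** — spots observed in < 75% of samples (default) are
  excluded before testing.
* **Spot tests** — classical equal-variance two-sample Student t-tests on
  log abundances (Welch available behind a flag); the fold change is the
  linear ratio `log_base ** Δmean`. Spots with under two observations per
  group get a missing p; zero variance in both groups gives p = 1 at
  equal means and p = 0 otherwise. **No multiple-testing correction is
  applied anywhere**: the workflow deliberately uses raw thresholds
  (p < 0.01 two-tailed for spots, p < 0.05 one-tailed for QPCR), so
  spot-level significant fractions should be read as raw rates.
* **PCA** — samples are observations, spots variables; residual missing
  values after the presence filter are imputed with the spot-wise mean
  (logged in output metadata), the matrix is mean-centred and decomposed
  by SVD. Scores are reproducible up to per-component sign; cumulative
  explained variance is reported as R²(k). Cross-validated predictive Q²
  is not computed — it depends on a proprietary cross-validation scheme
  with no single standard definition.
* **QPCR folds** — per replicate, the gene-of-interest quantity is
  normalized to a reference gene (GAPDH/HPRT role); fold change is the
  treatment ratio divided by the *mean* control ratio. Quantities must be
  positive at parse time. Because both treatments share the control
  denominator, their fold estimates are positively correlated; a low
  control excursion can inflate both rounds at once (visible as rare
  correlated false positives in simulations).
* **Two-round validation** — per round, a one-sample one-tailed Student
  t-test of log fold changes against 0 at α = 0.05. Log scale is used
  because fold-change noise is multiplicative and the test is then
  symmetric in up/down. Significantly positive → `increased`, negative →
  `decreased`, otherwise `no_change`; fewer than two usable replicates →
  `no_signal`. Round 2 (translation inhibition) is evaluated only for
  genes that increased in round 1, mirroring a staged study design; a
  flag evaluates all genes. `bona_fide_nmd` requires `increased` in both.
* **Summaries** — integer percentages are half-up rounded with exact
  decimal arithmetic. The sum-equals-denominator invariant is enforced by
  default; `strict=False` permits reporting against an externally fixed
  denominator, since published tables are occasionally internally
  inconsistent in exactly this way. Note 17/47 is 36% under this
  rounding; no rounding scheme yields 34% for that ratio.
* **Gel bands** — `percent_isoform` is the upper (NMD-sensitive) band's
  share of total signal, `100·upper/(upper+lower)`.

## Synthetic data: what it emulates, and what it does not

`synth_gene_set` builds gene loci whose feature inventory is exact by
construction rather than by chance: all planted stops are TAA; every ATG
not deliberately planted has its T replaced by C (an edit that cannot
create a new ATG or stop, as both are C-free); introns are padded with CC
so no start/stop codon can span a splice boundary in any isoform. Each
gene draws a 60–120-codon CDS and a 60–150-nt 5'UTR; `utr3_intron` genes
plant a 3'UTR intron with stop-to-junction distance drawn from 10–200 nt
(the first two such genes get the boundary values 50 and 51 so both sides
of the threshold are always represented); `uorf` genes plant one or two
uORFs of 1–30 codons, the last sometimes overlapping the main ORF via an
out-of-frame start near the UTR end with its first in-frame stop planted
a few codons into the CDS. About half the genes carry a CDS intron
(junctions upstream of the stop, which must not count), and about 30% lie
on the minus strand to exercise the coordinate machinery. Intron and
spacer lengths are drawn from stated uniform ranges (80–150 and
50–200 nt).

The default feature mix (40% 3'UTR-intron, 40% uORF, 20% featureless)
reflects that uORFs and 3'-end introns are the dominant feature classes
among validated NMD targets. The spot generator uses N = 6 per condition
with two knockdown conditions against one control, matching a
two-siRNA proteomics design; the QPCR generator defaults to 8 replicates
and 10% CV, matching the replication used to equalize power with such a
design. Noise is Gaussian on log abundances (spots) and log-normal
multiplicative (QPCR); peptides are uniform substrings of the encoded
protein, not true tryptic digests — the consistency filter's semantics do
not depend on digestion chemistry.

What the generators do **not** emulate: splice-site sequence, codon
usage, realistic UTR base composition, 2D-gel pI/MW structure,
spot-to-protein multiplicity, correlated missingness, or amplification
curves (normalized quantities are taken as inputs). Passing tests on
these cohorts therefore demonstrate correctness of the decision rules and
calibration of the statistics under their stated noise models, not
performance on real transcriptomes.

## Numerical and degenerate-input choices

Tolerances: PCA agreement with a direct SVD is required to 1e-8 up to
sign; t-test p-values match an independently coded t-distribution oracle
to 1e-9. Problem sizes used by the test and acceptance runs — 10,000 null
spots, a 500-gene cohort, 1,000 randomized alignment sets, 100 simulated
QPCR genes — were chosen so each recomputation completes in seconds while
keeping Monte-Carlo error well inside the asserted bounds. All generators
take a single RNG stream per call with an explicit seed; there is no
implicit global state. Degenerate inputs fail loudly: empty transcript
models, intervals with start ≥ end, non-positive QPCR quantities,
zero-sum band intensities, and empty peptide lists are all rejected at
construction or parse time.

## Known limitations

The compatibility rule is intentionally simpler than full EST-assembly
(no splice-site dinucleotide checks, no annotation updating); the 50-nt
rule is positional only, ignoring 3'UTR-length/poly(A)-proximity effects
on termination; uORF-induced PTCs are not modelled; Kozak context,
reinitiation and non-AUG starts are out of scope. The subsumption is
O(n³) in alignments per locus — fine for per-gene alignment clusters, not
for genome-scale input in one call.
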