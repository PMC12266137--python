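# Methods

## The locus model

The fixture emulates the intron-15 region of *GBE1* (minus-strand gene) as
a segment of a few kilobases in genuine GRCh38-style coordinates. Only the
printed constraints of the disease allele are treated as fixed:

* the delins — plus-strand `CCACCACAC` at chr3:81493813-81493821 replaced
  by `ACCTGTAATGTAAAAAACA` (net +10 nt);
* the ectopic acceptor `AG` immediately 5′ (transcript sense) of the
  pseudoexon start, inside the inserted run, so the pseudoexon begins with
  the insertion's terminal `GT`;
* pseudoexon lengths 241 nt (MT1) and 206 nt (MT2), sharing the acceptor
  and differing only at the donor-side boundary;
* an in-frame `TAA` (mRNA `UAA`) at pseudoexon positions 13–15, i.e. 12 nt
  of pseudoexon sequence 5′ of the stop;
* canonical exon 16 as the final exon of all isoforms, the pseudoexon
  penultimate in both mutant isoforms.

Everything else — exon and intron lengths, interior sequence — is synthetic,
drawn once from a packaged generator seed and screened so the reading frame
works out: exon coding lengths are multiples of three, exons 11–15 are
stop-free codons, the pseudoexon's first four codons are stop-free, and the
canonical stop lies early in exon 16. Exons 15/16 and the introns flanking
the insertion are ≥300 nt so that sites on both sides of the 200-nt
off-target distance boundary exist within the locus. The cryptic donor
positions are synthetic stand-ins: only the two pseudoexon lengths are
constrained, not their genomic coordinates.

Mutant transcripts are annotated on the variant haplotype's coordinate
frame and the canonical transcript on the reference frame; a liftover
(+10 nt for positions genomically 5′ of the insertion) places all junction
chains in a shared frame so that reads from different haplotypes are
directly comparable. Putting the gene on the minus strand was a deliberate
choice: reverse-complement and coordinate-orientation errors are the
dominant bug class in this domain, and the fixture exercises them in every
stage.

## Simulators

*Pileups.* Per-haplotype, per-position base counts over the delins
interval ±2 nt; at depth *d* and error rate *e* the true base receives
`d − Binomial(d, e)` reads and errors are spread uniformly over the three
alternatives. Error rates ≥0.5 are refused (majority voting is then
meaningless). The variant haplotype is simulated in its own coordinate
ladder, so insertion bases are ordinary columns; pileup insertion
observations are supported by the consensus caller but not emitted by this
simulator.

*Junction counts.* A binomial split of *n* junction-spanning reads between
inclusion (exon15→pseudoexon) and exclusion (exon15→exon16) at the true
PSI; inclusion reads are further split 50/50 over the two cryptic donors,
matching the observed lack of donor preference. Decoy junctions with
counts 1, 2 and 3 are always emitted so the ≥3-read display filter has
rows on both sides of its threshold. The simulator models mature junction
reads only; real total-RNA data additionally contains pre-mRNA reads,
which this generator does not emulate.

*Long reads.* Error-free at the base level: each read carries the exact
junction chain and spliced sequence of its multinomially drawn source
isoform. The isoform-level conclusion rests on junction chains, not base
accuracy, so robustness is tested through the 5′-truncation knob instead:
with probability `truncate_frac` a read loses a uniform-random number of
leading junctions, and a read that loses all of them becomes ambiguous.

*Dose plates.* The normalized variable-slope logistic
`y = 100/(1 + (EC50/x)^h)` with Gaussian noise, emitted on the raw
percent-of-mock scale (stimulation curves ride on a baseline of 100), so
the fitting stage must perform the baseline subtraction itself. Default
four replicates per dose, in the range reported for such screens.

Default parameters are the study conditions: depth 30 with 1% base error;
patient PSI values 2.8 / 1.8 / 0.87 / 1.3% at 5,000 junction reads;
isoform mixture 86.6 / 6.2 / 7.2% at 20,000 reads; five-point four-fold
dilution from 20 μM. All randomness flows from one explicit seed; the same
seed reproduces byte-identical outputs.

## Consensus calling

Per column the majority base is emitted when its count reaches
`min_support` (default 2 — single-read positions are excluded and
recorded). Ties emit the IUPAC ambiguity code of the tied set with a
warning, or raise under `tie_policy="fail"`. A column whose majority is a
deletion emits nothing. Insertion observations attach to the preceding
position and are emitted when the most common inserted string reaches
`min_support` and exceeds half the column depth; this convention is a
package decision, since pileup-based indel handling has no single standard.

## PSI and isoform assignment

PSI defaults to the acceptor side (the ectopic acceptor is shared by both
mutant isoforms, so a single junction captures all inclusion); donor-side
and mean conventions are options. The Wilson interval (statsmodels) is
attached; a zero denominator yields an explicitly undefined estimate.

Assignment requires the read's chain to be a contiguous sub-chain of
exactly one model and to cover at least `min_diagnostic_junctions`
junctions not shared by all models. This exact classifier is analyzable —
with full-length error-free reads it recovers multinomial proportions
exactly in expectation — at the price of ignoring base errors and novel
isoforms, which a production long-read quantifier would model.

The NMD rule is the canonical 50-nt heuristic: predicted when the first
in-frame stop (scanned from the annotated start codon) ends more than
`nmd_threshold_nt` (default 50) nucleotides upstream of the last exon–exon
junction, and never when the stop lies in the last exon.

## ASO design filters

18-mers tiled at 1-nt steps across the variant pre-mRNA, default window
insertion ±60 nt (the window extent is a package constant; no published
value exists, so candidate counts are not comparable to any historical
screen). GC bounds are inclusive at 25% and 75%; "outside the range" is
rejected. Homopolymer runs of six or more fail; exactly five passes. GC is
counted on the DNA target sequence — identical for the RNA alphabet.
Allele specificity is a Hamming count against windows anchored at the same
coordinates on each haplotype; a candidate overlapping the inserted run
has no anchored reference window and is reported as absent rather than
given a fabricated distance. A config switch re-targets the tiling to the
allele as first reported (one substitution off the corrected sequence),
reproducing the two historical design rounds.

## Off-target search

Sense-strand search of the ASO's binding site over pre-mRNA and mature
mRNA sequences. Completeness argument: three disjoint 6-nt seeds partition
an 18-mer, so any alignment with ≤2 mismatches contains one exact seed
(pigeonhole); seed hits propose diagonals that are verified exhaustively.
Any 18-mer alignment with ≥16 contiguous matches has ≤2 mismatches, so the
same arm catches the contiguous-match criterion. The "mismatch/gap" budget
is interpreted as: a single 1-nt bulge on either strand counts like one
mismatch; such gapped, zero-mismatch alignments are found by exact search
of every single-deletion/insertion variant of the query (the only gapped
case the ≤1 budget can accept). Distance to exon is measured from the
alignment edge to the nearest exon boundary of the gene's canonical
transcript when the alignment lies within its span, else the nearest exon
of any transcript; the 200-nt boundary is inclusive. Genome-scale
annotation is out of desk scope — the packaged screens run on synthetic
transcriptomes, and the index accepts user-supplied gene records for real
runs.

## Pharmacology

ΔΔCt uses technical-replicate means at the Ct level before calibration
(averaging conventions differ between labs; this one is fixed and
documented). Hit thresholds are strict inequalities (>125% single-dose,
>140% at the top dose of a dose-response run).

The 4PL fit subtracts the 100% mock baseline for stimulation data —
negative adjusted responses are retained as ordinary residuals — and fits
`y = top/(1 + (EC50/x)^h)` with the bottom pinned at the baseline, so the
EC50 parameter is the dose at 50% of the normalized span (absolute and
relative EC50 coincide under this model). Inhibition fits the decreasing
four-parameter form on the raw scale. Optimization is bounded least
squares on log10(EC50) with a deterministic multi-start grid (five
log-spaced EC50 initials spanning the dose range × Hill starts 0.5/1/2);
doses are internally rescaled by their maximum, which makes the fit
exactly equivariant under power-of-two dose rescalings (bit-identical
floating-point path) and equivariant to rounding error otherwise.
Non-convergence is reported as a flagged result, never a silent number.
EC50s outside the fitted dose span are flagged extrapolated.

## Problem sizes and numerical checks

The packaged tests and the acceptance script use the study-scale sizes
directly (depth 30; 5,000 junction reads per patient; 20,000 long reads;
200 Monte-Carlo plates) — all complete in seconds. Noiseless 4PL recovery
is verified to 1e-6 relative tolerance; the Monte-Carlo recovery study at
noise SD 5 (Hill 1) and SD 10 (Hill 1.5) keeps the median EC50 error
within 20%. Search and consensus algorithms are checked for set-identity
against exhaustive brute-force oracles on randomized inputs.

## Known limitations

* The synthetic locus preserves printed constraints, not real *GBE1*
  sequence; conclusions about filter pass rates or off-target counts do
  not transfer to the real transcriptome.
* Junction simulation ignores pre-mRNA contamination and alignment
  artifacts; pileup simulation ignores strand bias and indel-adjacent
  error enrichment.
* The off-target model scores hybridization similarity only — no
  thermodynamics, no RNase-H cleavage modeling, no expression weighting.
* NMD prediction is the 50-nt rule, a heuristic with known exceptions.
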