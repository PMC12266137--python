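# spliceaso

Analysis toolkit for a splice-modulating antisense-oligonucleotide (ASO)
program targeting a deep-intronic *GBE1* delins that causes adult
polyglucosan body disease (APBD).

A 9-nt run in intron 15 of *GBE1* (chr3:81493813-81493821, `CCACCACAC` on
the genomic plus strand) is replaced on the pathogenic haplotype by a 19-nt
insertion (`ACCTGTAATGTAAAAAACA`; transcript sense `TGTTTTTTACATTACAGGT`).
The inserted run creates an ectopic splice acceptor (`...ACATTAC AG | GT...`)
whose use splices a pseudoexon between canonical exons 15 and 16. Two
cryptic donors produce two mutant isoforms — pseudoexon lengths 241 nt (MT1)
and 206 nt (MT2) — and an in-frame UAA premature termination codon 12 nt
into the pseudoexon makes both isoforms substrates of nonsense-mediated
decay (NMD), depleting functional glycogen branching enzyme. Steric-block
ASOs tiled over the insertion can mask the ectopic acceptor and restore
canonical splicing.

`spliceaso` implements the computational arc of such a program, end to end
and at desk scale, with a synthetic locus supplying ground truth for every
stage:

| stage | module | core quantities |
|---|---|---|
| locus + data simulation | `spliceaso.locus`, `spliceaso.simulate` | two-haplotype fixture, pileups, junction counts, long-read chains, dose plates |
| delins reconstruction | `spliceaso.variants` | per-haplotype majority consensus, positions with <2 supporting reads excluded |
| splice quantification | `spliceaso.splicing` | pseudoexon PSI = incl/(incl+excl) with Wilson CI; junction-chain isoform assignment; ORF scan + 50-nt NMD rule |
| ASO design | `spliceaso.design` | 18-mer 1-nt tiling; GC 25–75% (inclusive); no homopolymer ≥6; allele-specificity Hamming counts |
| off-target screen | `spliceaso.offtarget` | complete seed-index search; off-target ⇔ (mm+gaps ≤ 1 or ≥16 contiguous) ∧ sense ∧ distance-to-exon ≤ 200 nt |
| pharmacology | `spliceaso.pharmacology` | 2^−ΔΔCt fold changes, strict >125%/>140% hit calls, absolute EC50/IC50 by 4PL `y = top/(1+(EC50/x)^h)` after baseline-100 subtraction |

Isoform assignment is deliberately an exact junction-chain classifier (a
read must be a contiguous sub-chain of exactly one model and cover a
discriminating junction), not a probabilistic EM quantifier; ambiguous
reads are never fractionally allocated.

## Worked example

```python
import spliceaso as sa

loc = sa.build_fixture_locus()

# 1. reconstruct the insertion allele from a noisy phased pileup
pile = sa.simulate_phased_pileup(loc, depth=30, error_rate=0.01, seed=7)
cons = sa.call_consensus(pile[1])
print(cons.segment(loc.delins.start, loc.delins.start + 18))

# 2. pseudoexon PSI from junction counts at a patient-level 2.8%
t = sa.simulate_junction_counts(loc, 0.028, 5000, seed=11)
est = sa.compute_psi(sa.filter_junctions(t), loc)
print(f"PSI = {est.percent:.2f}%  (95% CI {100*est.ci_low:.2f}-{100*est.ci_high:.2f}%)")

# 3. PTC/NMD annotation of mutant isoform 1
ann = sa.annotate_orf("MT1", loc)
print(ann.stop_codon, ann.stop_offset_in_pseudoexon, ann.nmd_predicted)

# 4. absolute EC50 from a noisy screen plate (5-point 4-fold from 20 uM)
doses = sa.serial_dilution(20, 4, 5)
tab = sa.simulate_dose_response(2.0, 1.5, doses, noise_sd=5.0, seed=3)
print(sa.fit_dose_response(tab, mode="stimulation").summary())
```

prints

```text
ACCTGTAATGTAAAAAACA
PSI = 2.68%  (95% CI 2.27-3.17%)
UAA 12 True
Dose-response fit: ASO (stimulation)
  EC50:          2.461
  Hill slope:    1.278
  Span:          0 .. 105.4
  R^2:           0.9784  (n = 20)
  Converged:     True
```

The consensus is exactly the 19-nt inserted allele; the PSI estimate sits
on the simulated truth with a binomial Wilson interval; the ORF scan finds
the UAA stop 12 nt into the pseudoexon and, because the stop lies 226 nt
upstream of the last exon–exon junction, flags MT1 for NMD; the 4PL fit
recovers the plate's EC50 of 2 μM to within the noise.

A full pipeline run (simulate → consensus → quantify → design → off-target
→ pharmacology, with a manifest of checksums) is available from the shell:

```sh
spliceaso demo --seed 1 --out-dir demo_run
```

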