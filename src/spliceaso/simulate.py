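"""Simulators for every input data type the pipeline consumes.

Each simulator draws from the ground-truth :class:`~spliceaso.locus.LocusModel`
so downstream estimators can be checked against known parameters:

* phased pileups with uniform base-call error (consensus calling),
* binomial junction-read splits at a true PSI (PSI estimation),
* multinomial long-read isoform mixtures as junction chains (assignment),
* four-parameter-logistic dose-response plates with Gaussian noise (fitting).

All randomness flows from an explicit seed; identical seed and parameters
give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus import LocusModel
from .variants import PhasedPileup, PileupColumn

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Bundle of simulation knobs used by the CLI; seed fully determines output."""

    seed: int = 0
    depth: int = 30
    error_rate: float = 0.01
    psi_true: float = 0.017
    total_junction_reads: int = 5000
    n_reads: int = 20000
    isoform_proportions: dict[str, float] | None = None
    noise_sd: float = 5.0

    def __post_init__(self):
        if self.isoform_proportions is not None:
            total = sum(self.isoform_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"isoform proportions must sum to 1, got {total}")


def simulate_phased_pileup(
    locus: LocusModel,
    depth: int,
    error_rate: float,
    seed: int,
    flank: int = 2,
) -> list[PhasedPileup]:
    """Simulate per-haplotype pileups over the delins interval (+/- flank).

    Haplotype 1 carries the reference run, haplotype 2 the inserted allele
    (columns in the variant haplotype's own coordinate frame, so the 19
    inserted bases are ordinary columns). At each column the true base
    receives ``depth - errors`` reads and errors are spread uniformly over
    the three alternative bases.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5): a majority vote is "
                         "meaningless once errors dominate")
    rng = np.random.default_rng(seed)
    d = locus.delins
    regions = [
        (1, "ref", d.start - flank, d.end + flank),
        (2, "alt", d.start - flank, d.start + len(d.alt_seq) - 1 + flank),
    ]
    pileups = []
    for hap_id, hap, lo, hi in regions:
        truth = locus.genomic_slice(lo, hi, hap)
        columns = []
        for pos, base in zip(range(lo, hi + 1), truth):
            n_err = rng.binomial(depth, error_rate)
            counts = dict.fromkeys(_BASES, 0)
            counts[base] = depth - n_err
            if n_err:
                alts = [b for b in _BASES if b != base]
                for b, k in zip(alts, rng.multinomial(n_err, [1 / 3] * 3)):
                    counts[b] += int(k)
            columns.append(PileupColumn(position=pos, counts=counts))
        pileups.append(PhasedPileup(haplotype_id=hap_id, columns=columns))
    return pileups


# decoy junctions always emitted so the display filter (min 3 reads) has
# rows on both sides of its threshold
_DECOY_COUNTS = (1, 2, 3)


def simulate_junction_counts(
    locus: LocusModel,
    psi_true: float,
    total_junction_reads: int,
    seed: int,
) -> pd.DataFrame:
    """Binomial split of junction-spanning reads at a true inclusion level.

    Inclusion reads span exon15 -> pseudoexon (the shared ectopic acceptor);
    exclusion reads span exon15 -> exon16. Inclusion reads are additionally
    split 50/50 over the two cryptic donors so donor-side junctions
    (pseudoexon -> exon16) are observable. Decoy junctions with counts 1, 2
    and 3 are always appended. Coordinates are in the variant haplotype's
    frame. E[inclusion / (inclusion + exclusion)] = ``psi_true``.
    """
    if total_junction_reads <= 0:
        raise ValueError("total_junction_reads must be positive")
    if not 0 <= psi_true <= 1:
        raise ValueError("psi_true must be in [0, 1]")
    rng = np.random.default_rng(seed)
    incl = int(rng.binomial(total_junction_reads, psi_true))
    excl = total_junction_reads - incl
    mt1_donor_reads = int(rng.binomial(incl, 0.5)) if incl else 0

    inc_d, inc_a = locus.inclusion_junction()
    exc_d, exc_a = locus.exclusion_junction()
    (d1_d, d1_a), (d2_d, d2_a) = locus.donor_inclusion_junctions()
    rows = [
        (inc_d, inc_a, incl, "inclusion_acceptor"),
        (exc_d, exc_a, excl, "exclusion"),
        (d1_d, d1_a, mt1_donor_reads, "inclusion_donor_MT1"),
        (d2_d, d2_a, incl - mt1_donor_reads, "inclusion_donor_MT2"),
    ]
    # place decoys in intron 14 territory, far from the real junctions
    base = locus.coordinate_offset + 50
    for i, c in enumerate(_DECOY_COUNTS):
        rows.append((base + 10 * i, base + 10 * i + 5, c, f"decoy_{c}"))
    return pd.DataFrame(rows, columns=["donor", "acceptor", "count", "label"])


@dataclass
class ReadChain:
    """One long read reduced to its ordered splice-junction chain."""

    read_id: str
    junctions: tuple[tuple[int, int], ...]
    sequence: str
    isoform_truth: str | None = None
    assigned_isoform: str | None = None


def simulate_long_reads(
    locus: LocusModel,
    proportions: dict[str, float],
    n_reads: int,
    seed: int,
    truncate_frac: float = 0.0,
) -> list[ReadChain]:
    """Multinomial isoform mixture of error-free junction-chain reads.

    Each read carries the full junction chain and spliced sequence of its
    source isoform (chains in the shared variant-haplotype frame). With
    probability ``truncate_frac`` a read is 5'-truncated: a uniform-random
    number of leading junctions (1 up to all) is dropped, mimicking the
    5' degradation common in long-read cDNA; a read that loses every
    junction becomes unassignable.
    """
    unknown = set(proportions) - set(locus.transcripts)
    if unknown:
        raise ValueError(f"unknown isoform id(s): {sorted(unknown)}")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total}")
    if not 0 <= truncate_frac <= 1:
        raise ValueError("truncate_frac must be in [0, 1]")

    rng = np.random.default_rng(seed)
    ids = sorted(proportions)
    counts = rng.multinomial(n_reads, [proportions[t] for t in ids])

    chains = {t: locus.junction_chain(t, shared_frame=True) for t in ids}
    seqs = {t: locus.spliced_sequence(t) for t in ids}
    exon_lens = {t: [e - s + 1 for s, e in locus.transcripts[t].exons] for t in ids}

    reads: list[ReadChain] = []
    order = rng.permutation(n_reads)
    sources = np.repeat(np.arange(len(ids)), counts)[order]
    for i, src in enumerate(sources):
        tid = ids[src]
        chain = chains[tid]
        seq = seqs[tid]
        if truncate_frac and rng.random() < truncate_frac and chain:
            k = int(rng.integers(1, len(chain) + 1))  # junctions dropped from the 5' end
            chain = chain[k:]
            seq = seq[sum(exon_lens[tid][:k]):]
        reads.append(ReadChain(
            read_id=f"read_{i:06d}", junctions=chain, sequence=seq, isoform_truth=tid,
        ))
    return reads


def reads_to_frame(reads: list[ReadChain]) -> pd.DataFrame:
    """Tabular form of a read list (one row per read, chain serialized)."""
    return pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "junctions": [";".join(f"{d}-{a}" for d, a in r.junctions) for r in reads],
        "isoform_truth": [r.isoform_truth for r in reads],
    })


def logistic_response(dose, ec50: float, hill: float) -> np.ndarray:
    """Normalized variable-slope stimulation curve, 0-100 span:
    y = 100 / (1 + (EC50 / x) ** h)."""
    dose = np.asarray(dose, dtype=float)
    return 100.0 / (1.0 + (ec50 / dose) ** hill)


def simulate_dose_response(
    ec50: float,
    hill: float,
    doses,
    noise_sd: float,
    seed: int,
    mode: str = "stimulation",
    n_replicates: int = 4,
    max_effect: float = 100.0,
) -> pd.DataFrame:
    """Dose-response plate on the raw percent-of-mock scale.

    Stimulation curves are emitted as ``100 + span * f(x)`` (mock baseline
    100%), so the fitting stage must itself subtract the baseline; inhibition
    curves decrease from 100 toward ``100 - span``. Gaussian noise with SD
    ``noise_sd`` is added per replicate.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if mode not in ("stimulation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    f = logistic_response(doses, ec50, hill) / 100.0  # 0..1
    mean = 100.0 + max_effect * f if mode == "stimulation" else 100.0 - max_effect * f
    rows = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=doses.size) if noise_sd > 0 else 0.0
        resp = mean + noise
        for d, y in zip(doses, np.atleast_1d(resp)):
            rows.append((float(d), float(y), rep))
    return pd.DataFrame(rows, columns=["dose", "response", "replicate"])
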