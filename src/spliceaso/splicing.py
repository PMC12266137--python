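"""Pseudoexon quantification, isoform assignment and ORF/NMD annotation.

PSI (percent spliced in) is inclusion-junction reads over inclusion plus
exclusion reads. Long reads are assigned to isoform models by exact
junction-chain containment — a deliberate simplification of probabilistic
isoform quantifiers: a read is assigned only when its observed chain is a
contiguous sub-chain of exactly one model and covers at least one junction
that discriminates between models; everything else is ambiguous, and
ambiguous reads are never fractionally allocated.

The NMD annotation applies the classical 50-nt rule: a stop codon more than
``nmd_threshold_nt`` upstream of the last exon-exon junction marks the
transcript for nonsense-mediated decay; a stop in the last exon never does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .locus import LocusModel


def filter_junctions(table: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Drop junctions below the display threshold (default: keep >= 3 reads),
    preserving row order."""
    return table[table["count"] >= min_count].copy()


@dataclass
class PsiEstimate:
    inclusion_count: int
    exclusion_count: int
    psi: float | None  # None when the denominator is zero
    ci_low: float | None
    ci_high: float | None
    side: str = "acceptor"

    @property
    def defined(self) -> bool:
        return self.psi is not None

    @property
    def percent(self) -> float | None:
        return None if self.psi is None else 100.0 * self.psi


def _junction_count(table: pd.DataFrame, junction: tuple[int, int]) -> int:
    d, a = junction
    rows = table[(table["donor"] == d) & (table["acceptor"] == a)]
    return int(rows["count"].sum())


def compute_psi(
    table: pd.DataFrame,
    locus: LocusModel,
    side: str = "acceptor",
    alpha: float = 0.05,
) -> PsiEstimate:
    """PSI of the pseudoexon from a junction table.

    ``side='acceptor'`` counts the shared exon15 -> pseudoexon junction as
    inclusion; ``side='donor'`` pools the two cryptic-donor junctions
    (pseudoexon -> exon16); ``side='mean'`` averages the two estimates'
    counts. Exclusion is always the canonical exon15 -> exon16 junction.
    A Wilson binomial confidence interval is attached. A zero denominator
    yields an explicitly undefined estimate rather than NaN propagation.
    """
    if side not in ("acceptor", "donor", "mean"):
        raise ValueError(f"unknown side {side!r}")
    acc = _junction_count(table, locus.inclusion_junction())
    don = sum(_junction_count(table, j) for j in locus.donor_inclusion_junctions())
    if side == "acceptor":
        incl = acc
    elif side == "donor":
        incl = don
    else:
        incl = round((acc + don) / 2)
    excl = _junction_count(table, locus.exclusion_junction())
    n = incl + excl
    if n == 0:
        return PsiEstimate(incl, excl, None, None, None, side)
    lo, hi = proportion_confint(incl, n, alpha=alpha, method="wilson")
    return PsiEstimate(incl, excl, incl / n, float(lo), float(hi), side)


@dataclass
class IsoformQuant:
    counts: dict[str, int]
    ambiguous: int
    proportions: dict[str, float] = field(default_factory=dict)

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())


def _is_contiguous_subchain(read_chain, model_chain) -> bool:
    if not read_chain:
        return False
    n, m = len(read_chain), len(model_chain)
    return any(model_chain[i:i + n] == read_chain for i in range(m - n + 1))


def assign_reads(
    reads,
    locus: LocusModel,
    min_diagnostic_junctions: int = 1,
) -> IsoformQuant:
    """Assign junction-chain reads to isoform models.

    A junction is *diagnostic* when it is absent from at least one model. A
    read is assigned to the single model whose chain contains the read's
    chain contiguously, provided the read covers at least
    ``min_diagnostic_junctions`` diagnostic junctions; otherwise it is
    counted as ambiguous. Proportions are computed over assigned reads only.
    """
    models = {tid: locus.junction_chain(tid, shared_frame=True) for tid in locus.transcripts}
    seen: dict[tuple, str] = {}
    for tid, chain in models.items():
        if chain in seen:
            raise ValueError(f"models {seen[chain]!r} and {tid!r} have identical junction chains")
        seen[chain] = tid
    shared_by_all = set.intersection(*(set(c) for c in models.values())) if models else set()

    counts = dict.fromkeys(models, 0)
    ambiguous = 0
    for read in reads:
        chain = tuple(read.junctions)
        matches = [tid for tid, mc in models.items() if _is_contiguous_subchain(chain, mc)]
        n_diag = sum(1 for j in chain if j not in shared_by_all)
        if len(matches) == 1 and n_diag >= min_diagnostic_junctions:
            read.assigned_isoform = matches[0]
            counts[matches[0]] += 1
        else:
            read.assigned_isoform = None
            ambiguous += 1
    total = sum(counts.values())
    proportions = {t: (c / total if total else 0.0) for t, c in counts.items()}
    return IsoformQuant(counts=counts, ambiguous=ambiguous, proportions=proportions)


def internal_exon_lengths(chain, strand: str = "-") -> list[int]:
    """Exon lengths between consecutive junctions of an observed chain.

    The exon between junction *i* and junction *i+1* runs from the acceptor
    of *i* to the donor of *i+1*; its length follows directly from the
    coordinates, so a read's internal exon structure (e.g. a pseudoexon
    length) is reconstructable without any transcript model.
    """
    lengths = []
    for (_, a1), (d2, _) in zip(chain, chain[1:]):
        lengths.append(a1 - d2 + 1 if strand == "-" else d2 - a1 + 1)
    return lengths


@dataclass
class OrfAnnotation:
    transcript_id: str
    stop_codon: str | None  # RNA letters, e.g. "UAA"
    stop_offset_in_pseudoexon: int | None  # pseudoexon nt 5' of the stop
    distance_stop_to_last_junction: int | None
    nmd_predicted: bool
    stop_in_last_exon: bool


def annotate_orf(
    transcript_id: str,
    locus: LocusModel,
    nmd_threshold_nt: int = 50,
) -> OrfAnnotation:
    """Scan the spliced mRNA in frame from the canonical start codon and
    apply the NMD rule to the first stop found."""
    mrna = locus.spliced_sequence(transcript_id)
    start = locus.start_codon_spliced_offset
    if mrna[start:start + 3] != "ATG":
        raise ValueError(f"{transcript_id}: no ATG at the annotated start codon offset")

    stop_at = None
    for i in range(start, len(mrna) - 2, 3):
        codon = mrna[i:i + 3]
        if codon in ("TAA", "TAG", "TGA"):
            stop_at = i
            stop_codon = codon.replace("T", "U")
            break
    if stop_at is None:
        return OrfAnnotation(transcript_id, None, None, None, False, False)

    t = locus.transcripts[transcript_id]
    exon_lengths = [e - s + 1 for s, e in t.exons]
    last_junction_pos = sum(exon_lengths[:-1])  # spliced offset of the last junction
    stop_end = stop_at + 3
    stop_in_last_exon = stop_end > last_junction_pos
    distance = None if stop_in_last_exon else last_junction_pos - stop_end

    pe_offset = None
    if transcript_id in locus.pseudoexon:
        pe_start = sum(exon_lengths[:-2])  # pseudoexon is penultimate
        pe_end = pe_start + exon_lengths[-2]
        if pe_start <= stop_at < pe_end:
            pe_offset = stop_at - pe_start

    nmd = (not stop_in_last_exon) and distance is not None and distance > nmd_threshold_nt
    return OrfAnnotation(
        transcript_id=transcript_id,
        stop_codon=stop_codon,
        stop_offset_in_pseudoexon=pe_offset,
        distance_stop_to_last_junction=distance,
        nmd_predicted=nmd,
        stop_in_last_exon=stop_in_last_exon,
    )
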