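"""Delins variants and per-haplotype consensus calling from phased pileups.

A "delins" replaces a run of reference bases with a different inserted run
(here a 9 nt reference run replaced by 19 inserted nt deep in an intron).
Consensus reconstruction mirrors how such an allele is resolved from phased
long-read pileups: per-position base counting, majority vote, and exclusion
of positions supported by a single read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    # IUPAC ambiguity codes
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

# base set -> IUPAC ambiguity code (used for consensus ties)
IUPAC_FROM_BASES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("ACG"): "V", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACGT"): "N",
}


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the DNA/IUPAC alphabet."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC ambiguity codes allowed).

    Raises :class:`SequenceAlphabetError` naming the offending position for
    any character outside the alphabet. Involution: rc(rc(x)) == x.
    """
    out = []
    for i, ch in enumerate(seq.upper()):
        try:
            out.append(_COMPLEMENT[ch])
        except KeyError:
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {i + 1} (1-based)"
            ) from None
    return "".join(reversed(out))


@dataclass(frozen=True)
class DelinsVariant:
    """A deletion-insertion: genomic interval plus replaced/inserted runs.

    Coordinates are 1-based inclusive on the plus strand, matching how such
    variants are printed (e.g. chr3:81493813-81493821).
    """

    chrom: str
    start: int
    end: int
    ref_seq: str
    alt_seq: str
    hgvs_label: str | None = None

    def __post_init__(self):
        if not self.ref_seq or not self.alt_seq:
            raise ValueError("ref_seq and alt_seq must be non-empty")
        for name in ("ref_seq", "alt_seq"):
            s = getattr(self, name)
            bad = set(s) - set("ACGT")
            if bad:
                raise SequenceAlphabetError(f"{name} contains non-ACGT characters: {sorted(bad)}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.end - self.start + 1 != len(self.ref_seq):
            raise ValueError(
                f"interval length {self.end - self.start + 1} != len(ref_seq) {len(self.ref_seq)}"
            )

    @property
    def length_change(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)

    def inverse(self) -> "DelinsVariant":
        """The variant that undoes this one on the alternate sequence."""
        return DelinsVariant(
            chrom=self.chrom,
            start=self.start,
            end=self.start + len(self.alt_seq) - 1,
            ref_seq=self.alt_seq,
            alt_seq=self.ref_seq,
        )


class RefMismatchError(ValueError):
    """Segment disagrees with the variant's expected reference run.

    Almost always a coordinate-convention bug (0- vs 1-based, off-by-one
    anchoring), so the message reports expected vs observed.
    """


def apply_delins(ref: str, variant: DelinsVariant, segment_offset: int) -> str:
    """Apply a delins to a reference segment.

    `segment_offset` is the 1-based genomic position of ``ref[0]``. The
    segment substring at the variant interval must equal ``variant.ref_seq``.
    """
    i0 = variant.start - segment_offset  # 0-based start within the segment
    i1 = i0 + len(variant.ref_seq)
    if i0 < 0 or i1 > len(ref):
        raise ValueError(
            f"variant interval {variant.start}-{variant.end} outside segment "
            f"{segment_offset}-{segment_offset + len(ref) - 1}"
        )
    observed = ref[i0:i1]
    if observed != variant.ref_seq:
        raise RefMismatchError(
            f"reference mismatch at {variant.chrom}:{variant.start}-{variant.end}: "
            f"expected {variant.ref_seq!r}, observed {observed!r}"
        )
    return ref[:i0] + variant.alt_seq + ref[i1:]


@dataclass
class PileupColumn:
    """Per-position base counts for one haplotype."""

    position: int  # 1-based genomic
    counts: dict[str, int]  # base in ACGT -> nonnegative count
    del_count: int = 0
    ins_observations: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.del_count


@dataclass
class PhasedPileup:
    haplotype_id: int
    columns: list[PileupColumn]

    def __post_init__(self):
        pos = [c.position for c in self.columns]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("pileup positions must be strictly increasing")
        for c in self.columns:
            if any(v < 0 for v in c.counts.values()) or c.del_count < 0:
                raise ValueError(f"negative count at position {c.position}")


@dataclass
class HaplotypeConsensus:
    haplotype_id: int
    sequence: str  # may contain IUPAC ambiguity codes
    support: list[int]  # per emitted base, read count backing it
    positions: list[int]  # per emitted base, the 1-based column position
    excluded_positions: list[int]

    def segment(self, start: int, end: int) -> str:
        """Emitted bases whose column position lies in [start, end]."""
        return "".join(
            b for b, p in zip(self.sequence, self.positions) if start <= p <= end
        )


class ConsensusTieError(ValueError):
    """Two bases tie for the majority and tie_policy='fail'."""


def call_consensus(
    pileup: PhasedPileup,
    min_support: int = 2,
    tie_policy: str = "ambiguity",
) -> HaplotypeConsensus:
    """Majority-vote consensus over a phased pileup.

    Per column the most frequent base is emitted when its count reaches
    ``min_support`` (default 2: single-read positions are excluded, the
    standard guard against residual sequencing error at low depth).
    Ties emit the IUPAC ambiguity code for the tied base set
    (``tie_policy='ambiguity'``) or raise (``'fail'``). A column whose
    majority is a deletion emits nothing. An insertion observed after a
    column is emitted when its count exceeds half the column depth and
    reaches ``min_support`` — pileup insertions are attached to the
    preceding position, so the majority criterion is over the column's
    read depth.
    """
    if not pileup.columns:
        raise ValueError("empty pileup")
    if tie_policy not in ("ambiguity", "fail"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")

    seq: list[str] = []
    support: list[int] = []
    positions: list[int] = []
    excluded: list[int] = []
    for col in pileup.columns:
        options = dict(col.counts)
        if col.del_count:
            options["-"] = col.del_count
        best = max(options.values(), default=0)
        if best < min_support:
            excluded.append(col.position)
        else:
            winners = sorted(k for k, v in options.items() if v == best)
            if len(winners) == 1:
                base = winners[0]
            elif tie_policy == "fail":
                raise ConsensusTieError(
                    f"tie at position {col.position}: {winners} each with {best} reads"
                )
            else:
                log.warning("consensus tie at position %d among %s; emitting IUPAC code",
                            col.position, winners)
                tied_bases = frozenset(w for w in winners if w != "-")
                base = IUPAC_FROM_BASES.get(tied_bases, "N") if tied_bases else "-"
            if base != "-":
                seq.append(base)
                support.append(best)
                positions.append(col.position)
        if col.ins_observations:
            ins, n = max(col.ins_observations.items(), key=lambda kv: (kv[1], kv[0]))
            if n >= min_support and n > col.depth / 2:
                seq.extend(ins)
                support.extend([n] * len(ins))
                positions.extend([col.position] * len(ins))

    return HaplotypeConsensus(
        haplotype_id=pileup.haplotype_id,
        sequence="".join(seq),
        support=support,
        positions=positions,
        excluded_positions=excluded,
    )


@dataclass
class AlleleReport:
    """Per-position comparison of a consensus against comparator alleles."""

    mismatches_vs_reference: list[tuple[int, str, str]]  # (1-based offset, consensus, comparator)
    mismatches_vs_reported: list[tuple[int, str, str]]

    @property
    def n_vs_reference(self) -> int:
        return len(self.mismatches_vs_reference)

    @property
    def n_vs_reported(self) -> int:
        return len(self.mismatches_vs_reported)


def _pairwise_mismatches(a: str, b: str) -> list[tuple[int, str, str]]:
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch ({len(a)} vs {len(b)}): anchor the comparison to a "
            "common interval (e.g. the delins interval) before comparing"
        )
    return [(i + 1, x, y) for i, (x, y) in enumerate(zip(a, b)) if x != y]


def compare_alleles(
    consensus: HaplotypeConsensus | str,
    reference_allele: str,
    reported_allele: str,
) -> AlleleReport:
    """Position-by-position comparison of a consensus allele to comparators.

    Inputs must already be in the same orientation and anchored to the same
    interval (equal lengths); a length mismatch raises with instructions
    rather than silently aligning.
    """
    seq = consensus.sequence if isinstance(consensus, HaplotypeConsensus) else consensus
    return AlleleReport(
        mismatches_vs_reference=_pairwise_mismatches(seq, reference_allele),
        mismatches_vs_reported=_pairwise_mismatches(seq, reported_allele),
    )
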