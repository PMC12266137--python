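"""Synthetic GBE1-like locus: ground truth for every downstream stage.

The fixture emulates the intron-15 region of a minus-strand gene carrying a
heterozygous deep-intronic delins (chr3:81493813-81493821 CCACCACAC ->
ACCTGTAATGTAAAAAACA on the genomic plus strand). On the variant haplotype
the inserted run creates an ectopic splice acceptor (transcript-sense
...ACATTAC **AG** | GT...), and two cryptic donors downstream yield two
mutant (MT) isoforms whose pseudoexon — 241 nt in MT1, 206 nt in MT2 —
sits between canonical exons 15 and 16. Twelve nucleotides into the
pseudoexon an in-frame UAA premature termination codon makes both MT
mRNAs nonsense-mediated-decay substrates, while the canonical transcript
terminates normally in its last exon.

Only the printed constraints are real (delins coordinates and alleles,
pseudoexon lengths, PTC position, acceptor placement, exon-16 retention);
exon/intron lengths and all interior sequence are synthetic, generated from
a packaged seed and screened so the reading frame meets the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import DelinsVariant, apply_delins, reverse_complement

CHROM = "chr3"
DELINS_START = 81493813
DELINS_END = 81493821
REF_PLUS = "CCACCACAC"  # replaced run, genomic plus strand
ALT_PLUS = "ACCTGTAATGTAAAAAACA"  # inserted run, genomic plus strand
REF_TS = reverse_complement(REF_PLUS)  # GTGTGGTGG, transcript sense
ALT_TS = reverse_complement(ALT_PLUS)  # TGTTTTTTACATTACAGGT, transcript sense
# The allele as first reported, one substitution off the corrected one.
REPORTED_ALT_TS = "TGTTTTTTACATGACAGGT"
HGVS_LABEL = "NM_000158.4(GBE1):c.2053-3358_2053-3350delinsTGTTTTTTACATTACAGGT"

_FIXTURE_SEED = 20240158  # packaged; fixes all synthetic interior sequence

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


class LocusValidationError(ValueError):
    """A fixture override violates a locus invariant; names the invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain of one isoform, in genomic coordinates of its haplotype.

    Exons are 1-based inclusive intervals ordered 5'->3' in transcript
    orientation (descending genomic position for a minus-strand gene).
    """

    id: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    is_mutant: bool = False

    def __post_init__(self):
        for s, e in self.exons:
            if s > e:
                raise LocusValidationError(f"{self.id}: exon start {s} > end {e}")
        order = [s for s, _ in self.exons]
        if self.strand == "-":
            if any(b >= a for a, b in zip(order, order[1:])):
                raise LocusValidationError(
                    f"{self.id}: exons must descend genomically on the minus strand"
                )
        else:
            if any(b <= a for a, b in zip(order, order[1:])):
                raise LocusValidationError(f"{self.id}: exons must ascend genomically")

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs in transcript order.

        For a minus-strand gene the donor is the genomic *start* of the
        upstream exon (its transcript-3' terminal base) and the acceptor the
        genomic *end* of the downstream exon (its transcript-5' first base).
        """
        chain = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "-":
                chain.append((s1, e2))
            else:
                chain.append((e1, s2))
        return tuple(chain)


@dataclass
class LocusModel:
    name: str
    sequence_ref: str  # genomic plus strand, reference haplotype
    sequence_alt: str  # genomic plus strand, delins haplotype
    gene_strand: str
    delins: DelinsVariant
    transcripts: dict[str, TranscriptModel]
    coordinate_offset: int  # genomic position of segment start, 1-based
    start_codon_spliced_offset: int  # 0-based offset of ATG in each mRNA
    pseudoexon: dict[str, tuple[int, int]] = field(default_factory=dict)
    # transcript id -> which haplotype its exon coordinates live on
    haplotype_of: dict[str, str] = field(default_factory=dict)

    # -- coordinate helpers -------------------------------------------------
    def _hap_seq(self, haplotype: str) -> str:
        return self.sequence_ref if haplotype == "ref" else self.sequence_alt

    def genomic_slice(self, start: int, end: int, haplotype: str = "ref") -> str:
        """Plus-strand bases for a 1-based inclusive genomic interval."""
        seq = self._hap_seq(haplotype)
        i0 = start - self.coordinate_offset
        i1 = end - self.coordinate_offset + 1
        if i0 < 0 or i1 > len(seq):
            raise ValueError(f"interval {start}-{end} outside the {haplotype} segment")
        return seq[i0:i1]

    def lift_ref_to_alt(self, pos: int) -> int:
        """Map a reference-haplotype genomic position into the delins
        haplotype's coordinate frame (positions 3' of the insertion on the
        plus strand are unchanged; positions 5' shift by the length change)."""
        if pos < self.delins.start:
            return pos
        if pos > self.delins.end:
            return pos + self.delins.length_change
        raise ValueError(f"position {pos} lies inside the replaced run; no unique liftover")

    # -- transcript-level helpers ------------------------------------------
    def spliced_sequence(self, transcript_id: str) -> str:
        """mRNA-sense DNA sequence of a transcript (exons spliced, reverse-
        complemented for a minus-strand gene)."""
        t = self.transcripts[transcript_id]
        hap = self.haplotype_of.get(transcript_id, "ref")
        pieces = []
        for s, e in t.exons:
            piece = self.genomic_slice(s, e, hap)
            pieces.append(reverse_complement(piece) if t.strand == "-" else piece)
        return "".join(pieces)

    def junction_chain(self, transcript_id: str, shared_frame: bool = True) -> tuple:
        """Junction chain of a transcript; with ``shared_frame`` the chain of
        a reference-haplotype transcript is lifted into the delins-haplotype
        frame so chains from different isoforms are directly comparable."""
        t = self.transcripts[transcript_id]
        chain = t.junction_chain()
        if shared_frame and self.haplotype_of.get(transcript_id, "ref") == "ref":
            chain = tuple((self.lift_ref_to_alt(d), self.lift_ref_to_alt(a)) for d, a in chain)
        return chain

    # Junctions used for PSI (delins-haplotype frame throughout).
    def inclusion_junction(self) -> tuple[int, int]:
        """exon15 donor -> pseudoexon acceptor (shared by both MT isoforms)."""
        mt1 = self.transcripts["MT1"]
        return mt1.junction_chain()[-2]

    def exclusion_junction(self) -> tuple[int, int]:
        """exon15 donor -> exon16 acceptor (canonical splice), delins frame."""
        return self.junction_chain("canonical", shared_frame=True)[-1]

    def donor_inclusion_junctions(self) -> list[tuple[int, int]]:
        """The two cryptic-donor junctions pseudoexon -> exon16."""
        return [self.transcripts[t].junction_chain()[-1] for t in ("MT1", "MT2")]

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        d = self.delins
        if apply_delins(self.sequence_ref, d, self.coordinate_offset) != self.sequence_alt:
            raise LocusValidationError("sequence_alt must equal sequence_ref with the delins applied")
        pe1 = self.pseudoexon["MT1"]
        pe2 = self.pseudoexon["MT2"]
        len1 = pe1[1] - pe1[0] + 1
        len2 = pe2[1] - pe2[0] + 1
        if len1 <= len2:
            raise LocusValidationError("MT1 pseudoexon must be longer than MT2's")
        if len2 < 15:
            raise LocusValidationError("pseudoexon must be at least 15 nt to contain the PTC")
        # MT2 differs from MT1 only at the pseudoexon donor-side boundary.
        if self.gene_strand == "-" and pe1[1] != pe2[1]:
            raise LocusValidationError("MT isoforms must share the pseudoexon acceptor boundary")
        for tid in ("MT1", "MT2"):
            t = self.transcripts[tid]
            if t.exons[-1] != self.transcripts["canonical"].exons[-1]:
                raise LocusValidationError(f"{tid} must end with canonical exon 16")
            if t.exons[-2] != self.pseudoexon[tid]:
                raise LocusValidationError(f"{tid}: pseudoexon must be the penultimate exon")
            mrna = self.spliced_sequence(tid)
            pe_start = sum(e - s + 1 for s, e in t.exons[:-2])
            if mrna[pe_start + 12:pe_start + 15] != "TAA":
                raise LocusValidationError(
                    f"{tid}: pseudoexon positions 13-15 must read UAA in mRNA sense"
                )
        # ectopic acceptor AG immediately 5' of the pseudoexon start, inside
        # the inserted allele (transcript sense ...AC AG | GT...)
        mt1 = self.transcripts["MT1"]
        hap = self.haplotype_of["MT1"]
        pe_s, pe_e = self.pseudoexon["MT1"]
        if self.gene_strand == "-":
            acceptor_din = reverse_complement(self.genomic_slice(pe_e + 1, pe_e + 2, hap))
        else:
            acceptor_din = self.genomic_slice(pe_s - 2, pe_s - 1, hap)
        if acceptor_din != "AG":
            raise LocusValidationError("ectopic acceptor AG must immediately precede the pseudoexon")
        for tid, t in self.transcripts.items():
            if t.spliced_length != len(self.spliced_sequence(tid)):
                raise LocusValidationError(f"{tid}: spliced length inconsistent with exons")


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _nonstop_codons(rng, n: int) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS, size=n))


def build_fixture_locus(
    pseudoexon_len_mt1: int = 241,
    pseudoexon_len_mt2: int = 206,
    name: str = "GBE1_intron15_fixture",
) -> LocusModel:
    """Build the packaged fixture locus.

    Defaults reproduce every printed constraint simultaneously: the 9->19
    delins at chr3:81493813-81493821, pseudoexon lengths 241/206 nt sharing
    the ectopic acceptor, the UAA PTC at pseudoexon positions 13-15, and
    canonical exon 16 as the final exon of all isoforms. Overrides are for
    stress-testing the validator and must still satisfy the invariants.
    """
    if pseudoexon_len_mt2 < 15:
        raise LocusValidationError("pseudoexon must be at least 15 nt to contain the PTC")
    if pseudoexon_len_mt1 < pseudoexon_len_mt2 + 2:
        raise LocusValidationError(
            "MT1 pseudoexon must extend at least 2 nt past MT2's donor boundary"
        )

    rng = np.random.default_rng(_FIXTURE_SEED)

    # --- assemble the reference transcript-sense sequence -----------------
    # exon lengths (UTR + coding) are synthetic constants; coding portions are
    # multiples of 3 so the frame at every boundary is explicit.
    utr5 = 12
    exon_coding = {"exon11": 108, "exon12": 90, "exon13": 99, "exon14": 120, "exon15": 300}
    exon16_len = 330

    parts: list[tuple[str, str]] = []  # (feature name, sequence)
    parts.append(("up_flank", _random_seq(rng, 200)))
    parts.append(("exon11", _random_seq(rng, utr5) + "ATG" + _nonstop_codons(rng, (exon_coding["exon11"] - 3) // 3)))
    for ex in ("exon12", "exon13", "exon14", "exon15"):
        parts.append((f"intron_before_{ex}", "GT" + _random_seq(rng, 296) + "AG"))
        parts.append((ex, _nonstop_codons(rng, exon_coding[ex] // 3)))
    parts.append(("intron15a", "GT" + _random_seq(rng, 398)))
    parts.append(("delins_site", REF_TS))
    # Pseudoexon interior, positions 3..L1 in pseudoexon coordinates (nt 1-2
    # are the GT tail of the inserted allele). First four codons stop-free,
    # codon 5 (positions 13-15) is the TAA PTC.
    mid_len = pseudoexon_len_mt2 - 15  # nt 16..L2
    tail_len = pseudoexon_len_mt1 - pseudoexon_len_mt2 - 2  # after the MT2 donor GT
    pe_tail = (
        _random_seq(rng, 1)  # nt 3 (codon GT?, never a stop)
        + _nonstop_codons(rng, 3)  # nt 4..12
        + "TAA"  # nt 13..15, the PTC
        + _random_seq(rng, mid_len)  # nt 16..L2
        + "GT"  # MT2 cryptic donor motif (exonic within MT1)
        + _random_seq(rng, tail_len)  # nt L2+3..L1
    )
    parts.append(("pe_tail", pe_tail))
    parts.append(("intron15b", "GT" + _random_seq(rng, 396) + "AG"))
    parts.append(("exon16", _nonstop_codons(rng, 10) + "TAA" + _random_seq(rng, exon16_len - 33)))
    parts.append(("down_flank", _random_seq(rng, 200)))

    # transcript-sense spans, 0-based half-open
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    chunks = []
    for feat, seq in parts:
        spans[feat] = (cursor, cursor + len(seq))
        cursor += len(seq)
        chunks.append(seq)
    ref_ts = "".join(chunks)
    n_ref = len(ref_ts)
    d0, d1 = spans["delins_site"]

    alt_ts = ref_ts[:d0] + ALT_TS + ref_ts[d1:]
    shift = len(ALT_TS) - len(REF_TS)  # +10
    n_alt = n_ref + shift

    # genomic anchoring: the replaced run's lowest plus-strand coordinate is
    # DELINS_START; transcript-sense index i maps to plus position
    # offset + N - 1 - i.
    offset = DELINS_START - (n_ref - d1)

    def ts_to_genomic(span: tuple[int, int], n: int) -> tuple[int, int]:
        a, b = span
        return (offset + n - b, offset + n - 1 - a)

    def alt_span(span: tuple[int, int]) -> tuple[int, int]:
        a, b = span
        return (a + shift, b + shift) if a >= d1 else (a, b)

    exon_order = ["exon11", "exon12", "exon13", "exon14", "exon15"]
    canonical_exons = tuple(ts_to_genomic(spans[e], n_ref) for e in exon_order + ["exon16"])

    # pseudoexon: nt 1-2 are the last two inserted bases, alt ts [d0+17, d0+19)
    pe1_ts = (d0 + 17, d0 + 17 + pseudoexon_len_mt1)
    pe2_ts = (d0 + 17, d0 + 17 + pseudoexon_len_mt2)
    pe1 = ts_to_genomic(pe1_ts, n_alt)
    pe2 = ts_to_genomic(pe2_ts, n_alt)

    mt_shared = tuple(ts_to_genomic(alt_span(spans[e]), n_alt) for e in exon_order)
    exon16_alt = ts_to_genomic(alt_span(spans["exon16"]), n_alt)

    transcripts = {
        "canonical": TranscriptModel("canonical", canonical_exons, "-", is_mutant=False),
        "MT1": TranscriptModel("MT1", mt_shared + (pe1, exon16_alt), "-", is_mutant=True),
        "MT2": TranscriptModel("MT2", mt_shared + (pe2, exon16_alt), "-", is_mutant=True),
    }

    sequence_ref = reverse_complement(ref_ts)
    sequence_alt = reverse_complement(alt_ts)
    delins = DelinsVariant(CHROM, DELINS_START, DELINS_END, REF_PLUS, ALT_PLUS, HGVS_LABEL)

    locus = LocusModel(
        name=name,
        sequence_ref=sequence_ref,
        sequence_alt=sequence_alt,
        gene_strand="-",
        delins=delins,
        transcripts=transcripts,
        coordinate_offset=offset,
        start_codon_spliced_offset=utr5,
        pseudoexon={"MT1": pe1, "MT2": pe2},
        haplotype_of={"canonical": "ref", "MT1": "alt", "MT2": "alt"},
    )
    locus.validate()
    return locus
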