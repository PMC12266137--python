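"""Self-contained hybridization off-target search over a transcriptome.

An alignment of an ASO's binding site (the reverse complement of the
oligo, i.e. the transcript-sense sequence it hybridizes to) is an
off-target when all of the following hold:

* mismatches + gaps <= 1, or >= 16 contiguous matching nucleotides,
* sense orientation (the oligo is reverse-complementary to the
  transcript's sense strand; antisense alignments are discarded), and
* the site lies within 200 nt of an exon (distance measured against the
  gene's canonical transcript where one exists, else the nearest exon of
  any transcript).

The search itself is a seed-and-verify scan over both pre-mRNA and mature
mRNA sense sequences. Ungapped arm: three disjoint 6-nt seeds partition an
18-mer, so by pigeonhole any alignment with <= 2 mismatches contains one
exact seed — candidate diagonals from seed hits are then verified by direct
comparison, making the scan provably complete at <= 2 mismatches. Any
18-mer alignment with >= 16 contiguous matches has <= 2 mismatches and is
caught by the same arm. Gapped arm: single-gap alignments with no
mismatches (the only gapped case the rule can accept) are found by exact
search of every 1-nt deletion/insertion variant of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import reverse_complement

SEED_LENGTH = 6


@dataclass
class Gene:
    """One gene: sense-strand pre-mRNA plus exon annotation per transcript
    (gene-local 1-based inclusive intervals)."""

    gene_id: str
    premrna: str
    transcripts: dict[str, list[tuple[int, int]]]
    canonical_id: str | None = None

    def mature(self, transcript_id: str) -> str:
        return "".join(self.premrna[s - 1:e] for s, e in self.transcripts[transcript_id])


@dataclass
class _Entry:
    gene_id: str
    transcript_id: str | None  # None for the pre-mRNA record
    kind: str  # "pre-mRNA" | "mature"
    sequence: str


@dataclass
class TranscriptomeIndex:
    genes: dict[str, Gene]
    entries: list[_Entry] = field(default_factory=list)
    _seeds: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def build(cls, genes: list[Gene], seed_length: int = SEED_LENGTH) -> "TranscriptomeIndex":
        index = cls(genes={g.gene_id: g for g in genes})
        for g in genes:
            for tid, exons in g.transcripts.items():
                for s, e in exons:
                    if s < 1 or e > len(g.premrna) or s > e:
                        raise ValueError(
                            f"{g.gene_id}/{tid}: exon {s}-{e} outside pre-mRNA "
                            f"of length {len(g.premrna)}"
                        )
            index.entries.append(_Entry(g.gene_id, None, "pre-mRNA", g.premrna))
            for tid in g.transcripts:
                index.entries.append(_Entry(g.gene_id, tid, "mature", g.mature(tid)))
        seeds: dict[str, list[tuple[int, int]]] = {}
        for ei, entry in enumerate(index.entries):
            seq = entry.sequence
            for p in range(len(seq) - seed_length + 1):
                seeds.setdefault(seq[p:p + seed_length], []).append((ei, p))
        index._seeds = seeds
        return index

    def seed_hits(self, kmer: str) -> list[tuple[int, int]]:
        return self._seeds.get(kmer, [])


@dataclass
class OffTargetAlignment:
    gene_id: str
    transcript_id: str | None
    target_kind: str  # "pre-mRNA" | "mature"
    start: int  # 1-based, local to the searched sequence
    aligned_length: int  # 18 ungapped; 17/19 with one gap
    mismatches: int
    gaps: int
    longest_contiguous_match: int
    orientation: str  # always "sense"; antisense alignments are never emitted
    distance_to_exon: int  # 0 if exonic
    used_canonical: bool
    is_offtarget: bool = False


def classify(alignment: OffTargetAlignment, max_distance: int = 200) -> bool:
    """The off-target predicate (boundaries inclusive: distance 200 counts,
    16 contiguous matches count)."""
    similar = (alignment.mismatches + alignment.gaps <= 1
               or alignment.longest_contiguous_match >= 16)
    return (similar
            and alignment.orientation == "sense"
            and alignment.distance_to_exon <= max_distance)


def _longest_match_run(a: str, b: str) -> int:
    best = run = 0
    for x, y in zip(a, b):
        run = run + 1 if x == y else 0
        best = max(best, run)
    return best


def _distance_to_exon(gene: Gene, start: int, end: int) -> tuple[int, bool]:
    """Distance (intervening nt) from an alignment to the nearest exon
    boundary, preferring the canonical transcript when the alignment lies
    within its span."""

    def dist(exons) -> int:
        best = None
        for s, e in exons:
            if start <= e and end >= s:
                return 0
            gap = s - end - 1 if s > end else start - e - 1
            best = gap if best is None else min(best, gap)
        return best

    if gene.canonical_id is not None:
        exons = gene.transcripts[gene.canonical_id]
        span = (min(s for s, _ in exons), max(e for _, e in exons))
        if start >= span[0] and end <= span[1]:
            return dist(exons), True
    all_exons = [iv for exons in gene.transcripts.values() for iv in exons]
    return dist(all_exons), False


def _gap_variants(query: str) -> dict[str, int]:
    """All 1-nt deletion (17-mer) and insertion (19-mer) variants of the
    query, each modelling a single-gap zero-mismatch alignment, mapped to
    the longest contiguous match block (the longer side of the gap; for a
    variant producible by several gap placements, the maximum)."""
    k = len(query)
    variants: dict[str, int] = {}
    for i in range(k):  # gap in the target: query base i unpaired
        v = query[:i] + query[i + 1:]
        run = max(i, k - 1 - i)
        variants[v] = max(variants.get(v, 0), run)
    for i in range(k + 1):  # gap in the query: extra target base at i
        for b in "ACGT":
            v = query[:i] + b + query[i:]
            run = max(i, k - i)
            variants[v] = max(variants.get(v, 0), run)
    return variants


def _exact_occurrences(index: TranscriptomeIndex, pattern: str):
    """All exact occurrences of a pattern (>= seed length) via the seed index."""
    for ei, p in index.seed_hits(pattern[:SEED_LENGTH]):
        seq = index.entries[ei].sequence
        if seq[p:p + len(pattern)] == pattern:
            yield ei, p


def search(aso, index: TranscriptomeIndex, max_mismatches: int = 2) -> list[OffTargetAlignment]:
    """All sense-strand alignments of an ASO's binding site.

    Returns every ungapped alignment with <= ``max_mismatches`` mismatches
    (which includes every alignment carrying a >= 16-nt exact block) plus
    every single-gap zero-mismatch alignment, annotated and classified.
    ``aso`` may be an :class:`~spliceaso.design.AsoCandidate` or a raw
    oligo sequence (RNA or DNA alphabet).
    """
    if hasattr(aso, "aso_seq_dna"):
        query = reverse_complement(aso.aso_seq_dna)
    else:
        query = reverse_complement(str(aso).upper().replace("U", "T"))
    k = len(query)
    n_seeds = k // SEED_LENGTH
    if n_seeds < max_mismatches + 1:
        raise ValueError(
            f"query of length {k} cannot host {max_mismatches + 1} disjoint "
            f"{SEED_LENGTH}-mers; completeness at {max_mismatches} mismatches is lost"
        )

    results: dict[tuple, OffTargetAlignment] = {}

    def emit(ei: int, start0: int, aligned_len: int, mm: int, gaps: int, run: int):
        key = (ei, start0, aligned_len, gaps)
        if key in results:
            return
        entry = index.entries[ei]
        gene = index.genes[entry.gene_id]
        if entry.kind == "mature":
            distance, used_canonical = 0, gene.canonical_id == entry.transcript_id
        else:
            distance, used_canonical = _distance_to_exon(gene, start0 + 1, start0 + aligned_len)
        aln = OffTargetAlignment(
            gene_id=entry.gene_id,
            transcript_id=entry.transcript_id,
            target_kind=entry.kind,
            start=start0 + 1,
            aligned_length=aligned_len,
            mismatches=mm,
            gaps=gaps,
            longest_contiguous_match=run,
            orientation="sense",
            distance_to_exon=distance,
            used_canonical=used_canonical,
        )
        aln.is_offtarget = classify(aln)
        results[key] = aln

    # ungapped arm: pigeonhole over disjoint seeds
    candidates = set()
    for si in range(max_mismatches + 1):
        q_off = si * SEED_LENGTH
        for ei, p in index.seed_hits(query[q_off:q_off + SEED_LENGTH]):
            candidates.add((ei, p - q_off))
    for ei, start0 in candidates:
        seq = index.entries[ei].sequence
        if start0 < 0 or start0 + k > len(seq):
            continue
        window = seq[start0:start0 + k]
        mm = sum(a != b for a, b in zip(query, window))
        if mm <= max_mismatches:
            emit(ei, start0, k, mm, 0, _longest_match_run(query, window))

    # gapped arm: exact occurrences of every single-gap variant
    for variant, run in _gap_variants(query).items():
        for ei, p in _exact_occurrences(index, variant):
            emit(ei, p, len(variant), 0, 1, run)

    return sorted(results.values(), key=lambda a: (a.gene_id, a.target_kind, a.start, a.gaps))


def summarize(
    aso_list,
    index: TranscriptomeIndex,
    on_target_gene: str | None = None,
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Per-ASO count of predicted off-targets, excluding the on-target gene.

    The zero-count set drives the design module's ``pass_offtarget`` flag.
    """
    rows = []
    for aso in aso_list:
        aso_id = getattr(aso, "id", str(aso))
        hits = search(aso, index, max_mismatches=max_mismatches)
        n = sum(1 for h in hits if h.is_offtarget and h.gene_id != on_target_gene)
        rows.append({"id": aso_id, "offtarget_count": n})
    return pd.DataFrame(rows)


def hits_to_frame(hits: list[OffTargetAlignment]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])
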