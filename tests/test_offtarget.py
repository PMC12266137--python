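"""Hybridization off-target search: completeness vs brute force, rule edges."""

import numpy as np
import pytest

from spliceaso.offtarget import (
    Gene,
    OffTargetAlignment,
    TranscriptomeIndex,
    classify,
    search,
    summarize,
)
from spliceaso.variants import reverse_complement


def _aln(mm=0, gaps=0, run=18, distance=0):
    return OffTargetAlignment(
        gene_id="g", transcript_id=None, target_kind="pre-mRNA", start=1,
        aligned_length=18, mismatches=mm, gaps=gaps, longest_contiguous_match=run,
        orientation="sense", distance_to_exon=distance, used_canonical=True,
    )


class TestClassify:
    @pytest.mark.parametrize("mm,gaps,run,dist,expected", [
        (0, 0, 18, 0, True),     # perfect exonic match
        (1, 0, 17, 0, True),     # one mismatch allowed
        (2, 0, 15, 0, False),    # 2 mm and only 15 contiguous: similar arm fails
        (2, 0, 16, 0, True),     # 16 contiguous rescues a 2-mismatch site
        (0, 1, 17, 0, True),     # one gap counts like one mismatch
        (1, 1, 10, 0, False),    # mismatch + gap exceeds the budget
        (1, 0, 17, 200, True),   # distance boundary inclusive
        (1, 0, 17, 201, False),  # one nt beyond the boundary
        (1, 0, 17, 250, False),
    ])
    def test_rule_boundaries(self, mm, gaps, run, dist, expected):
        assert classify(_aln(mm=mm, gaps=gaps, run=run, distance=dist)) is expected

    def test_monotone_in_distance_and_mismatches(self):
        for mm in range(3):
            for dist in (0, 100, 200, 201, 400):
                a = classify(_aln(mm=mm, run=18 - mm and 12 or 18, distance=dist))
                b = classify(_aln(mm=mm, run=18 - mm and 12 or 18,
                                  distance=max(0, dist - 50)))
                assert b >= a  # decreasing distance never flips true -> false


def _brute_force(query, index, max_mismatches=2):
    """Exhaustive sliding-window oracle over every offset of every sequence.

    Records keyed like the seed search: (entry index, 0-based start,
    aligned length, gap count). Ungapped: Hamming <= max_mismatches.
    Gapped: 17-nt windows equal to the query minus one base, and 19-nt
    windows equal to the query plus one inserted base.
    """
    k = len(query)
    found = {}
    for ei, entry in enumerate(index.entries):
        seq = entry.sequence
        for p in range(len(seq) - k + 1):
            mm = sum(a != b for a, b in zip(query, seq[p:p + k]))
            if mm <= max_mismatches:
                found[(ei, p, k, 0)] = mm
        for p in range(len(seq) - (k - 1) + 1):
            w = seq[p:p + k - 1]
            if any(query[:i] + query[i + 1:] == w for i in range(k)):
                found[(ei, p, k - 1, 1)] = 0
        for p in range(len(seq) - (k + 1) + 1):
            w = seq[p:p + k + 1]
            if any(w[:i] + w[i + 1:] == query for i in range(k + 1)):
                found[(ei, p, k + 1, 1)] = 0
    return found


def _random_transcriptome(rng, n_genes=2, length=800):
    genes = []
    for i in range(n_genes):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        third = length // 3
        genes.append(Gene(
            gene_id=f"G{i}", premrna=seq,
            transcripts={f"G{i}-t1": [(1, third), (2 * third, length)]},
            canonical_id=f"G{i}-t1",
        ))
    return genes


class TestSearchCompleteness:
    def test_exact_substring_found_at_known_offset(self):
        rng = np.random.default_rng(0)
        genes = _random_transcriptome(rng, 1)
        index = TranscriptomeIndex.build(genes)
        target = genes[0].premrna[100:118]
        hits = search(reverse_complement(target), index)
        pre = [h for h in hits if h.target_kind == "pre-mRNA" and h.gaps == 0
               and h.mismatches == 0]
        assert any(h.start == 101 for h in pre)

    def test_empty_transcriptome(self):
        index = TranscriptomeIndex.build([])
        assert search("ACGUACGUACGUACGUAC", index) == []

    def test_matches_bruteforce_on_random_transcriptomes(self):
        """Seed-and-verify search is set-identical to the exhaustive scan."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            genes = _random_transcriptome(rng, n_genes=2, length=600)
            index = TranscriptomeIndex.build(genes)
            # query related to a real site so hits actually occur
            base = list(genes[0].premrna[50:68])
            for _ in range(rng.integers(0, 3)):
                base[rng.integers(0, 18)] = rng.choice(list("ACGT"))
            query = "".join(base)
            hits = search(reverse_complement(query), index)
            got = {(next(i for i, e in enumerate(index.entries)
                         if e.gene_id == h.gene_id and e.transcript_id == h.transcript_id),
                    h.start - 1, h.aligned_length, h.gaps): h.mismatches
                   for h in hits}
            expected = _brute_force(query, index)
            assert got == expected

    def test_planted_gap_site_found(self):
        rng = np.random.default_rng(7)
        genes = _random_transcriptome(rng, 1)
        index = TranscriptomeIndex.build(genes)
        window17 = genes[0].premrna[200:217]
        # an 18-mer query with one extra base aligns to the 17-nt genomic
        # window with a single gap and zero mismatches
        extra = "A" if window17[9] != "A" else "C"
        query18 = window17[:9] + extra + window17[9:]
        hits = search(reverse_complement(query18), index)
        gapped = [h for h in hits if h.gaps == 1 and h.target_kind == "pre-mRNA"]
        assert any(h.start == 201 and h.aligned_length == 17 for h in gapped)


class TestDistanceAndSummary:
    def _single_gene(self, seq, exons, canonical="t1"):
        return TranscriptomeIndex.build([
            Gene("g", seq, {"t1": exons}, canonical_id=canonical)
        ])

    def test_planted_sites_at_150_and_201(self):
        rng = np.random.default_rng(3)
        flank = "".join(rng.choice(list("ACGT"), size=1500))
        site = "ACGTTGCATGCCAGGTAC"
        # exon at 1..100; sites end-anchored 150 nt and 201 nt past the exon
        seq = list(flank)
        seq[250:268] = site  # 1-based start 251, exon ends at 100 -> distance 150
        seq[301:319] = site  # 1-based start 302 -> distance 201, just past the rule
        seq = "".join(seq)
        index = self._single_gene(seq, [(1, 100)])
        hits = [h for h in search(reverse_complement(site), index)
                if h.target_kind == "pre-mRNA" and h.mismatches == 0 and h.gaps == 0]
        distances = sorted(h.distance_to_exon for h in hits)
        assert distances == [150, 201]
        offtargets = [h for h in hits if h.is_offtarget]
        assert len(offtargets) == 1 and offtargets[0].distance_to_exon == 150

    def test_exonic_hit_distance_zero_and_mature_hits(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        index = self._single_gene(seq, [(1, 200)])
        target = seq[50:68]
        hits = search(reverse_complement(target), index)
        pre = [h for h in hits if h.target_kind == "pre-mRNA" and h.mismatches == 0]
        mat = [h for h in hits if h.target_kind == "mature" and h.mismatches == 0]
        assert pre and pre[0].distance_to_exon == 0
        assert mat and mat[0].distance_to_exon == 0

    def test_summarize_excludes_on_target_gene(self):
        rng = np.random.default_rng(5)
        on_seq = "".join(rng.choice(list("ACGT"), size=300))
        off_seq = "".join(rng.choice(list("ACGT"), size=300))
        target = on_seq[100:118]
        off_seq = off_seq[:40] + target + off_seq[58:]  # planted exonic copy
        genes = [
            Gene("ONTGT", on_seq, {"t": [(1, 300)]}, canonical_id="t"),
            Gene("OTHER", off_seq, {"t": [(1, 300)]}, canonical_id="t"),
        ]
        index = TranscriptomeIndex.build(genes)

        class Oligo:
            id = "aso1"
            aso_seq_dna = reverse_complement(target)

        table = summarize([Oligo()], index, on_target_gene="ONTGT")
        # planted copy appears on OTHER's pre-mRNA and mature record
        assert table.loc[0, "offtarget_count"] >= 2

    def test_no_homology_means_zero(self):
        index = TranscriptomeIndex.build([
            Gene("g", "A" * 500, {"t": [(1, 500)]}, canonical_id="t")
        ])
        table = summarize(["GCGCGCGCGCGCGCGCGC"], index)
        assert table.loc[0, "offtarget_count"] == 0
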