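"""Fixture locus invariants and the simulators built on it."""

import numpy as np
import pytest

from spliceaso import (
    build_fixture_locus,
    call_consensus,
    reverse_complement,
    simulate_dose_response,
    simulate_junction_counts,
    simulate_long_reads,
    simulate_phased_pileup,
)
from spliceaso.locus import ALT_PLUS, ALT_TS, REF_PLUS, LocusValidationError
from spliceaso.simulate import SimulationConfig, logistic_response


class TestFixtureLocus:
    def test_all_printed_constraints_hold_simultaneously(self, locus):
        """Single fixture-validation check: delins geometry, pseudoexon
        lengths, PTC position, acceptor motif, exon-16 retention."""
        locus.validate()  # raises on any violated invariant
        d = locus.delins
        assert (d.end - d.start + 1, len(d.ref_seq), len(d.alt_seq)) == (9, 9, 19)
        pe1, pe2 = locus.pseudoexon["MT1"], locus.pseudoexon["MT2"]
        assert pe1[1] - pe1[0] + 1 == 241
        assert pe2[1] - pe2[0] + 1 == 206
        assert len(locus.sequence_alt) - len(locus.sequence_ref) == 10
        for tid in ("MT1", "MT2"):
            exons = locus.transcripts[tid].exons
            assert exons[-1] == locus.transcripts["canonical"].exons[-1]
            assert exons[-2] == locus.pseudoexon[tid]

    def test_mt2_shares_acceptor_but_shorter_donor_side(self, locus):
        pe1, pe2 = locus.pseudoexon["MT1"], locus.pseudoexon["MT2"]
        assert pe1[1] == pe2[1]  # shared acceptor boundary (genomic end, minus strand)
        assert (pe1[1] - pe1[0]) - (pe2[1] - pe2[0]) == 35

    def test_delins_sequences_on_both_strands(self, locus):
        d = locus.delins
        assert locus.genomic_slice(d.start, d.end, "ref") == REF_PLUS
        assert locus.genomic_slice(d.start, d.start + 18, "alt") == ALT_PLUS
        assert reverse_complement(ALT_PLUS) == ALT_TS

    def test_spliced_sequence_matches_exon_concatenation(self, locus):
        for tid, t in locus.transcripts.items():
            hap = locus.haplotype_of[tid]
            expected = "".join(
                reverse_complement(locus.genomic_slice(s, e, hap)) for s, e in t.exons
            )
            assert locus.spliced_sequence(tid) == expected
            assert t.spliced_length == len(expected)

    def test_shared_frame_junctions_align_across_haplotypes(self, locus):
        """Junctions genomically 5' of the delins shift by the length change;
        the canonical exon15 donor must coincide with the MT exon15 donor."""
        can = locus.junction_chain("canonical", shared_frame=True)
        mt1 = locus.junction_chain("MT1", shared_frame=True)
        assert can[:-1] == mt1[:len(can) - 1]
        assert can[-1][0] == mt1[len(can) - 1][0]  # same exon15 donor site
        assert can[-1][1] != mt1[len(can) - 1][1]  # different acceptors

    def test_invalid_override_names_invariant(self):
        with pytest.raises(LocusValidationError, match="15 nt"):
            build_fixture_locus(pseudoexon_len_mt1=50, pseudoexon_len_mt2=10)
        with pytest.raises(LocusValidationError, match="donor boundary"):
            build_fixture_locus(pseudoexon_len_mt1=100, pseudoexon_len_mt2=100)

    def test_reproducible(self, locus):
        again = build_fixture_locus()
        assert again.sequence_ref == locus.sequence_ref
        assert again.sequence_alt == locus.sequence_alt
        assert again.transcripts == locus.transcripts


class TestPhasedPileupSimulator:
    def test_no_noise_is_unanimous(self, locus):
        for p in simulate_phased_pileup(locus, depth=30, error_rate=0.0, seed=0):
            for col in p.columns:
                assert max(col.counts.values()) == 30

    def test_depth_one_single_read_everywhere(self, locus):
        for p in simulate_phased_pileup(locus, depth=1, error_rate=0.0, seed=0):
            for col in p.columns:
                assert sum(col.counts.values()) == 1

    def test_consensus_recovers_insertion_under_noise(self, locus):
        pileups = simulate_phased_pileup(locus, depth=30, error_rate=0.01, seed=7)
        cons = call_consensus(pileups[1])
        d = locus.delins
        assert cons.segment(d.start, d.start + 18) == ALT_PLUS

    def test_error_rate_half_refused(self, locus):
        with pytest.raises(ValueError, match="majority"):
            simulate_phased_pileup(locus, depth=30, error_rate=0.5, seed=0)

    def test_seed_determinism(self, locus):
        a = simulate_phased_pileup(locus, 20, 0.02, seed=5)
        b = simulate_phased_pileup(locus, 20, 0.02, seed=5)
        assert a == b


class TestJunctionSimulator:
    def test_psi_extremes(self, locus):
        t0 = simulate_junction_counts(locus, 0.0, 1000, seed=1)
        assert t0.loc[t0.label == "inclusion_acceptor", "count"].item() == 0
        t1 = simulate_junction_counts(locus, 1.0, 1000, seed=1)
        assert t1.loc[t1.label == "exclusion", "count"].item() == 0

    def test_estimate_within_three_binomial_sd(self, locus):
        n, p = 5000, 0.028
        t = simulate_junction_counts(locus, p, n, seed=1)
        incl = t.loc[t.label == "inclusion_acceptor", "count"].item()
        excl = t.loc[t.label == "exclusion", "count"].item()
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(incl / (incl + excl) - p) <= 3 * sd

    def test_decoys_always_present(self, locus):
        t = simulate_junction_counts(locus, 0.02, 100, seed=2)
        decoys = t[t.label.str.startswith("decoy")]
        assert sorted(decoys["count"]) == [1, 2, 3]

    def test_input_validation(self, locus):
        with pytest.raises(ValueError):
            simulate_junction_counts(locus, 0.5, 0, seed=1)


class TestLongReadSimulator:
    def test_pure_canonical(self, locus):
        reads = simulate_long_reads(locus, {"canonical": 1.0}, 100, seed=1)
        chain = locus.junction_chain("canonical", shared_frame=True)
        assert all(r.junctions == chain for r in reads)
        assert all(r.sequence == locus.spliced_sequence("canonical") for r in reads)

    def test_multinomial_counts_near_expectation(self, locus):
        props = {"canonical": 0.866, "MT1": 0.062, "MT2": 0.072}
        reads = simulate_long_reads(locus, props, 20000, seed=3)
        counts = {t: sum(r.isoform_truth == t for r in reads) for t in props}
        for t, p in props.items():
            sd = np.sqrt(p * (1 - p) * 20000)
            assert abs(counts[t] - 20000 * p) <= 3 * sd

    def test_unknown_isoform_rejected(self, locus):
        with pytest.raises(ValueError, match="unknown isoform"):
            simulate_long_reads(locus, {"nope": 1.0}, 10, seed=1)

    def test_full_truncation_leaves_some_reads_without_junctions(self, locus):
        reads = simulate_long_reads(locus, {"canonical": 1.0}, 300, seed=4,
                                    truncate_frac=1.0)
        assert any(len(r.junctions) == 0 for r in reads)
        assert all(len(r.junctions) < 6 for r in reads)


class TestDoseSimulator:
    def test_noiseless_definition_of_ec50(self):
        t = simulate_dose_response(2.0, 1.5, [2.0], 0.0, seed=1, n_replicates=1)
        # raw percent-of-mock scale: mock 100 plus half the 0-100 span
        assert t["response"].item() == pytest.approx(150.0)

    def test_steep_curve_saturates(self):
        assert logistic_response(200.0, 2.0, 8.0) == pytest.approx(100.0, abs=1e-10)

    def test_config_proportions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(isoform_proportions={"canonical": 0.5, "MT1": 0.2})
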