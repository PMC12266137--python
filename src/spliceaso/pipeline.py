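"""End-to-end orchestration of the synthetic pipeline.

``run_pipeline`` executes the stages in dependency order — simulate
(locus + all data types), consensus, PSI, isoform assignment, ORF/NMD,
ASO design, off-target screen, pharmacology — writing each stage's
outputs plus a manifest of parameters and output checksums. All
randomness derives from the single config seed, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .design import DesignConfig, design_candidates, design_report
from .locus import LocusModel, build_fixture_locus
from .offtarget import Gene, TranscriptomeIndex, summarize
from .pharmacology import fit_dose_response, fits_to_frame, serial_dilution
from .simulate import (
    reads_to_frame,
    simulate_dose_response,
    simulate_junction_counts,
    simulate_long_reads,
    simulate_phased_pileup,
)
from .splicing import annotate_orf, assign_reads, compute_psi, filter_junctions
from .variants import call_consensus


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "spliceaso_run"
    depth: int = 30
    error_rate: float = 0.01
    psi_true: float = 0.017
    total_junction_reads: int = 5000
    n_long_reads: int = 20000
    isoform_proportions: dict[str, float] = field(
        default_factory=lambda: {"canonical": 0.866, "MT1": 0.062, "MT2": 0.072}
    )
    design: DesignConfig = field(default_factory=DesignConfig)
    nmd_threshold_nt: int = 50
    dilution_start: float = 20.0
    dilution_factor: float = 4.0
    dilution_points: int = 5
    drc_ec50: float = 2.0
    drc_hill: float = 1.5
    drc_noise_sd: float = 5.0
    hit_threshold_percent: float = 140.0
    transcriptome: str | None = None  # "synthetic" builds decoys from the seed
    n_decoy_genes: int = 3

    def stage_seed(self, stage: str) -> int:
        """A per-stage seed derived stably from the run seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def locus_as_gene(locus: LocusModel, gene_id: str = "GBE1_fixture") -> Gene:
    """The fixture's variant haplotype as an off-target Gene record
    (transcript-sense pre-mRNA, transcript-local exon intervals)."""
    from .variants import reverse_complement

    premrna = reverse_complement(locus.sequence_alt)
    n = len(locus.sequence_alt)

    def ts_interval(exon: tuple[int, int]) -> tuple[int, int]:
        s, e = exon
        # transcript-sense 0-based index of genomic position g is
        # (offset + n - 1) - g; the exon 5' end is its genomic end.
        i0 = locus.coordinate_offset + n - 1 - e
        return (i0 + 1, i0 + (e - s + 1))

    transcripts = {}
    for tid in ("MT1", "MT2"):
        t = locus.transcripts[tid]
        transcripts[tid] = [ts_interval(ex) for ex in t.exons]
    # canonical lifted into the variant frame so all share one coordinate space
    lifted = tuple(
        (locus.lift_ref_to_alt(s), locus.lift_ref_to_alt(e))
        for s, e in locus.transcripts["canonical"].exons
    )
    transcripts["canonical"] = [ts_interval(ex) for ex in lifted]
    return Gene(gene_id=gene_id, premrna=premrna, transcripts=transcripts,
                canonical_id="canonical")


def make_decoy_genes(seed: int, n_genes: int = 3, length: int = 3000) -> list[Gene]:
    """Random decoy genes (uniform sequence, two exons each) for off-target
    screening at desk scale."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        third = length // 3
        exons = [(1, third), (2 * third, length)]
        genes.append(Gene(
            gene_id=f"DECOY{i + 1}", premrna=seq,
            transcripts={f"DECOY{i + 1}-201": exons}, canonical_id=f"DECOY{i + 1}-201",
        ))
    return genes


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}

    def record(stage: str, paths: dict):
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in paths.items()
        }

    # 1. simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        locus = build_fixture_locus()
        paths = sio.write_locus(locus, out / "locus")
        pileups = simulate_phased_pileup(
            locus, config.depth, config.error_rate, config.stage_seed("pileup"))
        sio.write_pileups(pileups, out / "pileup.tsv")
        junctions = simulate_junction_counts(
            locus, config.psi_true, config.total_junction_reads,
            config.stage_seed("junctions"))
        sio.write_table(junctions, out / "junctions.tsv")
        reads = simulate_long_reads(
            locus, config.isoform_proportions, config.n_long_reads,
            config.stage_seed("longreads"))
        sio.write_table(reads_to_frame(reads), out / "read_chains.tsv")
        doses = serial_dilution(config.dilution_start, config.dilution_factor,
                                config.dilution_points)
        dose_table = simulate_dose_response(
            config.drc_ec50, config.drc_hill, doses, config.drc_noise_sd,
            config.stage_seed("dose"), mode="stimulation")
        sio.write_table(dose_table, out / "dose_response.csv")
        record(stage, {**paths, "pileup": out / "pileup.tsv",
                       "junctions": out / "junctions.tsv",
                       "read_chains": out / "read_chains.tsv",
                       "dose_response": out / "dose_response.csv"})
    except Exception as e:
        raise StageError(stage, e) from e

    # 2. consensus ---------------------------------------------------------
    stage = "consensus"
    try:
        consensus_info = {}
        for p in pileups:
            cons = call_consensus(p)
            fasta = out / f"consensus_hap{p.haplotype_id}.fasta"
            report = out / f"consensus_hap{p.haplotype_id}.json"
            sio.write_consensus(cons, fasta, report)
            consensus_info[f"hap{p.haplotype_id}_fasta"] = fasta
            consensus_info[f"hap{p.haplotype_id}_report"] = report
        record(stage, consensus_info)
    except Exception as e:
        raise StageError(stage, e) from e

    # 3. quantify ----------------------------------------------------------
    stage = "quantify"
    try:
        kept = filter_junctions(junctions)
        psi = compute_psi(kept, locus)
        quant = assign_reads(reads, locus)
        orf = {tid: asdict(annotate_orf(tid, locus, config.nmd_threshold_nt))
               for tid in locus.transcripts}
        (out / "psi.json").write_text(json.dumps({
            "inclusion": psi.inclusion_count, "exclusion": psi.exclusion_count,
            "psi": psi.psi, "ci": [psi.ci_low, psi.ci_high]}, indent=2))
        (out / "orf.json").write_text(json.dumps(orf, indent=2))
        sio.write_table(
            fits_frame := _proportions_frame(quant), out / "isoform_proportions.csv")
        record(stage, {"psi": out / "psi.json", "orf": out / "orf.json",
                       "proportions": out / "isoform_proportions.csv"})
    except Exception as e:
        raise StageError(stage, e) from e

    # 4. design ------------------------------------------------------------
    stage = "design"
    try:
        candidates = design_candidates(locus, config.design)
        sio.write_table(design_report(candidates), out / "candidates.csv")
        record(stage, {"candidates": out / "candidates.csv"})
    except Exception as e:
        raise StageError(stage, e) from e

    # 5. off-target --------------------------------------------------------
    stage = "offtarget"
    try:
        if config.transcriptome not in (None, "synthetic"):
            raise ValueError(
                "external transcriptome FASTA+GFF3 input not configured; "
                "set transcriptome='synthetic' for the packaged decoy set"
            )
        genes = [locus_as_gene(locus)] + make_decoy_genes(
            config.stage_seed("decoys"), config.n_decoy_genes)
        index = TranscriptomeIndex.build(genes)
        ot = summarize(candidates, index, on_target_gene="GBE1_fixture")
        sio.write_table(ot, out / "offtargets.csv")
        report = design_report(candidates, dict(zip(ot["id"], ot["offtarget_count"])))
        sio.write_table(report, out / "design_report.csv")
        record(stage, {"offtargets": out / "offtargets.csv",
                       "design_report": out / "design_report.csv"})
    except Exception as e:
        raise StageError(stage, e) from e

    # 6. pharmacology ------------------------------------------------------
    stage = "pharmacology"
    try:
        fit = fit_dose_response(dose_table, mode="stimulation")
        sio.write_table(fits_to_frame([fit]), out / "drc_fits.csv")
        record(stage, {"drc_fits": out / "drc_fits.csv"})
    except Exception as e:
        raise StageError(stage, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _proportions_frame(quant):
    import pandas as pd

    return pd.DataFrame({
        "isoform": list(quant.counts),
        "count": list(quant.counts.values()),
        "proportion": [quant.proportions[t] for t in quant.counts],
    })


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
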