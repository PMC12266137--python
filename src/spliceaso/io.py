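"""Readers and writers for the pipeline's on-disk formats.

Conventions: GFF3 and VCF are 1-based inclusive; the delins VCF record is
left-anchored (POS one base 5' of the replaced run, anchor base shared by
REF and ALT); tables are headered TSV/CSV chosen by extension; FASTA via
Biopython. Writing then reading a LocusModel reproduces an equal model.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import LocusModel, TranscriptModel
from .variants import DelinsVariant, HaplotypeConsensus, PhasedPileup, PileupColumn


# -- FASTA ------------------------------------------------------------------

def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path), "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 -------------------------------------------------------------------

def write_locus_gff3(locus: LocusModel, path) -> None:
    """Transcript/exon features, 1-based inclusive, exons carrying Parent.

    Each transcript records which haplotype frame its coordinates live on
    (the variant haplotype for pseudoexon-bearing isoforms).
    """
    lines = ["##gff-version 3"]
    chrom = locus.delins.chrom
    for tid, t in locus.transcripts.items():
        hap = locus.haplotype_of.get(tid, "ref")
        lo = min(s for s, _ in t.exons)
        hi = max(e for _, e in t.exons)
        lines.append("\t".join([
            chrom, "spliceaso", "transcript", str(lo), str(hi), ".", t.strand, ".",
            f"ID={tid};haplotype={hap};is_mutant={int(t.is_mutant)}",
        ]))
        for i, (s, e) in enumerate(t.exons, start=1):
            lines.append("\t".join([
                chrom, "spliceaso", "exon", str(s), str(e), ".", t.strand, ".",
                f"ID={tid}.exon{i};Parent={tid}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_transcripts(path) -> dict[str, dict]:
    """Transcript id -> {exons (transcript order), strand, haplotype, is_mutant}."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out: dict[str, dict] = {}
    for tr in db.features_of_type("transcript"):
        exons = [(f.start, f.end) for f in db.children(tr, featuretype="exon")]
        exons.sort(key=lambda iv: iv[0], reverse=(tr.strand == "-"))
        out[tr.id] = {
            "exons": exons,
            "strand": tr.strand,
            "haplotype": tr.attributes.get("haplotype", ["ref"])[0],
            "is_mutant": bool(int(tr.attributes.get("is_mutant", ["0"])[0])),
        }
    return out


# -- VCF (single left-anchored delins record) -------------------------------

def write_vcf_record(locus: LocusModel, path) -> None:
    d = locus.delins
    anchor = locus.genomic_slice(d.start - 1, d.start - 1, "ref")
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={d.chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    info = f"HGVS={d.hgvs_label}" if d.hgvs_label else "."
    row = [d.chrom, str(d.start - 1), ".", anchor + d.ref_seq, anchor + d.alt_seq,
           ".", "PASS", info]
    Path(path).write_text("\n".join(header) + "\n" + "\t".join(row) + "\n")


def read_vcf_record(path) -> DelinsVariant:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"{path}:{lineno}: malformed VCF record ({len(fields)} fields)")
        chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
        if ref[0] != alt[0]:
            raise ValueError(f"{path}:{lineno}: record is not left-anchored")
        hgvs = None
        for kv in fields[7].split(";"):
            if kv.startswith("HGVS="):
                hgvs = kv[5:]
        return DelinsVariant(chrom, pos + 1, pos + len(ref) - 1, ref[1:], alt[1:], hgvs)
    raise ValueError(f"{path}: no variant record found")


# -- LocusModel round trip --------------------------------------------------

def write_locus(locus: LocusModel, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "locus.fasta",
        "gff3": out / "transcripts.gff3",
        "vcf": out / "delins.vcf",
        "meta": out / "locus.json",
    }
    write_fasta({f"{locus.name}|ref": locus.sequence_ref,
                 f"{locus.name}|alt": locus.sequence_alt}, paths["fasta"])
    write_locus_gff3(locus, paths["gff3"])
    write_vcf_record(locus, paths["vcf"])
    meta = {
        "name": locus.name,
        "gene_strand": locus.gene_strand,
        "coordinate_offset": locus.coordinate_offset,
        "start_codon_spliced_offset": locus.start_codon_spliced_offset,
        "pseudoexon": locus.pseudoexon,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_locus(in_dir) -> LocusModel:
    src = Path(in_dir)
    meta = json.loads((src / "locus.json").read_text())
    fasta = read_fasta(src / "locus.fasta")
    name = meta["name"]
    delins = read_vcf_record(src / "delins.vcf")
    transcripts = {}
    haplotype_of = {}
    for tid, rec in read_gff3_transcripts(src / "transcripts.gff3").items():
        transcripts[tid] = TranscriptModel(
            id=tid, exons=tuple(rec["exons"]), strand=rec["strand"],
            is_mutant=rec["is_mutant"],
        )
        haplotype_of[tid] = rec["haplotype"]
    locus = LocusModel(
        name=name,
        sequence_ref=fasta[f"{name}|ref"],
        sequence_alt=fasta[f"{name}|alt"],
        gene_strand=meta["gene_strand"],
        delins=delins,
        transcripts=transcripts,
        coordinate_offset=meta["coordinate_offset"],
        start_codon_spliced_offset=meta["start_codon_spliced_offset"],
        pseudoexon={k: tuple(v) for k, v in meta["pseudoexon"].items()},
        haplotype_of=haplotype_of,
    )
    locus.validate()
    return locus


# -- tables -----------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# -- pileups ----------------------------------------------------------------

def write_pileups(pileups: list[PhasedPileup], path) -> None:
    rows = []
    for p in pileups:
        for col in p.columns:
            ins = ",".join(f"{s}:{n}" for s, n in sorted(col.ins_observations.items())) or "."
            rows.append({
                "haplotype": p.haplotype_id, "pos": col.position,
                "A": col.counts.get("A", 0), "C": col.counts.get("C", 0),
                "G": col.counts.get("G", 0), "T": col.counts.get("T", 0),
                "DEL": col.del_count, "INS": ins,
            })
    write_table(pd.DataFrame(rows), path)


def read_pileups(path) -> list[PhasedPileup]:
    df = read_table(path)
    pileups = []
    for hap, grp in df.groupby("haplotype", sort=True):
        columns = []
        for _, r in grp.sort_values("pos").iterrows():
            ins = {}
            if isinstance(r["INS"], str) and r["INS"] != ".":
                for item in r["INS"].split(","):
                    s, n = item.rsplit(":", 1)
                    ins[s] = int(n)
            columns.append(PileupColumn(
                position=int(r["pos"]),
                counts={b: int(r[b]) for b in "ACGT"},
                del_count=int(r["DEL"]),
                ins_observations=ins,
            ))
        pileups.append(PhasedPileup(haplotype_id=int(hap), columns=columns))
    return pileups


def write_consensus(consensus: HaplotypeConsensus, fasta_path, report_path=None) -> None:
    write_fasta({f"haplotype_{consensus.haplotype_id}": consensus.sequence}, fasta_path)
    if report_path is not None:
        Path(report_path).write_text(json.dumps({
            "haplotype_id": consensus.haplotype_id,
            "length": len(consensus.sequence),
            "support": consensus.support,
            "positions": consensus.positions,
            "excluded_positions": consensus.excluded_positions,
        }, indent=2))
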