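"""Rule-based design of splice-modulating antisense oligonucleotides.

Candidates are 18-mers tiled at 1-nt resolution across a pre-mRNA window
around the delins, each the reverse complement of its transcript-sense
target. Three filters mirror standard steric-block ASO practice: GC
content within 25-75% (inclusive), no homopolymer run of six or more, and
no predicted hybridization off-target (computed by :mod:`spliceaso.offtarget`).
Allele specificity is tracked as Hamming distances of the target site
against the variant and reference haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .locus import ALT_TS, REF_TS, REPORTED_ALT_TS, LocusModel
from .variants import reverse_complement


@dataclass
class DesignConfig:
    aso_length: int = 18
    step: int = 1
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_run_allowed: int = 5  # runs of max_run_allowed + 1 or more are rejected
    alphabet: str = "RNA"  # ASOs are RNA oligos; "DNA" reports T instead of U
    window_flank: int = 60  # window = insertion +/- this many nt
    target_allele: str = "corrected"  # or "reported", the pre-correction allele

    def __post_init__(self):
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.alphabet not in ("RNA", "DNA"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.target_allele not in ("corrected", "reported"):
            raise ValueError(f"unknown target_allele {self.target_allele!r}")


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


@dataclass
class AsoCandidate:
    id: str
    target_start: int  # 1-based inclusive, transcript-sense pre-mRNA coords
    target_end: int
    target_seq: str  # transcript-sense DNA
    aso_seq: str  # reverse complement, RNA or DNA alphabet
    gc_fraction: float = field(init=False)
    max_homopolymer_run: int = field(init=False)
    mismatches_vs_alt: int | None = None
    mismatches_vs_ref: int | None = None  # None: no anchored ref window exists
    pass_gc: bool | None = None
    pass_homopolymer: bool | None = None
    pass_offtarget: bool | None = None
    chemistry: str = "2'MOE/PS"  # inert metadata

    def __post_init__(self):
        n = len(self.target_seq)
        self.gc_fraction = (self.target_seq.count("G") + self.target_seq.count("C")) / n
        self.max_homopolymer_run = max_homopolymer_run(self.target_seq)

    @property
    def aso_seq_dna(self) -> str:
        return self.aso_seq.replace("U", "T")


def _make_candidate(premrna: str, start: int, length: int, alphabet: str, idx: int) -> AsoCandidate:
    target = premrna[start - 1:start - 1 + length]
    aso = reverse_complement(target)
    if alphabet == "RNA":
        aso = aso.replace("T", "U")
    return AsoCandidate(
        id=f"ASO_{idx:03d}",
        target_start=start,
        target_end=start + length - 1,
        target_seq=target,
        aso_seq=aso,
    )


def tile_candidates(
    target_premrna: str,
    window: tuple[int, int],
    config: DesignConfig | None = None,
) -> list[AsoCandidate]:
    """One candidate per start position across a window (1-based inclusive
    transcript-sense coordinates), ordered 5'->3'."""
    config = config or DesignConfig()
    lo, hi = window
    if lo < 1 or hi > len(target_premrna):
        raise ValueError(f"window {window} outside sequence of length {len(target_premrna)}")
    k = config.aso_length
    if hi - lo + 1 < k:
        raise ValueError(f"window length {hi - lo + 1} shorter than aso_length {k}")
    return [
        _make_candidate(target_premrna, s, k, config.alphabet, i + 1)
        for i, s in enumerate(range(lo, hi - k + 2, config.step))
    ]


def gc_filter(candidate: AsoCandidate, gc_min: float = 0.25, gc_max: float = 0.75) -> bool:
    """True iff GC fraction lies within [gc_min, gc_max] (bounds inclusive)."""
    return gc_min <= candidate.gc_fraction <= gc_max


def homopolymer_filter(candidate: AsoCandidate, max_run_allowed: int = 5) -> bool:
    """False iff any single-base run reaches max_run_allowed + 1 (default:
    reject runs of six or more)."""
    return candidate.max_homopolymer_run <= max_run_allowed


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def allele_specificity(
    candidate: AsoCandidate,
    ref_allele_window: str | None,
    alt_allele_window: str | None,
) -> tuple[int | None, int | None]:
    """Hamming mismatches of the candidate's target site against windows
    anchored at the same coordinates on each haplotype. A missing window
    (no anchored liftover across the delins breakpoint) yields None —
    the site is simply absent from that allele."""
    mm_ref = None if ref_allele_window is None else hamming(candidate.target_seq, ref_allele_window)
    mm_alt = None if alt_allele_window is None else hamming(candidate.target_seq, alt_allele_window)
    candidate.mismatches_vs_ref = mm_ref
    candidate.mismatches_vs_alt = mm_alt
    return mm_ref, mm_alt


def design_candidates(locus: LocusModel, config: DesignConfig | None = None) -> list[AsoCandidate]:
    """Tile and annotate candidates against the variant pre-mRNA.

    The design template is the transcript-sense pre-mRNA of the variant
    haplotype; ``config.target_allele='reported'`` swaps in the allele as
    first reported (one substitution off the corrected one), reproducing
    the two historical design rounds. GC and homopolymer flags are set;
    the off-target flag is left to the off-target stage.
    """
    config = config or DesignConfig()
    premrna_alt = reverse_complement(locus.sequence_alt)  # transcript sense
    d0 = premrna_alt.find(ALT_TS)
    if d0 < 0:
        raise ValueError("variant pre-mRNA does not contain the inserted allele")
    template = premrna_alt
    if config.target_allele == "reported":
        template = premrna_alt[:d0] + REPORTED_ALT_TS + premrna_alt[d0 + len(ALT_TS):]

    ins_lo, ins_hi = d0 + 1, d0 + len(ALT_TS)  # 1-based inserted-run interval
    window = (max(1, ins_lo - config.window_flank),
              min(len(template), ins_hi + config.window_flank))
    candidates = tile_candidates(template, window, config)

    premrna_ref = reverse_complement(locus.sequence_ref)
    shift = len(ALT_TS) - len(REF_TS)
    for c in candidates:
        # anchored ref window exists only when the site avoids the inserted run
        if c.target_end < ins_lo:
            ref_win = premrna_ref[c.target_start - 1:c.target_end]
        elif c.target_start > ins_hi:
            ref_win = premrna_ref[c.target_start - 1 - shift:c.target_end - shift]
        else:
            ref_win = None
        alt_win = premrna_alt[c.target_start - 1:c.target_end]
        allele_specificity(c, ref_win, alt_win)
        c.pass_gc = gc_filter(c, config.gc_min, config.gc_max)
        c.pass_homopolymer = homopolymer_filter(c, config.max_run_allowed)
    return candidates


def design_report(
    candidates: list[AsoCandidate],
    offtarget_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """All candidates with metrics, per-filter flags, failure reasons and the
    overall pass (AND of the three filters), in stable positional order."""
    rows = []
    for c in sorted(candidates, key=lambda c: c.target_start):
        if offtarget_counts is not None and c.id in offtarget_counts:
            c.pass_offtarget = offtarget_counts[c.id] == 0
        flags = {"gc": c.pass_gc, "homopolymer": c.pass_homopolymer, "offtarget": c.pass_offtarget}
        known = {k: v for k, v in flags.items() if v is not None}
        overall = all(known.values()) if known else None
        reasons = ",".join(k for k, v in known.items() if not v)
        rows.append({
            "id": c.id,
            "target_start": c.target_start,
            "target_end": c.target_end,
            "target_seq": c.target_seq,
            "aso_seq": c.aso_seq,
            "gc_fraction": c.gc_fraction,
            "max_homopolymer_run": c.max_homopolymer_run,
            "mismatches_vs_alt": c.mismatches_vs_alt,
            "mismatches_vs_ref": c.mismatches_vs_ref,
            "offtarget_count": (offtarget_counts or {}).get(c.id),
            "pass_gc": c.pass_gc,
            "pass_homopolymer": c.pass_homopolymer,
            "pass_offtarget": c.pass_offtarget,
            "overall_pass": overall,
            "fail_reasons": reasons,
        })
    return pd.DataFrame(rows)
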