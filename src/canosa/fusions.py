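"""Deterministic rule engine for gene-fusion candidate triage.

Candidates need >= 5 split or paired supporting reads to be considered, and
fail review if: either partner lies on an unplaced scaffold; both partners
belong to the same gene family (explicit family tags, or as a fallback the
same symbol stem after stripping trailing digits); the partners are adjacent
same-strand genes (read-through transcript); no structural-variant
breakpoint pair explains the junction; or the partner transcript sequences
share a strong local alignment (homology artifact).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .genomic_io import GeneModel, normalize_chrom

__all__ = [
    "FusionCandidate",
    "TriageParams",
    "TriageVerdict",
    "SvBreakpointPair",
    "triage",
    "batch_triage",
]

ALL_RULES = frozenset(
    {"low_support", "scaffold", "same_family", "read_through", "no_sv_support", "homology"}
)


@dataclass(frozen=True)
class FusionCandidate:
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: int  # 1-based junction coordinate on gene A's side
    chrom_b: str
    pos_b: int
    split_reads: int = 0
    paired_reads: int = 0

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.paired_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.gene_a == self.gene_b:
            raise ValueError("fusion partners must be distinct genes")

    @property
    def support(self) -> int:
        return self.split_reads + self.paired_reads


@dataclass(frozen=True)
class SvBreakpointPair:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass
class TriageParams:
    min_support: int = 5
    sv_window: int = 100_000
    min_identity: float = 0.80
    min_len: int = 50
    readthrough_max_dist: int = 500_000
    enabled_rules: frozenset[str] = ALL_RULES


@dataclass
class TriageVerdict:
    candidate: FusionCandidate
    reasons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.reasons - ALL_RULES
        if unknown:
            raise ValueError(f"unknown failure reasons: {unknown}")

    @property
    def passed(self) -> bool:
        return not self.reasons


_TRAILING_DIGITS = re.compile(r"\d+$")


def _family_of(gene: GeneModel | None, symbol: str) -> str:
    if gene is not None and gene.family:
        return gene.family
    # heuristic fallback: paralog numbering shares a symbol stem
    return _TRAILING_DIGITS.sub("", symbol)


def _adjacent_same_strand(
    a: GeneModel, b: GeneModel, genes_by_chrom: Mapping[str, list[GeneModel]], max_dist: int
) -> bool:
    if a.interval.chrom != b.interval.chrom or a.strand != b.strand:
        return False
    ordered = genes_by_chrom[a.interval.chrom]
    ia = ordered.index(a)
    ib = ordered.index(b)
    if abs(ia - ib) != 1:
        return False
    gap = max(
        0,
        max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end),
    )
    return gap <= max_dist


def _has_local_homology(
    seq_a: str, seq_b: str, min_identity: float, min_len: int
) -> bool:
    """Local alignment (match 1, mismatch -1, gap -2) with identity and
    length floors; the in-package analogue of a cross-partner read BLAST."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:
        alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    except (IndexError, ValueError):
        return False
    aligned_a, aligned_b = alignment.aligned
    length = sum(int(end - start) for start, end in aligned_a)
    if length < min_len:
        return False
    matches = sum(
        1
        for (sa, ea), (sb, _) in zip(aligned_a, aligned_b)
        for offset in range(int(ea - sa))
        if seq_a[int(sa) + offset].upper() == seq_b[int(sb) + offset].upper()
    )
    return matches / length >= min_identity


def triage(
    candidate: FusionCandidate,
    genes: Mapping[str, GeneModel],
    sv_calls: Sequence[SvBreakpointPair] = (),
    sequences: Mapping[str, str] | None = None,
    params: TriageParams | None = None,
) -> TriageVerdict:
    """Evaluate every enabled failure rule; a candidate passes iff no rule fires."""
    params = params or TriageParams()
    enabled = params.enabled_rules
    reasons: set[str] = set()

    if "low_support" in enabled and candidate.support < params.min_support:
        reasons.add("low_support")

    if "scaffold" in enabled:
        for chrom in (candidate.chrom_a, candidate.chrom_b):
            if not normalize_chrom(chrom)[1]:
                reasons.add("scaffold")

    gene_a = genes.get(candidate.gene_a)
    gene_b = genes.get(candidate.gene_b)

    if "same_family" in enabled:
        fam_a = _family_of(gene_a, candidate.gene_a)
        fam_b = _family_of(gene_b, candidate.gene_b)
        if fam_a and fam_a == fam_b:
            reasons.add("same_family")

    if "read_through" in enabled and gene_a is not None and gene_b is not None:
        genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes.values():
            genes_by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom_genes in genes_by_chrom.values():
            chrom_genes.sort(key=lambda g: g.interval.start)
        if _adjacent_same_strand(
            gene_a, gene_b, genes_by_chrom, params.readthrough_max_dist
        ):
            reasons.add("read_through")

    if "no_sv_support" in enabled:
        supported = any(
            (
                sv.chrom_a == candidate.chrom_a
                and abs(sv.pos_a - candidate.pos_a) <= params.sv_window
                and sv.chrom_b == candidate.chrom_b
                and abs(sv.pos_b - candidate.pos_b) <= params.sv_window
            )
            or (
                sv.chrom_a == candidate.chrom_b
                and abs(sv.pos_a - candidate.pos_b) <= params.sv_window
                and sv.chrom_b == candidate.chrom_a
                and abs(sv.pos_b - candidate.pos_a) <= params.sv_window
            )
            for sv in sv_calls
        )
        if not supported:
            reasons.add("no_sv_support")

    if (
        "homology" in enabled
        and sequences is not None
        and candidate.gene_a in sequences
        and candidate.gene_b in sequences
    ):
        if _has_local_homology(
            sequences[candidate.gene_a],
            sequences[candidate.gene_b],
            params.min_identity,
            params.min_len,
        ):
            reasons.add("homology")

    return TriageVerdict(candidate=candidate, reasons=reasons)


def batch_triage(
    candidates: Sequence[FusionCandidate],
    genes: Mapping[str, GeneModel],
    sv_calls: Sequence[SvBreakpointPair] = (),
    sequences: Mapping[str, str] | None = None,
    params: TriageParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Triage a candidate table; returns per-candidate verdicts and summary
    counts per failure reason. Verdicts are independent of input order."""
    verdicts = [
        triage(c, genes, sv_calls, sequences, params) for c in candidates
    ]
    rows = [
        {
            "gene_a": v.candidate.gene_a,
            "gene_b": v.candidate.gene_b,
            "support": v.candidate.support,
            "passed": v.passed,
            "reasons": ",".join(sorted(v.reasons)),
        }
        for v in verdicts
    ]
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "support", "passed", "reasons"])
    counts: dict[str, int] = {rule: 0 for rule in sorted(ALL_RULES)}
    for v in verdicts:
        for reason in v.reasons:
            counts[reason] += 1
    return table, counts
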