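"""Data model, coordinate conventions, and readers/writers for the pipeline's formats.

Conventions
-----------
* Internal intervals are 0-based half-open (:class:`GenomicInterval`).
* VCF and readcount files are 1-based at the boundary; BED is 0-based half-open.
* Chromosome labels are canonicalised to the bare form without a ``chr`` prefix;
  for the canine genome the canonical set is ``{1..38, X}``.
"""

from __future__ import annotations

import math
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "CANINE_CANONICAL",
    "FormatError",
    "GenomeBuild",
    "GenomicInterval",
    "SiteReadcount",
    "SampleSupport",
    "VariantRecord",
    "Segment",
    "GeneModel",
    "normalize_chrom",
    "chrom_sort_key",
    "read_readcounts",
    "write_readcounts",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_segments_bed",
    "write_segments_bed",
    "read_genes_bed",
    "write_genes_bed",
    "overlap_length",
    "subtract_intervals",
]

#: Canonical chromosome labels for the canine genome: autosomes 1-38 plus X.
CANINE_CANONICAL = frozenset(str(i) for i in range(1, 39)) | {"X"}

ROLES = ("normal", "primary", "metastasis")
PLATFORMS = ("WGS", "WES", "RNA")


class FormatError(ValueError):
    """A malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeBuild:
    """Chromosome names/lengths plus optional genome trinucleotide composition.

    ``trinucleotide_freqs`` maps the 32 pyrimidine-centred trinucleotide
    contexts (e.g. ``"ACA"``) to their genome-wide fraction; it is the
    composition used to renormalise mutation spectra.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    trinucleotide_freqs: dict[str, float] | None = None
    canonical: frozenset[str] = CANINE_CANONICAL

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome labels must be unique")
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} must have positive length")
        if self.trinucleotide_freqs is not None:
            total = sum(self.trinucleotide_freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"trinucleotide_freqs sum to {total}, expected 1")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)


@dataclass
class SiteReadcount:
    """Per-sample allele depths at one 1-based position (bam-readcount style)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    depth: int
    allele_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative depth")
        if sum(self.allele_counts.values()) > self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: allele counts exceed depth {self.depth}"
            )

    def vaf(self, allele: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.allele_counts.get(allele, 0) / self.depth


@dataclass(frozen=True)
class SampleSupport:
    """Read support for one variant in one (sample role, platform) slot."""

    var_reads: int
    depth: int

    def __post_init__(self) -> None:
        if self.var_reads < 0 or self.depth < 0:
            raise ValueError("negative read counts")
        if self.var_reads > self.depth:
            raise ValueError(f"var_reads {self.var_reads} > depth {self.depth}")

    @property
    def vaf(self) -> float:
        return self.var_reads / self.depth if self.depth > 0 else 0.0


@dataclass
class VariantRecord:
    """A somatic candidate with per-sample/per-platform support.

    ``support`` maps ``(role, platform)`` with role in {normal, primary,
    metastasis} and platform in {WGS, WES, RNA}.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    consequence: str = ""
    support: dict[tuple[str, str], SampleSupport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, platform in self.support:
            if role not in ROLES:
                raise ValueError(f"unknown sample role {role!r}")
            if platform not in PLATFORMS:
                raise ValueError(f"unknown platform {platform!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def vaf(self, role: str, platform: str) -> float | None:
        sup = self.support.get((role, platform))
        return None if sup is None else sup.vaf


@dataclass
class Segment:
    """A genomic interval carrying a copy number or a mean VAF deviation."""

    interval: GenomicInterval
    value: float
    n_markers: int
    kind: str  # "CN" or "LOH"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("CN", "LOH"):
            raise ValueError(f"segment kind must be CN or LOH, got {self.kind!r}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.kind == "CN" and self.value < 0:
            raise ValueError("copy number must be >= 0")
        if self.kind == "LOH" and not (0.0 <= self.value <= 0.5 + 1e-9):
            raise ValueError(f"LOH deviation {self.value} outside [0, 0.5]")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    symbol: str
    interval: GenomicInterval
    strand: str = "+"
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# chromosome naming


def normalize_chrom(
    label: str, canonical: frozenset[str] = CANINE_CANONICAL
) -> tuple[str, bool]:
    """Return ``(canonical_label, is_canonical)``.

    ``"chr5"`` and ``"5"`` both map to ``"5"``; ``"x"`` maps to ``"X"``.
    Unplaced scaffolds are returned unchanged and flagged non-canonical.
    """
    stripped = label[3:] if label.lower().startswith("chr") else label
    if stripped.upper() in canonical:
        return stripped.upper(), True
    if stripped in canonical:
        return stripped, True
    return label, False


def chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Sort autosomes numerically, then X, then other labels alphabetically."""
    name, canonical = normalize_chrom(label)
    if canonical and name.isdigit():
        return (0, int(name), "")
    if canonical:
        return (1, 0, name)
    return (2, 0, name)


# ---------------------------------------------------------------------------
# readcount TSV (bam-readcount style)


def read_readcounts(path: str | Path) -> list[SiteReadcount]:
    """Read a bam-readcount-style TSV: chrom, pos (1-based), ref, depth, base:count...

    Raises :class:`FormatError` naming the offending line for malformed rows.
    """
    records: list[SiteReadcount] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 columns "
                    "(chrom, pos, ref, depth), got "
                    f"{len(fields)}"
                )
            chrom, pos_s, ref, depth_s = fields[:4]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer pos/depth") from exc
            counts: dict[str, int] = {}
            for token in fields[4:]:
                if not token:
                    continue
                parts = token.split(":")
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: malformed allele count {token!r}"
                    )
                try:
                    counts[parts[0]] = int(parts[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: malformed allele count {token!r}"
                    ) from exc
            try:
                records.append(
                    SiteReadcount(
                        chrom=chrom, pos=pos, ref=ref, depth=depth, allele_counts=counts
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_readcounts(records: Iterable[SiteReadcount], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            counts = "\t".join(
                f"{base}:{n}" for base, n in sorted(rec.allele_counts.items())
            )
            handle.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.depth}\t{counts}\n")


# ---------------------------------------------------------------------------
# VCF

_VCF_SAMPLES = [f"{role}.{platform}" for role in ROLES for platform in PLATFORMS]


def _vcf_header(contigs: Mapping[str, int], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence string (percent-encoded)")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total depth")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_variants_vcf(
    variants: Sequence[VariantRecord],
    path: str | Path,
    genome: GenomeBuild | None = None,
) -> None:
    """Write variants as an uncompressed VCF, one sample column per
    ``role.platform`` slot that occurs anywhere in the call set."""
    samples = [
        s
        for s in _VCF_SAMPLES
        if any(tuple(s.split(".")) in v.support for v in variants)
    ] or ["primary.WGS"]
    if genome is not None:
        contigs = {c: genome.chrom_lengths[c] for c in genome.chrom_names}
    else:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + 1000)
    header = _vcf_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda r: (chrom_sort_key(r.chrom), r.pos)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            if v.consequence:
                rec.info["CSQ"] = urllib.parse.quote(v.consequence, safe="")
            for sample in samples:
                role, platform = sample.split(".")
                sup = v.support.get((role, platform))
                if sup is None:
                    rec.samples[sample]["AD"] = (None, None)
                else:
                    rec.samples[sample]["AD"] = (sup.depth - sup.var_reads, sup.var_reads)
                    rec.samples[sample]["DP"] = sup.depth
            out.write(rec)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alt allele. Sample
    columns must be named ``role.platform``; AD (ref, alt...) and DP carry the
    support counts.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        parsed_samples: list[tuple[str, str, str]] = []
        for sample in vcf.header.samples:
            role, _, platform = sample.rpartition(".")
            if role not in ROLES or platform not in PLATFORMS:
                raise FormatError(
                    f"{path}: sample {sample!r} is not of the form role.platform "
                    f"with role in {ROLES} and platform in {PLATFORMS}"
                )
            parsed_samples.append((sample, role, platform))
        for rec in vcf:
            gene = rec.info.get("GENE")
            csq = rec.info.get("CSQ")
            consequence = urllib.parse.unquote(csq) if csq else ""
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                support: dict[tuple[str, str], SampleSupport] = {}
                for sample, role, platform in parsed_samples:
                    fmt = rec.samples[sample]
                    ad = fmt.get("AD")
                    if ad is None or ad[0] is None:
                        continue
                    var_reads = int(ad[alt_index + 1] or 0)
                    dp = fmt.get("DP")
                    depth = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                    support[(role, platform)] = SampleSupport(var_reads, depth)
                records.append(
                    VariantRecord(
                        chrom=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        consequence=consequence,
                        support=support,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# segment BED


def write_segments_bed(segments: Sequence[Segment], path: str | Path) -> None:
    """Write segments as BED (0-based half-open): chrom, start, end, label,
    value, n_markers. Output is sorted; overlapping segments of the same kind
    on one chromosome are an error."""
    ordered = sorted(
        segments, key=lambda s: (chrom_sort_key(s.interval.chrom), s.interval.start)
    )
    for prev, cur in zip(ordered, ordered[1:]):
        if (
            prev.kind == cur.kind
            and prev.interval.chrom == cur.interval.chrom
            and cur.interval.start < prev.interval.end
        ):
            raise ValueError(
                f"overlapping {cur.kind} segments on {cur.interval.chrom}: "
                f"{prev.interval.start}-{prev.interval.end} and "
                f"{cur.interval.start}-{cur.interval.end}"
            )
    with open(path, "w") as handle:
        for seg in ordered:
            name = seg.label if seg.label else "."
            handle.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                f"\t{name}\t{seg.value:g}\t{seg.n_markers}\n"
            )


def read_segments_bed(path: str | Path, kind: str) -> list[Segment]:
    segments: list[Segment] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, value, n_markers = fields[:6]
            segments.append(
                Segment(
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    value=float(value),
                    n_markers=int(n_markers),
                    kind=kind,
                    label=None if name == "." else name,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# gene model BED


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Gene model BED: chrom, start, end, symbol, score, strand[, family]."""
    genes: list[GeneModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, symbol = fields[:4]
            strand = fields[5] if len(fields) > 5 and fields[5] else "."
            family = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
            genes.append(
                GeneModel(
                    symbol=symbol,
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    strand=strand,
                    family=family,
                )
            )
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    ordered = sorted(genes, key=lambda g: (chrom_sort_key(g.interval.chrom), g.interval.start))
    with open(path, "w") as handle:
        for g in ordered:
            family = g.family if g.family else "."
            handle.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.symbol}\t0\t{g.strand}\t{family}\n"
            )


# ---------------------------------------------------------------------------
# interval arithmetic helpers


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def subtract_intervals(
    interval: GenomicInterval, cuts: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove ``cuts`` from ``interval``, returning the remaining pieces."""
    pieces = [interval]
    for cut in cuts:
        if cut.chrom != interval.chrom:
            continue
        next_pieces: list[GenomicInterval] = []
        for piece in pieces:
            if cut.end <= piece.start or cut.start >= piece.end:
                next_pieces.append(piece)
                continue
            if piece.start < cut.start:
                next_pieces.append(GenomicInterval(piece.chrom, piece.start, cut.start))
            if cut.end < piece.end:
                next_pieces.append(GenomicInterval(piece.chrom, cut.end, piece.end))
        pieces = next_pieces
    return pieces
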