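"""Synthetic tumor/normal datasets with planted ground truth.

The generator emulates the statistical structure the analysis stages assume:
diploid chromosomes carrying germline heterozygous SNPs, somatic SNVs
organized into clones with set cell fractions, copy-number segments, a
copy-number-neutral LOH block containing a biallelic truncal variant (the
purity proxy), optional kataegis clusters, and substitution contexts drawn
from a signature mixture applied to the generated reference sequence.

Read counts follow a Poisson-depth x binomial-allele-sampling noise model.
The expected variant allele fraction at a site with tumor allele dosage
``m`` out of ``C`` total tumor copies, at purity ``p``, is::

    VAF = (p*m + (1-p)*m_normal) / (p*C + 2*(1-p))

with ``m_normal`` = 1 for germline hets and 0 for somatic variants. A
biallelic truncal variant in a copy-neutral LOH region (m=2, C=2) therefore
has expected VAF equal to the purity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import signatures as sigs
from .genomic_io import (
    GenomeBuild,
    GenomicInterval,
    SampleSupport,
    SiteReadcount,
    VariantRecord,
    write_segments_bed,
    Segment,
)

__all__ = [
    "CnaSpec",
    "LohSpec",
    "CloneSpec",
    "KataegisSpec",
    "Scenario",
    "GermlineHet",
    "SomaticVariant",
    "TruthSet",
    "simulate_reference",
    "trinucleotide_frequencies",
    "plant_truth",
    "haplotype_copies",
    "expected_het_vaf",
    "expected_somatic_vaf",
    "simulate_readcounts",
    "simulate_callset",
    "simulate_coverage_windows",
    "export_truth",
    "load_truth",
]

LOH_CLASSES = ("deletion-LOH", "CN-neutral-LOH", "gain-LOH")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass(frozen=True)
class CnaSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copies: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class LohSpec:
    chrom: str
    start: int
    end: int
    loh_class: str

    def __post_init__(self) -> None:
        if self.loh_class not in LOH_CLASSES:
            raise ValueError(f"unknown LOH class {self.loh_class!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class CloneSpec:
    """A somatic clone: cell fractions per lesion and its private variant count."""

    name: str
    fraction_primary: float
    fraction_metastasis: float
    n_variants: int

    def __post_init__(self) -> None:
        for f in (self.fraction_primary, self.fraction_metastasis):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"clone fraction {f} outside [0, 1]")

    def fraction(self, role: str) -> float:
        if role == "primary":
            return self.fraction_primary
        if role == "metastasis":
            return self.fraction_metastasis
        raise ValueError(f"no clone fraction for role {role!r}")


@dataclass(frozen=True)
class KataegisSpec:
    chrom: str
    start: int  # 1-based anchor position
    n: int


@dataclass
class Scenario:
    """Study conditions for one synthetic tumor/normal dataset.

    Defaults mirror the study design qualitatively: a 3 x 10 Mb genome at
    GC 0.41, purity 0.8, WGS coverage 60x / WES 120x, one truncal clone fully
    shared between lesions, one small primary-private clone and three
    metastasis-private clones (17 primary vs 26 metastatic variants, 15
    shared), ~20% of the genome aneuploid with more loss than gain, one
    copy-neutral LOH block holding the biallelic truncal variant, a
    signature mixture dominated by the aging-like component, and no kataegis.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000}
    )
    gc: float = 0.41
    purity: float = 0.8
    coverage: float = 60.0
    wes_coverage: float = 120.0
    rna_coverage: float = 0.0
    het_density: float = 1.0 / 2000.0
    error_rate: float = 0.0
    window_size: int = 10_000
    clones: list[CloneSpec] = field(
        default_factory=lambda: [
            CloneSpec("truncal", 1.0, 1.0, 15),
            CloneSpec("primary-A", 0.25, 0.0, 2),
            CloneSpec("met-A", 0.0, 0.55, 4),
            CloneSpec("met-B", 0.0, 0.30, 4),
            CloneSpec("met-C", 0.0, 0.15, 3),
        ]
    )
    cna: list[CnaSpec] = field(
        default_factory=lambda: [
            CnaSpec("2", 0, 3_500_000, 1),
            CnaSpec("2", 8_000_000, 9_000_000, 1),
            CnaSpec("3", 6_000_000, 7_600_000, 3),
            CnaSpec("3", 9_000_000, 9_100_000, 6),
        ]
    )
    loh: list[LohSpec] = field(
        default_factory=lambda: [
            LohSpec("1", 3_000_000, 6_000_000, "CN-neutral-LOH"),
            LohSpec("2", 0, 3_500_000, "deletion-LOH"),
        ]
    )
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.7, "S2": 0.2, "S3": 0.1}
    )
    kataegis: list[KataegisSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        total = sum(self.signature_mix.values())
        if self.signature_mix and not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"signature mixture sums to {total}, expected 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clones"] = [dataclasses.asdict(c) for c in self.clones]
        d["cna"] = [dataclasses.asdict(c) for c in self.cna]
        d["loh"] = [dataclasses.asdict(s) for s in self.loh]
        d["kataegis"] = [dataclasses.asdict(k) for k in self.kataegis]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        if "clones" in d:
            d["clones"] = [CloneSpec(**c) for c in d["clones"]]
        if "cna" in d:
            d["cna"] = [CnaSpec(**c) for c in d["cna"]]
        if "loh" in d:
            d["loh"] = [LohSpec(**s) for s in d["loh"]]
        if "kataegis" in d:
            d["kataegis"] = [KataegisSpec(**k) for k in d["kataegis"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# truth containers


@dataclass(frozen=True)
class GermlineHet:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    hap: int  # haplotype carrying the alt allele; haplotype 1 is lost in LOH


@dataclass(frozen=True)
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    clone: str
    context96: str
    multiplicity: int = 1
    gene: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    """Planted ground truth: the recovery oracle for every downstream stage."""

    genome: GenomeBuild
    sequences: dict[str, str]
    scenario: Scenario
    germline_hets: list[GermlineHet]
    somatic: list[SomaticVariant]
    truncal_variant: tuple[str, int, str, str]
    kataegis_truth: list[GenomicInterval]
    seed: int

    @property
    def purity(self) -> float:
        return self.scenario.purity

    @property
    def cna_truth(self) -> list[CnaSpec]:
        return self.scenario.cna

    @property
    def loh_truth(self) -> list[LohSpec]:
        return self.scenario.loh

    @property
    def signature_mix(self) -> dict[str, float]:
        return self.scenario.signature_mix

    def clone(self, name: str) -> CloneSpec:
        for c in self.scenario.clones:
            if c.name == name:
                return c
        raise KeyError(name)


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(
    chrom_lengths: Mapping[str, int],
    gc: float = 0.41,
    seed: int = 0,
) -> tuple[GenomeBuild, dict[str, str]]:
    """Generate an iid random reference with the requested GC content.

    Deterministic for a seed; base composition is non-uniform so the
    trinucleotide frequencies carried by the returned build are informative.
    """
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has zero length")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cuts = np.cumsum(probs)[:3]
    sequences: dict[str, str] = {}
    trimer_totals = np.zeros(64)
    for name in chrom_lengths:
        r = rng.random(chrom_lengths[name])
        codes = (
            (r > cuts[0]).view(np.uint8)
            + (r > cuts[1]).view(np.uint8)
            + (r > cuts[2]).view(np.uint8)
        ).astype(np.int32)
        sequences[name] = _BASES[codes].tobytes().decode()
        if codes.size >= 3:
            trimers = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
            trimer_totals += np.bincount(trimers, minlength=64)
    build = GenomeBuild(
        chrom_names=list(chrom_lengths),
        chrom_lengths=dict(chrom_lengths),
        trinucleotide_freqs=_fold_trimer_counts(trimer_totals),
    )
    return build, sequences


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(raw.size, dtype=np.int64)
    code[raw == ord("C")] = 1
    code[raw == ord("G")] = 2
    code[raw == ord("T")] = 3
    return code


def trinucleotide_frequencies(sequences: Mapping[str, str]) -> dict[str, float]:
    """Pyrimidine-centred trinucleotide fractions of a genome (32 contexts)."""
    totals = np.zeros(64)
    for seq in sequences.values():
        code = _encode(seq)
        if code.size < 3:
            continue
        trimers = code[:-2] * 16 + code[1:-1] * 4 + code[2:]
        totals += np.bincount(trimers, minlength=64)
    return _fold_trimer_counts(totals)


def _fold_trimer_counts(totals: np.ndarray) -> dict[str, float]:
    """Fold 64 trimer counts onto the 32 pyrimidine-centred contexts."""
    freqs: dict[str, float] = {ctx: 0.0 for ctx in sigs.CONTEXTS_32}
    bases = "ACGT"
    for code_val in range(64):
        tri = bases[code_val // 16] + bases[(code_val // 4) % 4] + bases[code_val % 4]
        folded = tri if tri[1] in "CT" else sigs.revcomp(tri)
        freqs[folded] += totals[code_val]
    total = sum(freqs.values())
    return {ctx: v / total for ctx, v in freqs.items()}


# ---------------------------------------------------------------------------
# truth planting


def _in_any(chrom: str, pos: int, regions: Sequence) -> bool:
    return any(
        r.chrom == chrom and r.start < pos <= r.end for r in regions
    )  # pos 1-based vs half-open 0-based: inside iff start < pos <= end


def plant_truth(
    genome: GenomeBuild,
    sequences: Mapping[str, str],
    scenario: Scenario,
    seed: int,
    signature_matrix: pd.DataFrame | None = None,
) -> TruthSet:
    """Plant germline hets, clonal somatic SNVs, CNA/LOH truth, the biallelic
    truncal variant, and optional kataegis clusters."""
    _validate_scenario(scenario)
    rng = np.random.default_rng(seed)
    if signature_matrix is None:
        signature_matrix = sigs.synthetic_signatures()

    # germline hets: Poisson process at the configured density
    hets: list[GermlineHet] = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        n = rng.poisson(length * scenario.het_density)
        n = min(n, length - 2)
        positions = np.sort(
            rng.choice(np.arange(2, length), size=n, replace=False)
        )  # 1-based, avoiding chromosome edges
        haps = rng.integers(0, 2, size=n)
        seq = sequences[chrom]
        for pos, hap in zip(positions, haps):
            ref = seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + rng.integers(1, 4)) % 4]
            hets.append(GermlineHet(chrom, int(pos), ref, alt, int(hap)))

    used: set[tuple[str, int]] = {(h.chrom, h.pos) for h in hets}
    avoid = list(scenario.cna) + list(scenario.loh)

    probs96 = sigs.mixture_context_probs(scenario.signature_mix, signature_matrix)
    chrom_names = list(genome.chrom_names)
    chrom_weights = np.array([genome.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()

    def sample_site(target_ctx: str) -> tuple[str, int, str, str]:
        """Rejection-sample a genomic position whose folded trinucleotide
        matches the target 96-class; returns (chrom, pos, ref, alt)."""
        want_tri = f"{target_ctx[0]}{target_ctx[2]}{target_ctx[6]}"
        want_alt = target_ctx[4]
        for _ in range(200_000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
            pos = int(rng.integers(2, genome.chrom_lengths[chrom]))
            if (chrom, pos) in used or _in_any(chrom, pos, avoid):
                continue
            triplet = sequences[chrom][pos - 2 : pos + 1]
            if triplet[1] in "CT":
                folded, alt = triplet, want_alt
            else:
                folded, alt = sigs.revcomp(triplet), sigs.revcomp(want_alt)
            if folded == want_tri:
                used.add((chrom, pos))
                return chrom, pos, triplet[1], alt
        raise RuntimeError(f"could not place a variant with context {target_ctx}")

    somatic: list[SomaticVariant] = []
    for clone in scenario.clones:
        classes = rng.choice(96, size=clone.n_variants, p=probs96)
        for cls in classes:
            label = sigs.CONTEXTS_96[cls]
            chrom, pos, ref, alt = sample_site(label)
            somatic.append(
                SomaticVariant(chrom, pos, ref, alt, clone.name, label)
            )

    # the biallelic truncal variant inside the first copy-neutral LOH block
    cn_loh = [s for s in scenario.loh if s.loh_class == "CN-neutral-LOH"]
    if not cn_loh:
        raise ValueError("scenario must contain a CN-neutral-LOH segment")
    block = cn_loh[0]
    seq = sequences[block.chrom]
    for _ in range(200_000):
        pos = int(rng.integers(max(2, block.start + 1), block.end))
        if (block.chrom, pos) not in used:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not place the truncal variant")
    used.add((block.chrom, pos))
    ref = seq[pos - 1]
    alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
    label = sigs.context_label(seq[pos - 2 : pos + 1], alt)
    truncal = SomaticVariant(
        block.chrom, pos, ref, alt, "truncal", label, multiplicity=2, gene="TP53"
    )
    somatic.append(truncal)

    # optional kataegis clusters: runs of closely spaced TpC C>T / C>G changes
    kataegis_truth: list[GenomicInterval] = []
    for spec in scenario.kataegis:
        seq = sequences[spec.chrom]
        positions: list[int] = []
        cursor = spec.start
        while len(positions) < spec.n and cursor < len(seq) - 1:
            # next plus-strand TpC site at or after the cursor
            if seq[cursor - 1] == "C" and seq[cursor - 2] == "T" and (
                (spec.chrom, cursor) not in used
            ):
                positions.append(cursor)
                used.add((spec.chrom, cursor))
                cursor += int(rng.integers(50, 500))
            else:
                cursor += 1
        if len(positions) < spec.n:
            raise ValueError(
                f"could not place {spec.n} kataegis variants on {spec.chrom}"
            )
        for pos in positions:
            alt = "T" if rng.random() < 0.5 else "G"
            label = sigs.context_label(seq[pos - 2 : pos + 1], alt)
            somatic.append(
                SomaticVariant(spec.chrom, pos, "C", alt, "truncal", label)
            )
        kataegis_truth.append(
            GenomicInterval(spec.chrom, positions[0] - 1, positions[-1])
        )

    return TruthSet(
        genome=genome if genome.trinucleotide_freqs else dataclasses.replace(
            genome, trinucleotide_freqs=trinucleotide_frequencies(sequences)
        ),
        sequences=dict(sequences),
        scenario=scenario,
        germline_hets=hets,
        somatic=somatic,
        truncal_variant=truncal.key,
        kataegis_truth=kataegis_truth,
        seed=seed,
    )


def _validate_scenario(scenario: Scenario) -> None:
    by_chrom: dict[str, list[CnaSpec]] = {}
    for cna in scenario.cna:
        by_chrom.setdefault(cna.chrom, []).append(cna)
    for chrom, specs in by_chrom.items():
        ordered = sorted(specs, key=lambda c: c.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end and a.copies != b.copies:
                raise ValueError(
                    f"contradictory CNA truth on {chrom}: "
                    f"{a.start}-{a.end} ({a.copies} copies) overlaps "
                    f"{b.start}-{b.end} ({b.copies} copies)"
                )
    for loh in scenario.loh:
        copies = _mean_copies(scenario.cna, loh.interval)
        if loh.loh_class == "CN-neutral-LOH" and not (1.5 <= copies <= 2.5):
            raise ValueError(
                f"CN-neutral-LOH at {loh.chrom}:{loh.start}-{loh.end} sits on "
                f"{copies:.2f} copies"
            )
        if loh.loh_class == "deletion-LOH" and copies >= 1.5:
            raise ValueError(
                f"deletion-LOH at {loh.chrom}:{loh.start}-{loh.end} sits on "
                f"{copies:.2f} copies"
            )
        if loh.loh_class == "gain-LOH" and copies <= 2.5:
            raise ValueError(
                f"gain-LOH at {loh.chrom}:{loh.start}-{loh.end} sits on "
                f"{copies:.2f} copies"
            )


def _mean_copies(cna: Sequence[CnaSpec], interval: GenomicInterval) -> float:
    total = len(interval) * 2.0
    for spec in cna:
        if spec.chrom != interval.chrom:
            continue
        ov = max(0, min(spec.end, interval.end) - max(spec.start, interval.start))
        total += ov * (spec.copies - 2)
    return total / len(interval)


# ---------------------------------------------------------------------------
# allele dosage


def haplotype_copies(
    truth: TruthSet, chrom: str, pos: int
) -> tuple[int, int, int]:
    """Tumor copy state at a 1-based position: (total, hap0 copies, hap1 copies).

    Convention: losses remove haplotype 1 first; gains (and the duplication in
    copy-neutral LOH) amplify haplotype 0.
    """
    copies = 2
    for spec in truth.scenario.cna:
        if spec.chrom == chrom and spec.start < pos <= spec.end:
            copies = spec.copies
            break
    loh = None
    for spec in truth.scenario.loh:
        if spec.chrom == chrom and spec.start < pos <= spec.end:
            loh = spec
            break
    if loh is not None:
        return copies, copies, 0
    if copies >= 2:
        return copies, copies - 1, 1
    if copies == 1:
        return 1, 1, 0
    return 0, 0, 0


def expected_het_vaf(truth: TruthSet, het: GermlineHet, role: str) -> float:
    """Expected tumor VAF of a germline het under the allele-dosage model."""
    if role == "normal":
        return 0.5
    p = truth.purity
    total, hap0, hap1 = haplotype_copies(truth, het.chrom, het.pos)
    m_tumor = hap0 if het.hap == 0 else hap1
    denom = p * total + 2 * (1 - p)
    if denom == 0:
        return 0.0
    return (p * m_tumor + (1 - p) * 1.0) / denom


def expected_somatic_vaf(truth: TruthSet, var: SomaticVariant, role: str) -> float:
    """Expected VAF of a somatic variant in a lesion (0 in the normal)."""
    if role == "normal":
        return 0.0
    p = truth.purity
    fraction = truth.clone(var.clone).fraction(role)
    total, _, _ = haplotype_copies(truth, var.chrom, var.pos)
    denom = p * total + 2 * (1 - p)
    if denom == 0:
        return 0.0
    return (p * fraction * var.multiplicity) / denom


# ---------------------------------------------------------------------------
# read-count and call-set simulation


def _draw_site(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    coverage: float,
    vaf: float,
    error_rate: float,
) -> SiteReadcount:
    depth = int(rng.poisson(coverage))
    p = min(1.0, max(vaf, 0.0) + (error_rate if vaf == 0.0 else 0.0))
    var_reads = int(rng.binomial(depth, p)) if depth > 0 else 0
    return SiteReadcount(
        chrom=chrom,
        pos=pos,
        ref=ref,
        depth=depth,
        allele_counts={ref: depth - var_reads, alt: var_reads},
    )


def simulate_readcounts(
    truth: TruthSet,
    role: str,
    coverage: float | None = None,
    seed: int = 0,
) -> list[SiteReadcount]:
    """Per-site readcounts at every germline-het and somatic site for one sample.

    Depth is Poisson(coverage); variant reads are binomial at the expected
    allele-dosage VAF. Normal-sample somatic support is limited to the
    configured sequencing-error rate (default 0).
    """
    if role not in ("normal", "primary", "metastasis"):
        raise ValueError(f"unknown sample role {role!r}")
    if coverage is None:
        coverage = truth.scenario.coverage
    rng = np.random.default_rng(seed)
    err = truth.scenario.error_rate
    out: list[SiteReadcount] = []
    for het in truth.germline_hets:
        vaf = expected_het_vaf(truth, het, role)
        out.append(
            _draw_site(rng, het.chrom, het.pos, het.ref, het.alt, coverage, vaf, 0.0)
        )
    for var in truth.somatic:
        vaf = expected_somatic_vaf(truth, var, role)
        out.append(
            _draw_site(rng, var.chrom, var.pos, var.ref, var.alt, coverage, vaf, err)
        )
    out.sort(key=lambda r: (truth.genome.chrom_names.index(r.chrom), r.pos))
    return out


def simulate_callset(truth: TruthSet, seed: int = 0) -> list[VariantRecord]:
    """Somatic candidate records with per-role/per-platform support counts.

    Platforms covered: WGS at the scenario coverage, WES at the (deeper) WES
    coverage, and RNA when the scenario sets a nonzero RNA coverage.
    """
    rng = np.random.default_rng(seed)
    scen = truth.scenario
    platforms = [("WGS", scen.coverage), ("WES", scen.wes_coverage)]
    if scen.rna_coverage > 0:
        platforms.append(("RNA", scen.rna_coverage))
    records: list[VariantRecord] = []
    for var in truth.somatic:
        support: dict[tuple[str, str], SampleSupport] = {}
        for role in ("normal", "primary", "metastasis"):
            vaf = expected_somatic_vaf(truth, var, role)
            for platform, cov in platforms:
                depth = int(rng.poisson(cov))
                p = min(1.0, vaf + (scen.error_rate if vaf == 0.0 else 0.0))
                var_reads = int(rng.binomial(depth, p)) if depth > 0 else 0
                support[(role, platform)] = SampleSupport(var_reads, depth)
        records.append(
            VariantRecord(
                chrom=var.chrom,
                pos=var.pos,
                ref=var.ref,
                alt=var.alt,
                gene=var.gene,
                consequence="non_synonymous_coding",
                support=support,
            )
        )
    return records


def simulate_coverage_windows(
    truth: TruthSet,
    role: str,
    seed: int = 0,
    window: int | None = None,
) -> pd.DataFrame:
    """Mean-depth windows (fixed width) for the depth-ratio CN estimator.

    Expected tumor depth in a window scales with the purity-mixed copy
    number; realized depth is Poisson over the window's bases.
    """
    if role not in ("normal", "primary", "metastasis"):
        raise ValueError(f"unknown sample role {role!r}")
    if window is None:
        window = truth.scenario.window_size
    rng = np.random.default_rng(seed)
    scen = truth.scenario
    p = scen.purity
    rows = []
    for chrom in truth.genome.chrom_names:
        length = truth.genome.chrom_lengths[chrom]
        seq_code = _encode(truth.sequences[chrom])
        gc_mask = (seq_code == 1) | (seq_code == 2)
        for start in range(0, length, window):
            end = min(start + window, length)
            iv = GenomicInterval(chrom, start, end)
            if role == "normal":
                factor = 1.0
            else:
                factor = (p * _mean_copies(scen.cna, iv) + 2 * (1 - p)) / 2.0
            expected = scen.coverage * factor
            total_reads = rng.poisson(expected * (end - start))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gc": float(gc_mask[start:end].mean()),
                    "depth": total_reads / (end - start),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth export / reload


def export_truth(truth: TruthSet, outdir: str | Path) -> None:
    """Write machine-readable truth: BED files, a JSON document, and the
    reference as FASTA. Deterministic per (scenario, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cna_segments = [
        Segment(
            interval=c.interval, value=float(c.copies), n_markers=1, kind="CN"
        )
        for c in truth.cna_truth
    ]
    write_segments_bed(cna_segments, outdir / "truth_cna.bed")
    loh_segments = [
        Segment(
            interval=s.interval, value=0.0, n_markers=1, kind="LOH", label=s.loh_class
        )
        for s in truth.loh_truth
    ]
    write_segments_bed(loh_segments, outdir / "truth_loh.bed")
    with open(outdir / "truth_kataegis.bed", "w") as handle:
        for iv in truth.kataegis_truth:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    doc = {
        "seed": truth.seed,
        "scenario": truth.scenario.to_dict(),
        "genome": {
            "chrom_names": truth.genome.chrom_names,
            "chrom_lengths": truth.genome.chrom_lengths,
            "trinucleotide_freqs": truth.genome.trinucleotide_freqs,
        },
        "germline_hets": [dataclasses.asdict(h) for h in truth.germline_hets],
        "somatic": [dataclasses.asdict(v) for v in truth.somatic],
        "truncal_variant": list(truth.truncal_variant),
        "kataegis_truth": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
            for iv in truth.kataegis_truth
        ],
    }
    with open(outdir / "truth.json", "w") as handle:
        json.dump(doc, handle, indent=1)

    with open(outdir / "reference.fa", "w") as handle:
        for chrom in truth.genome.chrom_names:
            handle.write(f">{chrom}\n")
            seq = truth.sequences[chrom]
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def load_truth(outdir: str | Path) -> TruthSet:
    """Reload an exported truth set (inverse of :func:`export_truth`)."""
    outdir = Path(outdir)
    with open(outdir / "truth.json") as handle:
        doc = json.load(handle)
    sequences: dict[str, str] = {}
    current = None
    chunks: list[str] = []
    with open(outdir / "reference.fa") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current is not None:
                    sequences[current] = "".join(chunks)
                current = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if current is not None:
            sequences[current] = "".join(chunks)
    genome = GenomeBuild(
        chrom_names=doc["genome"]["chrom_names"],
        chrom_lengths={k: int(v) for k, v in doc["genome"]["chrom_lengths"].items()},
        trinucleotide_freqs=doc["genome"]["trinucleotide_freqs"],
    )
    return TruthSet(
        genome=genome,
        sequences=sequences,
        scenario=Scenario.from_dict(doc["scenario"]),
        germline_hets=[GermlineHet(**h) for h in doc["germline_hets"]],
        somatic=[SomaticVariant(**v) for v in doc["somatic"]],
        truncal_variant=tuple(doc["truncal_variant"]),
        kataegis_truth=[
            GenomicInterval(k["chrom"], k["start"], k["end"])
            for k in doc["kataegis_truth"]
        ],
        seed=doc["seed"],
    )


def sequence_digest(sequences: Mapping[str, str]) -> str:
    """Stable digest of a genome's sequences (determinism checks)."""
    h = hashlib.sha256()
    for chrom in sorted(sequences):
        h.update(chrom.encode())
        h.update(sequences[chrom].encode())
    return h.hexdigest()
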