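"""The multi-stage somatic variant filter cascade.

Stages, applied in order: caller-level read-support filtering (separate WES
and WGS rule sets), consequence whitelisting (exact string match against the
annotator's consequence list), population-database exclusion (allele-level),
ad-hoc cross-platform support filtering, and a clonal-analysis pre-filter
that additionally excludes LOH and copy-altered genomic space.

Every stage reports per-variant keep/remove decisions with reason codes.
Removal criteria within a stage are joined by OR: any triggered condition
removes the variant (a ``conjunctive_normal_rule`` switch restores the
reading in which high normal VAF and low normal coverage must co-occur).
Thresholds are stored as the printed removal bounds; comparisons are
inclusive of the printed value (e.g. "variant reads <= 4 removed" keeps 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .genomic_io import GenomicInterval, Segment, VariantRecord, normalize_chrom

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "StageCount",
    "FilterReport",
    "load_whitelist",
    "load_db_sites",
    "caller_level_filter",
    "consequence_filter",
    "population_db_filter",
    "adhoc_filter",
    "clonal_prefilter",
    "run_cascade",
]

TUMOR_ROLES = ("primary", "metastasis")
DNA_PLATFORMS = ("WGS", "WES")


def load_whitelist() -> frozenset[str]:
    """The verbatim consequence whitelist shipped with the package."""
    text = (
        resources.files("canosa.data").joinpath("consequence_whitelist.txt").read_text()
    )
    return frozenset(line for line in text.splitlines() if line)


@dataclass
class FilterConfig:
    """All cascade thresholds, defaulting to the published values.

    WES caller-level removal: tumor VAF <= 2.5%, tumor variant reads <= 4,
    tumor coverage <= 10, normal VAF >= 10%, normal coverage <= 10.
    WGS caller-level removal: tumor VAF <= 10%, tumor VAF <= 15% in every
    related tumor sample, tumor variant reads <= 10 (WGS) / <= 15 (WES),
    tumor or normal coverage <= 20x (WGS) / <= 40x (WES), normal VAF >= 1%
    or normal variant reads >= 2 in any WGS/WES sample.
    Ad-hoc retention: canonical chromosome, >= 7 variant reads and >= 4% VAF
    in WGS/WES/RNA of a lesion, <= 4 normal DNA reads.
    Clonal pre-filter: zero normal support, WES depth >= 80 in both lesions,
    >= 7 variant reads, and no LOH/copy-altered overlap.
    """

    # WES caller-level removal bounds
    wes_tumor_vaf_max: float = 0.025
    wes_tumor_var_reads_max: int = 4
    wes_tumor_cov_max: int = 10
    wes_normal_vaf_min: float = 0.10
    wes_normal_cov_max: int = 10
    conjunctive_normal_rule: bool = False

    # WGS caller-level removal bounds
    wgs_tumor_vaf_max: float = 0.10
    wgs_related_vaf_max: float = 0.15
    wgs_var_reads_max: dict[str, int] = field(
        default_factory=lambda: {"WGS": 10, "WES": 15}
    )
    wgs_cov_max: dict[str, int] = field(
        default_factory=lambda: {"WGS": 20, "WES": 40}
    )
    wgs_normal_vaf_min: float = 0.01
    wgs_normal_var_reads_min: int = 2

    # ad-hoc stage
    adhoc_var_reads_min: int = 7
    adhoc_vaf_min: float = 0.04
    adhoc_normal_reads_max: int = 4

    # clonal pre-filter
    prefilter_wes_depth_min: int = 80
    prefilter_var_reads_min: int = 7
    cn_neutral_window: tuple[float, float] = (1.5, 2.5)

    whitelist: frozenset[str] = field(default_factory=load_whitelist)

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("consequence whitelist must be non-empty")


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.keep and not self.reasons:
            raise ValueError("a removal must carry at least one reason")


@dataclass
class StageCount:
    name: str
    n_input: int
    n_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed + self.n_retained:
            raise ValueError("stage counts must satisfy input = removed + retained")


@dataclass
class FilterReport:
    stages: list[StageCount] = field(default_factory=list)
    reasons: dict[tuple, list[str]] = field(default_factory=dict)

    def add_stage(self, name: str, decisions: dict[tuple, FilterDecision]) -> None:
        removed = sum(1 for d in decisions.values() if not d.keep)
        self.stages.append(
            StageCount(name, len(decisions), removed, len(decisions) - removed)
        )
        for key, decision in decisions.items():
            if not decision.keep:
                self.reasons.setdefault(key, []).extend(
                    f"{name}:{r}" for r in decision.reasons
                )


# ---------------------------------------------------------------------------
# caller-level filter


def _require(variant: VariantRecord, role: str, platform: str):
    sup = variant.support.get((role, platform))
    if sup is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} {variant.ref}>{variant.alt} "
            f"has no support entry for sample {role}.{platform}"
        )
    return sup


def caller_level_filter(
    variant: VariantRecord,
    platform: str,
    config: FilterConfig | None = None,
    tumor_role: str = "primary",
) -> FilterDecision:
    """Apply the platform-specific caller-level removal rules for one lesion.

    ``platform`` selects the rule set ("WES" or "WGS"); removal occurs if any
    listed condition holds and the reasons list every triggered condition.
    """
    config = config or FilterConfig()
    reasons: list[str] = []
    if platform == "WES":
        tumor = _require(variant, tumor_role, "WES")
        normal = _require(variant, "normal", "WES")
        if tumor.vaf <= config.wes_tumor_vaf_max:
            reasons.append("tumor_vaf_low")
        if tumor.var_reads <= config.wes_tumor_var_reads_max:
            reasons.append("tumor_var_reads_low")
        if tumor.depth <= config.wes_tumor_cov_max:
            reasons.append("tumor_cov_low")
        normal_vaf_high = normal.vaf >= config.wes_normal_vaf_min
        normal_cov_low = normal.depth <= config.wes_normal_cov_max
        if config.conjunctive_normal_rule:
            if normal_vaf_high and normal_cov_low:
                reasons.append("normal_vaf_high_and_cov_low")
        else:
            if normal_vaf_high:
                reasons.append("normal_vaf_high")
            if normal_cov_low:
                reasons.append("normal_cov_low")
    elif platform == "WGS":
        tumor = _require(variant, tumor_role, "WGS")
        normal = _require(variant, "normal", "WGS")
        if tumor.vaf <= config.wgs_tumor_vaf_max:
            reasons.append("tumor_vaf_low")
        related = [
            variant.support[(role, "WGS")]
            for role in TUMOR_ROLES
            if role != tumor_role and (role, "WGS") in variant.support
        ]
        if related and all(s.vaf <= config.wgs_related_vaf_max for s in related):
            reasons.append("related_vaf_low")
        for plat in DNA_PLATFORMS:
            sup = variant.support.get((tumor_role, plat))
            if sup is not None and sup.var_reads <= config.wgs_var_reads_max[plat]:
                reasons.append(f"tumor_var_reads_low_{plat.lower()}")
        for plat in DNA_PLATFORMS:
            for role in (tumor_role, "normal"):
                sup = variant.support.get((role, plat))
                if sup is not None and sup.depth <= config.wgs_cov_max[plat]:
                    reasons.append(f"{role}_cov_low_{plat.lower()}")
        for plat in DNA_PLATFORMS:
            sup = variant.support.get(("normal", plat))
            if sup is not None and (
                sup.vaf >= config.wgs_normal_vaf_min
                or sup.var_reads >= config.wgs_normal_var_reads_min
            ):
                reasons.append(f"normal_support_{plat.lower()}")
    else:
        raise ValueError(f"caller-level filter platform must be WES or WGS, got {platform!r}")
    return FilterDecision(keep=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# consequence / population DB / ad-hoc


def consequence_filter(
    variant: VariantRecord, whitelist: frozenset[str] | None = None
) -> FilterDecision:
    """Retain iff the full consequence string matches the whitelist exactly."""
    whitelist = whitelist if whitelist is not None else load_whitelist()
    if variant.consequence in whitelist:
        return FilterDecision(keep=True)
    return FilterDecision(keep=False, reasons=["consequence_not_whitelisted"])


def load_db_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Load population-database sites from a TSV of chrom, pos, ref, alt."""
    sites: set[tuple[str, int, str, str]] = set()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            sites.add((chrom, int(pos), ref, alt))
    return sites


def population_db_filter(
    variant: VariantRecord, db_sites: set[tuple[str, int, str, str]]
) -> FilterDecision:
    """Remove a variant iff an allele-level (chrom, pos, ref, alt) match exists."""
    if variant.key in db_sites:
        return FilterDecision(keep=False, reasons=["in_population_db"])
    return FilterDecision(keep=True)


def adhoc_filter(
    variant: VariantRecord, config: FilterConfig | None = None
) -> FilterDecision:
    """Cross-platform ad-hoc retention rule.

    Retained iff the chromosome is canonical (1-38 or X), at least one
    lesion/platform entry (WGS, WES or RNA) has >= 7 variant reads and
    >= 4% VAF, and every normal DNA entry has <= 4 variant reads.
    """
    config = config or FilterConfig()
    reasons: list[str] = []
    _, canonical = normalize_chrom(variant.chrom)
    if not canonical:
        reasons.append("non_canonical_chrom")
    supported = any(
        sup.var_reads >= config.adhoc_var_reads_min and sup.vaf >= config.adhoc_vaf_min
        for (role, platform), sup in variant.support.items()
        if role in TUMOR_ROLES
    )
    if not supported:
        reasons.append("no_tumor_support")
    for platform in DNA_PLATFORMS:
        sup = variant.support.get(("normal", platform))
        if sup is not None and sup.var_reads > config.adhoc_normal_reads_max:
            reasons.append(f"normal_support_{platform.lower()}")
    return FilterDecision(keep=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# clonal pre-filter


def _locus_in_segments(
    chrom: str, pos: int, segments: Iterable[Segment]
) -> list[Segment]:
    iv = GenomicInterval(chrom, pos - 1, pos)
    return [s for s in segments if s.interval.overlaps(iv)]


def clonal_prefilter(
    variant: VariantRecord,
    loh_segments: Sequence[Segment] = (),
    cna_segments: Sequence[Segment] = (),
    config: FilterConfig | None = None,
) -> FilterDecision:
    """Pre-filter for clonal analysis.

    Retained iff: zero normal variant reads in both WGS and WES, WES depth
    >= 80 in both the primary and the metastasis, >= 7 variant reads in
    either lesion, and the locus intersects no LOH segment and no CN segment
    outside the copy-neutral window.
    """
    config = config or FilterConfig()
    reasons: list[str] = []
    for platform in DNA_PLATFORMS:
        sup = variant.support.get(("normal", platform))
        if sup is not None and sup.var_reads > 0:
            reasons.append(f"normal_support_{platform.lower()}")
    for role in TUMOR_ROLES:
        sup = variant.support.get((role, "WES"))
        if sup is None or sup.depth < config.prefilter_wes_depth_min:
            reasons.append(f"wes_depth_low_{role}")
    if not any(
        sup.var_reads >= config.prefilter_var_reads_min
        for (role, _), sup in variant.support.items()
        if role in TUMOR_ROLES
    ):
        reasons.append("var_reads_low")
    if _locus_in_segments(variant.chrom, variant.pos, loh_segments):
        reasons.append("in_loh_space")
    lo, hi = config.cn_neutral_window
    if any(
        not (lo <= seg.value <= hi)
        for seg in _locus_in_segments(variant.chrom, variant.pos, cna_segments)
    ):
        reasons.append("copy_altered_space")
    return FilterDecision(keep=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# cascade


def run_cascade(
    variants: Sequence[VariantRecord],
    config: FilterConfig | None = None,
    db_sites: set[tuple[str, int, str, str]] | None = None,
    tumor_role: str = "primary",
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the full cascade: caller-level -> consequence -> population DB ->
    ad-hoc. A variant survives the caller-level stage if it survives the rule
    set of at least one DNA platform on which the lesion has support."""
    config = config or FilterConfig()
    db_sites = db_sites or set()
    report = FilterReport()

    decisions: dict[tuple, FilterDecision] = {}
    for v in variants:
        platforms = [
            p
            for p in DNA_PLATFORMS
            if (tumor_role, p) in v.support and ("normal", p) in v.support
        ]
        if not platforms:
            decisions[v.key] = FilterDecision(False, ["no_dna_tumor_support"])
            continue
        per_platform = [caller_level_filter(v, p, config, tumor_role) for p in platforms]
        if any(d.keep for d in per_platform):
            decisions[v.key] = FilterDecision(True)
        else:
            reasons = [
                f"{p.lower()}_{r}" for p, d in zip(platforms, per_platform) for r in d.reasons
            ]
            decisions[v.key] = FilterDecision(False, reasons)
    report.add_stage("caller_level", decisions)
    survivors = [v for v in variants if decisions[v.key].keep]

    decisions = {v.key: consequence_filter(v, config.whitelist) for v in survivors}
    report.add_stage("consequence", decisions)
    survivors = [v for v in survivors if decisions[v.key].keep]

    decisions = {v.key: population_db_filter(v, db_sites) for v in survivors}
    report.add_stage("population_db", decisions)
    survivors = [v for v in survivors if decisions[v.key].keep]

    decisions = {v.key: adhoc_filter(v, config) for v in survivors}
    report.add_stage("adhoc", decisions)
    survivors = [v for v in survivors if decisions[v.key].keep]

    return survivors, report
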