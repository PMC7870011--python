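"""Primary-vs-metastasis comparison, purity estimation, expression tiers,
and driver prioritization.

Variant sets are matched on allele-level keys (chrom, pos, ref, alt). The
percent-shared statistic uses the union of the two sets as its denominator
and is rounded half away from zero to an integer percent. Tumor purity is
estimated as the variant allele frequency of a designated truncal variant
(the biallelic mutation inside the copy-neutral LOH block), reported per
platform with the maximum alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genomic_io import Segment, VariantRecord

__all__ = [
    "ComparisonResult",
    "DriverEvidence",
    "match_variants",
    "percent_shared",
    "estimate_purity",
    "expression_tiers",
    "score_drivers",
]

Key = tuple[str, int, str, str]


@dataclass
class ComparisonResult:
    shared: set[Key]
    unique_a: set[Key]
    unique_b: set[Key]
    #: per shared key, (max VAF in set A sample, max VAF in set B sample)
    vaf_pairs: dict[Key, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_union(self) -> int:
        return len(self.shared) + len(self.unique_a) + len(self.unique_b)

    @property
    def percent_shared(self) -> int:
        n_a = len(self.shared) + len(self.unique_a)
        n_b = len(self.shared) + len(self.unique_b)
        return percent_shared(n_a, n_b, self.n_union)


def _max_vaf(variant: VariantRecord, role: str) -> float:
    vafs = [
        sup.vaf for (r, _), sup in variant.support.items() if r == role
    ]
    return max(vafs, default=0.0)


def match_variants(
    set_a: Sequence[VariantRecord],
    set_b: Sequence[VariantRecord],
    role_a: str = "primary",
    role_b: str = "metastasis",
) -> ComparisonResult:
    """Allele-level set comparison of two call sets.

    Duplicate keys within one set are an error. For shared keys the result
    records the maximum VAF across platforms in each lesion (scatter-plot
    substrate).
    """
    keys_a = [v.key for v in set_a]
    keys_b = [v.key for v in set_b]
    for name, keys in (("A", keys_a), ("B", keys_b)):
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant keys within set {name}")
    a_by_key = {v.key: v for v in set_a}
    b_by_key = {v.key: v for v in set_b}
    shared = set(a_by_key) & set(b_by_key)
    pairs = {
        key: (_max_vaf(a_by_key[key], role_a), _max_vaf(b_by_key[key], role_b))
        for key in shared
    }
    return ComparisonResult(
        shared=shared,
        unique_a=set(a_by_key) - shared,
        unique_b=set(b_by_key) - shared,
        vaf_pairs=pairs,
    )


def percent_shared(n_a: int, n_b: int, n_union: int) -> int:
    """Integer percent of the union shared by both sets.

    ``100 * (n_a + n_b - n_union) / n_union`` rounded half away from zero.
    """
    if n_union < max(n_a, n_b):
        raise ValueError("union cannot be smaller than either set")
    if n_a + n_b < n_union:
        raise ValueError("sets cannot cover more than the union")
    if n_union == 0:
        return 0
    value = 100.0 * (n_a + n_b - n_union) / n_union
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def estimate_purity(
    variants: Sequence[VariantRecord],
    truncal_key: Key,
    roles: Sequence[str] = ("primary", "metastasis"),
) -> dict[str, dict]:
    """Purity per lesion as the truncal variant's VAF, per platform.

    Returns ``{role: {"per_platform": {platform: vaf}, "max": vaf}}``.
    Raises ``ValueError`` if the truncal variant is absent or has no covered
    platform for a requested lesion.
    """
    by_key = {v.key: v for v in variants}
    if truncal_key not in by_key:
        raise ValueError(f"truncal variant {truncal_key} not found in call set")
    truncal = by_key[truncal_key]
    out: dict[str, dict] = {}
    for role in roles:
        per_platform = {
            platform: sup.vaf
            for (r, platform), sup in truncal.support.items()
            if r == role and sup.depth > 0
        }
        if not per_platform:
            raise ValueError(
                f"truncal variant has no covered platform in the {role} sample"
            )
        out[role] = {"per_platform": per_platform, "max": max(per_platform.values())}
    return out


def expression_tiers(
    fpkm: pd.DataFrame,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample expression tiers from FPKM rank percentiles.

    ``fpkm`` is genes x samples. When ``counts`` is given, genes with a
    cumulative raw read count < 1 across all samples are removed first.
    The percentile of a gene is its descending rank (ties share the minimum
    rank) over the gene count, in percent — the 25th-highest of 1000 genes
    sits at 2.5%: high < 2.5, moderate in [2.5, 22], low > 22.
    """
    if (fpkm < 0).any().any():
        raise ValueError("FPKM values must be >= 0")
    if counts is not None:
        keep = counts.sum(axis=1) >= 1
        fpkm = fpkm.loc[keep.reindex(fpkm.index, fill_value=False)]
    n = len(fpkm)
    tiers = pd.DataFrame(index=fpkm.index, columns=fpkm.columns, dtype=object)
    for sample in fpkm.columns:
        values = fpkm[sample]
        rank = values.rank(method="min", ascending=False)
        pct = 100.0 * rank / n
        tiers.loc[pct < 2.5, sample] = "high"
        tiers.loc[(pct >= 2.5) & (pct <= 22.0), sample] = "moderate"
        tiers.loc[pct > 22.0, sample] = "low"
    return tiers


@dataclass
class DriverEvidence:
    """Driver-prioritization evidence for one gene; score counts true flags."""

    gene: str
    in_cancer_census: bool = False
    mutated_both_patients: bool = False
    shared_primary_met: bool = False
    cross_platform_concordant: bool = False
    rationale: list[str] = field(default_factory=list)

    @property
    def score(self) -> int:
        return sum(
            (
                self.in_cancer_census,
                self.mutated_both_patients,
                self.shared_primary_met,
                self.cross_platform_concordant,
            )
        )


def score_drivers(
    evidence: pd.DataFrame,
    census_genes: Sequence[str] = (),
    loh_segments: Sequence[Segment] = (),
) -> list[DriverEvidence]:
    """Rank genes by the count of satisfied prioritization criteria.

    ``evidence`` is indexed by gene symbol with boolean columns
    ``mutated_both_patients`` and ``shared_primary_met``, plus the
    cross-platform columns ``amplified``, ``deleted``, ``has_snv``,
    ``in_loh`` and the string column ``expression_tier``. Cross-platform
    concordance is (amplified and high expression), (deleted and low
    expression), or (SNV inside an LOH segment). Ties are broken by gene
    symbol.
    """
    census = set(census_genes)
    results: list[DriverEvidence] = []
    for gene, row in evidence.iterrows():
        tier = row.get("expression_tier", "")
        amplified = bool(row.get("amplified", False))
        deleted = bool(row.get("deleted", False))
        has_snv = bool(row.get("has_snv", False))
        in_loh = bool(row.get("in_loh", False))
        concordant_reasons = []
        if amplified and tier == "high":
            concordant_reasons.append("copy gain with high expression")
        if deleted and tier == "low":
            concordant_reasons.append("copy loss with low expression")
        if has_snv and in_loh:
            concordant_reasons.append("SNV with LOH")
        ev = DriverEvidence(
            gene=str(gene),
            in_cancer_census=str(gene) in census,
            mutated_both_patients=bool(row.get("mutated_both_patients", False)),
            shared_primary_met=bool(row.get("shared_primary_met", False)),
            cross_platform_concordant=bool(concordant_reasons),
            rationale=concordant_reasons,
        )
        results.append(ev)
    return sorted(results, key=lambda e: (-e.score, e.gene))
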