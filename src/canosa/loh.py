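"""Somatic and germline loss-of-heterozygosity detection.

Somatic LOH: select germline heterozygous SNPs from the normal sample
(VAF 0.40-0.60, depth >= 20), compute each marker's tumor VAF deviation
|VAF - 0.5|, segment the per-chromosome deviation series with a penalized
change-point search, and call LOH for segments whose mean absolute deviation
from the heterozygous baseline is >= 0.1.

Germline LOH: tile fixed ~500 kb bins across each chromosome and flag bins
with fewer than 5 germline het sites; such bins are blind spots for somatic
LOH (no heterozygosity to lose) and, by default, are masked out of the
somatic calls.

Classification against copy number: deletion-LOH below 1.5 copies,
copy-number-neutral LOH within [1.5, 2.5], gain-LOH above 2.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .changepoint import segment_indices
from .genomic_io import (
    GeneModel,
    GenomeBuild,
    GenomicInterval,
    Segment,
    SiteReadcount,
    chrom_sort_key,
    overlap_length,
    subtract_intervals,
)

__all__ = [
    "HetMarker",
    "LohSegment",
    "select_germline_hets",
    "tumor_deviation_track",
    "segment_deviation",
    "call_somatic_loh",
    "germline_loh_bins",
    "classify_loh",
    "annotate_segments",
]

LOH_THRESHOLD = 0.1
NEUTRAL_WINDOW = (1.5, 2.5)


@dataclass(frozen=True)
class HetMarker:
    """A germline heterozygous site usable as an LOH marker."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    normal_vaf: float
    normal_depth: int


@dataclass
class LohSegment:
    """An LOH call: the deviation segment plus its copy-number class."""

    segment: Segment
    loh_class: str | None = None  # deletion-LOH / CN-neutral-LOH / gain-LOH / None
    genes: list[str] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return self.segment.interval


def select_germline_hets(
    normal_readcounts: Iterable[SiteReadcount],
    vaf_range: tuple[float, float] = (0.40, 0.60),
    min_depth: int = 20,
) -> list[HetMarker]:
    """Germline het selection: normal VAF within ``vaf_range`` (inclusive)
    at >= ``min_depth`` coverage. The alt allele is the deepest non-reference
    allele at the site."""
    markers: list[HetMarker] = []
    for site in normal_readcounts:
        if site.depth < min_depth:
            continue
        non_ref = {
            base: n for base, n in site.allele_counts.items() if base != site.ref and n > 0
        }
        if not non_ref:
            continue
        alt = max(non_ref, key=non_ref.get)
        vaf = non_ref[alt] / site.depth
        if vaf_range[0] <= vaf <= vaf_range[1]:
            markers.append(
                HetMarker(site.chrom, site.pos, site.ref, alt, vaf, site.depth)
            )
    return markers


def tumor_deviation_track(
    markers: Sequence[HetMarker],
    tumor_readcounts: Iterable[SiteReadcount],
) -> tuple[pd.DataFrame, int]:
    """Per-marker tumor VAF deviation |VAF - 0.5|, ordered by (chrom, pos).

    Markers without tumor coverage are dropped; the second return value
    counts them. Raises ``ValueError`` when no marker overlaps the tumor
    readcounts.
    """
    by_site = {(r.chrom, r.pos): r for r in tumor_readcounts}
    rows = []
    dropped = 0
    for m in markers:
        site = by_site.get((m.chrom, m.pos))
        if site is None or site.depth == 0:
            dropped += 1
            continue
        vaf = site.allele_counts.get(m.alt, 0) / site.depth
        rows.append(
            {"chrom": m.chrom, "pos": m.pos, "vaf": vaf, "deviation": abs(vaf - 0.5)}
        )
    if not rows:
        raise ValueError("no markers overlap the tumor readcounts")
    track = pd.DataFrame(rows)
    track = track.sort_values(
        ["chrom", "pos"], key=lambda col: col.map(chrom_sort_key) if col.name == "chrom" else col
    ).reset_index(drop=True)
    return track, dropped


def segment_deviation(
    track: pd.DataFrame,
    min_markers: int = 10,
    beta: float = 3.0,
    merge_tol: float = 0.02,
    min_segment_markers: int = 5,
) -> list[Segment]:
    """Partition each chromosome's marker span into constant-deviation segments.

    Change points come from the penalized search in
    :mod:`canosa.changepoint`; no segment is shorter than
    ``min_segment_markers`` markers, and adjacent segments with mean
    deviations within ``merge_tol`` are joined. Segment boundaries between
    change points are placed at the midpoint between flanking markers;
    chromosomes with fewer than ``min_markers`` markers are skipped with a
    warning.
    """
    segments: list[Segment] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        positions = sub["pos"].to_numpy()
        deviations = sub["deviation"].to_numpy()
        if positions.size < min_markers:
            warnings.warn(
                f"chromosome {chrom}: only {positions.size} markers "
                f"(< {min_markers}); skipped"
            )
            continue
        for i, j in segment_indices(
            deviations, beta=beta, merge_tol=merge_tol, min_size=min_segment_markers
        ):
            start = (
                positions[i] - 1
                if i == 0
                else (positions[i - 1] + positions[i]) // 2
            )
            end = (
                positions[j - 1]
                if j == positions.size
                else (positions[j - 1] + positions[j]) // 2
            )
            value = float(np.clip(deviations[i:j].mean(), 0.0, 0.5))
            segments.append(
                Segment(
                    interval=GenomicInterval(str(chrom), int(start), int(end)),
                    value=value,
                    n_markers=int(j - i),
                    kind="LOH",
                )
            )
    return segments


def call_somatic_loh(
    segments: Sequence[Segment],
    threshold: float = LOH_THRESHOLD,
    blind_spots: Sequence[GenomicInterval] | None = None,
) -> list[LohSegment]:
    """Call LOH for segments with mean deviation >= ``threshold`` (inclusive).

    When ``blind_spots`` (germline-LOH bins) are given, the called intervals
    are trimmed so no reported call intersects a blind spot.
    """
    calls: list[LohSegment] = []
    for seg in segments:
        if seg.value < threshold:
            continue
        if blind_spots:
            pieces = subtract_intervals(seg.interval, blind_spots)
        else:
            pieces = [seg.interval]
        for piece in pieces:
            markers = max(1, round(seg.n_markers * len(piece) / seg.length))
            calls.append(
                LohSegment(
                    segment=Segment(
                        interval=piece,
                        value=seg.value,
                        n_markers=markers,
                        kind="LOH",
                    )
                )
            )
    return calls


def germline_loh_bins(
    het_positions: Mapping[str, Sequence[int]],
    genome: GenomeBuild,
    bin_size: int = 500_000,
    min_freq: int = 5,
) -> list[GenomicInterval]:
    """Germline-LOH blind spots: fixed bins with fewer than ``min_freq`` hets.

    Bins tile from coordinate 0; the trailing partial bin uses its raw count.
    """
    flagged: list[GenomicInterval] = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        positions = np.asarray(het_positions.get(chrom, ()), dtype=int)
        n_bins = (length + bin_size - 1) // bin_size
        counts = (
            np.bincount((positions - 1) // bin_size, minlength=n_bins)
            if positions.size
            else np.zeros(n_bins, dtype=int)
        )
        for b in range(n_bins):
            if counts[b] < min_freq:
                flagged.append(
                    GenomicInterval(
                        chrom, b * bin_size, min((b + 1) * bin_size, length)
                    )
                )
    return flagged


def classify_loh(
    loh_segments: Sequence[LohSegment],
    cn_segments: Sequence[Segment],
    neutral_window: tuple[float, float] = NEUTRAL_WINDOW,
) -> list[LohSegment]:
    """Assign deletion / copy-neutral / gain classes from overlapping copy number.

    The copy number over each LOH segment is the length-weighted mean of the
    overlapping CN segments; a segment with no CN coverage keeps class
    ``None`` with a warning.
    """
    lo, hi = neutral_window
    out: list[LohSegment] = []
    for call in loh_segments:
        weights = 0.0
        weighted_cn = 0.0
        for cn in cn_segments:
            ov = overlap_length(call.interval, cn.interval)
            if ov > 0:
                weights += ov
                weighted_cn += ov * cn.value
        if weights == 0:
            warnings.warn(
                f"LOH segment {call.interval.chrom}:{call.interval.start}-"
                f"{call.interval.end} has no copy-number coverage"
            )
            out.append(LohSegment(call.segment, None, list(call.genes)))
            continue
        mean_cn = weighted_cn / weights
        if mean_cn < lo:
            cls = "deletion-LOH"
        elif mean_cn <= hi:
            cls = "CN-neutral-LOH"
        else:
            cls = "gain-LOH"
        out.append(LohSegment(call.segment, cls, list(call.genes)))
    return out


def annotate_segments(
    segments: Sequence[LohSegment],
    genes: Sequence[GeneModel],
    flank: int = 10_000,
) -> list[LohSegment]:
    """Attach symbol-sorted gene lists overlapping each segment +/- ``flank``."""
    out: list[LohSegment] = []
    for call in segments:
        iv = call.interval
        padded = GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank)
        symbols = sorted(
            {g.symbol for g in genes if g.interval.overlaps(padded)}
        )
        out.append(LohSegment(call.segment, call.loh_class, symbols))
    return out
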