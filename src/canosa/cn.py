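"""Windowed depth-ratio copy-number estimation and aneuploidy summarization.

A deliberately simple tumor/normal estimator: fixed-width coverage windows
(default 10 kb), per-window copy number ``2 * ratio / median(ratio)`` where
``ratio`` is tumor/normal mean depth and the median is taken over autosomal
windows, an optional LOESS-style GC correction, and piecewise-constant
segmentation with the same penalized change-point engine used for LOH.

Percent aneuploidy is the fraction of assessed genome length in segments at
or below the loss threshold (default 1.5 copies) or at or above the gain
threshold (default 2.5 copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .changepoint import segment_indices
from .genomic_io import (
    GeneModel,
    GenomicInterval,
    Segment,
    chrom_sort_key,
    normalize_chrom,
    overlap_length,
)

__all__ = [
    "LOSS_THRESHOLD",
    "GAIN_THRESHOLD",
    "window_cn_estimate",
    "segment_cn",
    "percent_aneuploidy",
    "annotate_genes_cn",
]

LOSS_THRESHOLD = 1.5
GAIN_THRESHOLD = 2.5

_WINDOW_COLS = ["chrom", "start", "end"]


def window_cn_estimate(
    tumor_windows: pd.DataFrame,
    normal_windows: pd.DataFrame,
    gc_correct: bool = False,
    min_normal_depth: float = 10.0,
) -> pd.DataFrame:
    """Per-window copy number from the tumor/normal depth ratio.

    Both inputs need columns chrom, start, end, depth (and gc when
    ``gc_correct``); the window grids must match exactly. Windows whose
    normal depth is below ``min_normal_depth`` are dropped; the returned
    frame carries a ``cn`` column and ``attrs["n_dropped"]``.
    """
    if not tumor_windows[_WINDOW_COLS].reset_index(drop=True).equals(
        normal_windows[_WINDOW_COLS].reset_index(drop=True)
    ):
        raise ValueError("tumor and normal window grids do not match")
    merged = tumor_windows.reset_index(drop=True).copy()
    merged = merged.rename(columns={"depth": "tumor_depth"})
    merged["normal_depth"] = normal_windows.reset_index(drop=True)["depth"].to_numpy()

    keep = merged["normal_depth"] >= min_normal_depth
    n_dropped = int((~keep).sum())
    merged = merged.loc[keep].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no windows with sufficient normal depth")

    ratio = merged["tumor_depth"].to_numpy() / merged["normal_depth"].to_numpy()

    if gc_correct:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        gc = merged["gc"].to_numpy()
        trend = lowess(ratio, gc, frac=0.3, return_sorted=False)
        trend = np.where(trend > 0, trend, np.median(ratio))
        ratio = ratio / trend * np.median(ratio)

    autosomal = np.array(
        [
            normalize_chrom(c)[0] != "X" and normalize_chrom(c)[1]
            for c in merged["chrom"]
        ],
        dtype=bool,
    )
    baseline = np.median(ratio[autosomal]) if autosomal.any() else np.median(ratio)
    merged["cn"] = 2.0 * ratio / baseline
    merged.attrs["n_dropped"] = n_dropped
    return merged


def segment_cn(
    windows: pd.DataFrame,
    beta: float = 3.0,
    min_windows: int = 10,
    merge_tol: float = 0.25,
) -> list[Segment]:
    """Piecewise-constant CN segments per chromosome (value = mean window CN)."""
    segments: list[Segment] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        values = sub["cn"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if values.size < min_windows:
            continue
        for i, j in segment_indices(values, beta=beta, merge_tol=merge_tol):
            segments.append(
                Segment(
                    interval=GenomicInterval(str(chrom), int(starts[i]), int(ends[j - 1])),
                    value=float(max(values[i:j].mean(), 0.0)),
                    n_markers=int(j - i),
                    kind="CN",
                )
            )
    return segments


@dataclass
class AneuploidySummary:
    loss_pct: float
    gain_pct: float

    @property
    def total_pct(self) -> float:
        return self.loss_pct + self.gain_pct

    def as_dict(self) -> dict[str, float]:
        return {
            "loss_pct": self.loss_pct,
            "gain_pct": self.gain_pct,
            "total_pct": self.total_pct,
        }


def percent_aneuploidy(
    segments: Sequence[Segment],
    loss_thr: float = LOSS_THRESHOLD,
    gain_thr: float = GAIN_THRESHOLD,
) -> AneuploidySummary:
    """Percent of assessed genome length lost (CN <= ``loss_thr``) and gained
    (CN >= ``gain_thr``). The denominator is the summed segment length."""
    ordered = sorted(segments, key=lambda s: (chrom_sort_key(s.interval.chrom), s.interval.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise ValueError("copy-number segments must be non-overlapping")
    total = sum(s.length for s in segments)
    if total == 0:
        return AneuploidySummary(0.0, 0.0)
    loss = sum(s.length for s in segments if s.value <= loss_thr)
    gain = sum(s.length for s in segments if s.value >= gain_thr)
    return AneuploidySummary(100.0 * loss / total, 100.0 * gain / total)


def annotate_genes_cn(
    segments: Sequence[Segment],
    genes: Sequence[GeneModel],
    loss_thr: float = LOSS_THRESHOLD,
    gain_thr: float = GAIN_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene copy number (length-weighted mean over overlapping segments)
    and call in {amplified, deleted, neutral}; genes without any segment
    overlap are neutral and flagged in the ``assessed`` column."""
    rows = []
    for gene in genes:
        weight = 0.0
        weighted_cn = 0.0
        for seg in segments:
            ov = overlap_length(gene.interval, seg.interval)
            if ov > 0:
                weight += ov
                weighted_cn += ov * seg.value
        if weight == 0:
            rows.append(
                {"gene": gene.symbol, "copies": 2.0, "call": "neutral", "assessed": False}
            )
            continue
        copies = weighted_cn / weight
        if copies <= loss_thr:
            call = "deleted"
        elif copies >= gain_thr:
            call = "amplified"
        else:
            call = "neutral"
        rows.append(
            {"gene": gene.symbol, "copies": copies, "call": call, "assessed": True}
        )
    return pd.DataFrame(rows, columns=["gene", "copies", "call", "assessed"])
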