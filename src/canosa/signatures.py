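"""96-context mutation spectra, genome-composition normalization,
signature-exposure refitting, and rainfall/kataegis analysis.

Single-base substitutions are classed on the pyrimidine strand into the
standard 96 categories ``5'[ref>alt]3'`` (ref in {C, T}). Spectra observed on
one genomic territory (e.g. exome) are renormalised to another composition by
per-trinucleotide frequency ratios before signature exposures are refit with
forward-selection nonnegative least squares, mirroring the refitting strategy
of deconstructSigs (including its default 0.06 weight cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genomic_io import VariantRecord, chrom_sort_key

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXTS_96",
    "CONTEXTS_32",
    "MutationSpectrum",
    "SignatureExposure",
    "KataegisCluster",
    "revcomp",
    "snv_context96",
    "build_spectrum",
    "normalize_spectrum",
    "fit_signature_exposures",
    "synthetic_signatures",
    "sample_spectrum",
    "intermutation_distances",
    "detect_kataegis",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: COSMIC-style ordering: substitution-major, then 5' base, then 3' base.
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

#: 32 pyrimidine-centred trinucleotides, e.g. "ACA", "TCG".
CONTEXTS_32 = tuple(
    f"{five}{center}{three}" for center in "CT" for five in "ACGT" for three in "ACGT"
)

_INDEX_96 = {label: i for i, label in enumerate(CONTEXTS_96)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Trinucleotide context (5' + ref + 3') of each of the 96 classes.
TRINUC_OF_96 = tuple(f"{label[0]}{label[2]}{label[6]}" for label in CONTEXTS_96)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_label(triplet: str, alt: str) -> str:
    """96-class label for a reference triplet and alt allele, folding
    purine-centred changes onto the pyrimidine strand."""
    triplet = triplet.upper()
    alt = alt.upper()
    if triplet[1] in "CT":
        return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"
    rc = revcomp(triplet)
    return f"{rc[0]}[{rc[1]}>{alt.translate(_COMPLEMENT)}]{rc[2]}"


def snv_context96(
    chrom: str, pos: int, ref: str, alt: str, sequences: Mapping[str, str]
) -> str | None:
    """96-class of an SNV given the reference sequence (``pos`` 1-based).

    Returns ``None`` at a chromosome edge (no flanking base). Raises
    ``ValueError`` if the reference allele does not match the sequence.
    """
    seq = sequences[chrom]
    if pos < 2 or pos > len(seq) - 1:
        return None
    base = seq[pos - 1].upper()
    if base != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: sequence has {base}, variant ref {ref}"
        )
    return context_label(seq[pos - 2 : pos + 1], alt)


@dataclass
class MutationSpectrum:
    """Counts over the 96 substitution contexts (order :data:`CONTEXTS_96`)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 entries")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be >= 0")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty spectrum")
        return self.counts / total

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXTS_96))


def build_spectrum(
    variants: Iterable[VariantRecord], sequences: Mapping[str, str]
) -> tuple[MutationSpectrum, int]:
    """Count SNVs into a 96-context spectrum.

    Non-SNVs and chromosome-edge variants are skipped; the second return
    value is the number skipped.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            skipped += 1
            continue
        label = snv_context96(v.chrom, v.pos, v.ref, v.alt, sequences)
        if label is None:
            skipped += 1
            continue
        counts[_INDEX_96[label]] += 1
    return MutationSpectrum(counts), skipped


def normalize_spectrum(
    spectrum: MutationSpectrum,
    source_freqs: Mapping[str, float],
    target_freqs: Mapping[str, float],
) -> MutationSpectrum:
    """Rescale a spectrum observed on one trinucleotide composition to another.

    Each context count is multiplied by ``target_freq / source_freq`` of its
    trinucleotide, then the whole spectrum is rescaled to preserve the total
    count. With equal compositions this is the identity.
    """
    for ctx in CONTEXTS_32:
        if ctx not in source_freqs or ctx not in target_freqs:
            raise ValueError(f"missing trinucleotide frequency for {ctx}")
        if source_freqs[ctx] <= 0:
            raise ValueError(f"zero source frequency for {ctx}")
    ratios = np.array(
        [target_freqs[tri] / source_freqs[tri] for tri in TRINUC_OF_96]
    )
    scaled = spectrum.counts * ratios
    total = scaled.sum()
    if total > 0:
        scaled = scaled * (spectrum.n / total)
    return MutationSpectrum(scaled)


@dataclass
class SignatureExposure:
    """Fitted signature weights plus the residual reconstruction error."""

    weights: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if sum(self.weights.values()) > 1 + 1e-9:
            raise ValueError("weights must sum to <= 1")

    @property
    def unexplained(self) -> float:
        return 1.0 - sum(self.weights.values())


def _nnls_fit(matrix: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    weights, _ = nnls(matrix, target)
    residual = float(np.linalg.norm(target - matrix @ weights))
    return weights, residual


def fit_signature_exposures(
    spectrum: MutationSpectrum,
    signatures: pd.DataFrame,
    weight_cutoff: float = 0.06,
    tol: float = 1e-4,
) -> SignatureExposure:
    """Refit signature exposures by forward-selection nonnegative least squares.

    Signatures (rows = 96 contexts, columns = signatures, each column a
    probability vector) are added greedily while they reduce the Euclidean
    reconstruction error of the spectrum fractions by more than ``tol``.
    Weights below ``weight_cutoff`` are zeroed and the remainder refit.
    """
    if spectrum.n == 0:
        raise ValueError("cannot fit an empty spectrum")
    if not np.allclose(signatures.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    sig_matrix = signatures.to_numpy(dtype=float)
    names = list(signatures.columns)
    target = spectrum.fractions

    active: list[int] = []
    best_residual = float(np.linalg.norm(target))
    while len(active) < len(names):
        candidate_best: tuple[float, int] | None = None
        for j in range(len(names)):
            if j in active:
                continue
            w, res = _nnls_fit(sig_matrix[:, active + [j]], target)
            if candidate_best is None or res < candidate_best[0]:
                candidate_best = (res, j)
        if candidate_best is None or best_residual - candidate_best[0] <= tol:
            break
        best_residual = candidate_best[0]
        active.append(candidate_best[1])

    if not active:  # degenerate: keep the single best signature
        errs = [
            _nnls_fit(sig_matrix[:, [j]], target)[1] for j in range(len(names))
        ]
        active = [int(np.argmin(errs))]

    weights, residual = _nnls_fit(sig_matrix[:, active], target)
    kept = [j for j, w in zip(active, weights) if w >= weight_cutoff]
    if kept and len(kept) < len(active):
        weights, residual = _nnls_fit(sig_matrix[:, kept], target)
        active = kept
    elif not kept:
        active, weights = [], np.array([])
        residual = float(np.linalg.norm(target))

    total = float(weights.sum()) if len(weights) else 0.0
    if total > 1.0:
        weights = weights / total
        residual = float(np.linalg.norm(target - sig_matrix[:, active] @ weights))

    out = {name: 0.0 for name in names}
    for j, w in zip(active, weights):
        out[names[j]] = float(w)
    return SignatureExposure(weights=out, residual=residual)


def synthetic_signatures(k: int = 5, seed: int = 7) -> pd.DataFrame:
    """A deterministic synthetic 96 x k signature matrix for tests and demos.

    S1 is C>T-at-NpCpG rich (aging-like), S2 is T>G-at-NpTpT rich, S3 is flat;
    further columns are sparse random probability vectors. This is a synthetic
    stand-in, not the COSMIC catalogue.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    s1 = np.full(96, 0.1)
    for i, label in enumerate(CONTEXTS_96):
        if "[C>T]" in label and label.endswith("G"):
            s1[i] = 8.0
    cols["S1"] = s1 / s1.sum()

    s2 = np.full(96, 0.1)
    for i, label in enumerate(CONTEXTS_96):
        if "[T>G]" in label and label[0] == "T" and label.endswith("T"):
            s2[i] = 10.0
    cols["S2"] = s2 / s2.sum()

    cols["S3"] = np.full(96, 1.0 / 96)

    for extra in range(3, k):
        v = rng.dirichlet(np.full(96, 0.08))
        cols[f"S{extra + 1}"] = v

    return pd.DataFrame(cols, index=list(CONTEXTS_96)).iloc[:, :k]


def sample_spectrum(
    mix: Mapping[str, float],
    signatures: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
) -> MutationSpectrum:
    """Draw a spectrum of ``n`` mutations from a signature mixture."""
    weights = np.array([mix.get(name, 0.0) for name in signatures.columns])
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to > 0")
    probs = signatures.to_numpy() @ (weights / weights.sum())
    counts = rng.multinomial(n, probs / probs.sum())
    return MutationSpectrum(counts)


def mixture_context_probs(
    mix: Mapping[str, float], signatures: pd.DataFrame
) -> np.ndarray:
    """96-context probability vector implied by a signature mixture."""
    weights = np.array([mix.get(name, 0.0) for name in signatures.columns])
    probs = signatures.to_numpy() @ weights
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# rainfall / kataegis


def intermutation_distances(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Distance from each variant to the previous one on the same chromosome.

    The first variant on each chromosome has no distance and is omitted.
    Returns a DataFrame with columns chrom, pos, distance.
    """
    ordered = sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos))
    rows = []
    prev: VariantRecord | None = None
    for v in ordered:
        if prev is not None and prev.chrom == v.chrom:
            rows.append({"chrom": v.chrom, "pos": v.pos, "distance": v.pos - prev.pos})
        prev = v
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance"])


@dataclass
class KataegisCluster:
    chrom: str
    start: int  # 1-based position of first variant in cluster
    end: int  # 1-based position of last variant
    n: int
    tpc_fraction: float


def detect_kataegis(
    variants: Sequence[VariantRecord],
    sequences: Mapping[str, str],
    min_run: int = 6,
    max_imd: int = 1000,
    min_tpc_fraction: float = 0.5,
) -> list[KataegisCluster]:
    """Find runs of locally hypermutated TpC-focused substitutions.

    A cluster is a maximal run of >= ``min_run`` consecutive same-chromosome
    SNVs with every intermutation distance <= ``max_imd`` in which at least
    ``min_tpc_fraction`` of the variants are C>T or C>G changes at a TpC
    context (class ``T[C>T]N`` or ``T[C>G]N``).
    """
    snvs = [v for v in variants if len(v.ref) == 1 and len(v.alt) == 1]
    ordered = sorted(snvs, key=lambda v: (chrom_sort_key(v.chrom), v.pos))
    clusters: list[KataegisCluster] = []
    run: list[VariantRecord] = []

    def flush(run: list[VariantRecord]) -> None:
        if len(run) < min_run:
            return
        labels = [
            snv_context96(v.chrom, v.pos, v.ref, v.alt, sequences) for v in run
        ]
        tpc = sum(
            1
            for lab in labels
            if lab is not None and (lab.startswith("T[C>T]") or lab.startswith("T[C>G]"))
        )
        frac = tpc / len(run)
        if frac >= min_tpc_fraction:
            clusters.append(
                KataegisCluster(
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos,
                    n=len(run),
                    tpc_fraction=frac,
                )
            )

    for v in ordered:
        if run and (v.chrom != run[-1].chrom or v.pos - run[-1].pos > max_imd):
            flush(run)
            run = []
        run.append(v)
    flush(run)
    return clusters
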