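"""Strand-aware metagene profiles over a fixed 12-bin gene model.

Every ORF is rescaled to 10 equal segments ordered 5'->3' along
transcription (not genome coordinates), flanked by one upstream (promoter)
and one downstream (terminator) segment of the same unit length, so genes of
different sizes are comparable. Two profile flavours exist: the percentage
of binding-cluster incidences falling in each bin, and the mean smoothed
signal per bin. Length-stratified variants check that a gradient is not a
gene-length artefact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .clusters import BindingCluster
from .genome import Feature, Interval
from .tiling import SmoothedTrack

__all__ = [
    "BIN_LABELS",
    "MetageneProfile",
    "segment_gene",
    "cluster_distribution_profile",
    "signal_mean_profile",
    "stratify_by_length",
    "stratified_profiles",
]

N_ORF_BINS = 10
BIN_LABELS = ["5p_flank"] + [f"orf_{i}" for i in range(1, N_ORF_BINS + 1)] + ["3p_flank"]


@dataclass(frozen=True)
class MetageneProfile:
    """12 ordered bin values (flank, 10 ORF segments 5'->3', flank)."""

    bins: np.ndarray
    mode: str  # "cluster_percent" | "signal_mean"
    n_genes: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.size != N_ORF_BINS + 2:
            raise ValueError("a metagene profile has exactly 12 bins")
        object.__setattr__(self, "bins", b)

    @property
    def orf_bins(self) -> np.ndarray:
        return self.bins[1:-1]

    def orf_trend(self) -> tuple[float, float]:
        """Spearman (rho, P) of bin value vs bin index over the 10 ORF bins."""
        r = spearmanr(np.arange(1, N_ORF_BINS + 1), self.orf_bins)
        return float(r.statistic), float(r.pvalue)


def segment_gene(
    gene: Feature, chrom_length: int | None = None
) -> list[Interval | None]:
    """Split a stranded ORF into the 12-bin metagene model.

    The ORF is cut into 10 genomic segments of equal length; any remainder
    is distributed one bp each to the 3'-most segments. Flanks have the unit
    segment length (ORF length // 10). Bins are returned 5'->3', so for a
    minus-strand gene they run right-to-left genomically. Flanks falling off
    the chromosome are clipped; a fully clipped flank is None.
    """
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.id} must be stranded for metagene binning")
    length = gene.length
    if length < N_ORF_BINS:
        raise ValueError(f"gene {gene.id}: ORF shorter than {N_ORF_BINS} bp")
    base, rem = divmod(length, N_ORF_BINS)
    sizes_5_to_3 = [base] * (N_ORF_BINS - rem) + [base + 1] * rem

    genomic_sizes = sizes_5_to_3 if gene.strand == "+" else sizes_5_to_3[::-1]
    edges = np.concatenate([[gene.start], gene.start + np.cumsum(genomic_sizes)])
    orf_bins = [
        Interval(gene.chrom, int(edges[i]), int(edges[i + 1]))
        for i in range(N_ORF_BINS)
    ]
    if gene.strand == "-":
        orf_bins = orf_bins[::-1]

    def _flank(start: int, end: int) -> Interval | None:
        start = max(0, start)
        if chrom_length is not None:
            end = min(end, chrom_length)
        return Interval(gene.chrom, start, end) if start < end else None

    flank = base
    left = _flank(gene.start - flank, gene.start)
    right = _flank(gene.end, gene.end + flank)
    upstream, downstream = (left, right) if gene.strand == "+" else (right, left)
    return [upstream, *orf_bins, downstream]


def _spans_by_chrom(clusters: Sequence[BindingCluster]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        by.setdefault(c.chrom, []).append((c.start, c.end))
    return {k: np.array(sorted(v)) for k, v in by.items()}


def cluster_distribution_profile(
    clusters: Sequence[BindingCluster],
    genes: Sequence[Feature],
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Percentage of cluster incidences per metagene bin.

    Each (cluster, bin) pair with >= 1 bp overlap counts one incidence: a
    cluster spanning k bins of a gene contributes k incidences, and
    percentages are taken over all incidences so the bins sum to 100.
    """
    spans = _spans_by_chrom(clusters)
    counts = np.zeros(N_ORF_BINS + 2)
    for gene in genes:
        chrom_spans = spans.get(gene.chrom)
        if chrom_spans is None:
            continue
        chrom_len = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        segs = segment_gene(gene, chrom_len)
        lo = gene.start - gene.length  # generous candidate window around gene
        hi = gene.end + gene.length
        cand = chrom_spans[(chrom_spans[:, 0] < hi) & (chrom_spans[:, 1] > lo)]
        for s, e in cand:
            for b, seg in enumerate(segs):
                if seg is not None and min(e, seg.end) > max(s, seg.start):
                    counts[b] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no cluster-bin incidences: nothing to profile")
    return MetageneProfile(100.0 * counts / total, "cluster_percent", len(genes))


def signal_mean_profile(
    smoothed: Mapping[str, SmoothedTrack],
    genes: Sequence[Feature],
    chrom_sizes: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Mean smoothed signal per metagene bin, pooled over genes."""
    if not genes:
        raise ValueError("empty gene list")
    sums = np.zeros(N_ORF_BINS + 2)
    ns = np.zeros(N_ORF_BINS + 2)
    for gene in genes:
        track = smoothed.get(gene.chrom)
        if track is None:
            continue
        chrom_len = chrom_sizes.get(gene.chrom) if chrom_sizes else None
        for b, seg in enumerate(segment_gene(gene, chrom_len)):
            if seg is None:
                continue
            lo = np.searchsorted(track.positions, seg.start, side="left")
            hi = np.searchsorted(track.positions, seg.end, side="left")
            if hi > lo:
                sums[b] += track.signal[lo:hi].sum()
                ns[b] += hi - lo
    empty = ns == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} metagene bin(s) contain no probes; values absent"
        )
    with np.errstate(invalid="ignore"):
        values = np.where(empty, np.nan, sums / np.where(empty, 1, ns))
    return MetageneProfile(values, "signal_mean", len(genes))


def stratify_by_length(
    genes: Sequence[Feature], n_strata: int
) -> list[list[Feature]]:
    """Split genes into equal-count length quantile strata (short to long).

    Ties are broken by gene id so the split is deterministic.
    """
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    if len(genes) < n_strata:
        raise ValueError("fewer genes than strata")
    ordered = sorted(genes, key=lambda g: (g.length, g.id))
    return [list(part) for part in np.array_split(np.array(ordered, dtype=object), n_strata)]


def stratified_profiles(
    genes: Sequence[Feature],
    n_strata: int,
    profile_fn: Callable[[Sequence[Feature]], MetageneProfile],
) -> list[MetageneProfile]:
    """Apply a profile function to each length stratum."""
    return [profile_fn(stratum) for stratum in stratify_by_length(genes, n_strata)]
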