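"""Structural statistics of gene sets and top-N occupancy ranking.

A gene set pulled out by any analysis (de-regulated genes, cluster-mapped
genes, top-occupancy genes) is characterised by comparing its length, G+C
and expression distributions against the genome with a two-sided
Mann–Whitney U test, and the highest-occupancy genes are ranked by the
maximum mean smoothed signal in a sliding window inside each ORF.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, pearsonr

from .genome import Feature, GenomeAnnotation
from .tiling import SmoothedTrack

__all__ = [
    "GeneSetComparison",
    "compare_to_genome",
    "top_n_by_sliding_window",
    "enrichment_expression_correlation",
    "GENE_ATTRIBUTES",
]

GENE_ATTRIBUTES = ("length", "gc_fraction", "expression_level")


def _attribute_values(genes: Iterable[Feature], attribute: str) -> np.ndarray:
    if attribute not in GENE_ATTRIBUTES:
        raise ValueError(f"unknown gene attribute {attribute!r}")
    vals = [getattr(g, attribute) for g in genes]
    if any(v is None for v in vals):
        raise ValueError(f"attribute {attribute!r} missing on some genes")
    return np.asarray(vals, dtype=float)


def _mwu_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U P-value.

    Exact for small samples: tie-free data go through scipy's exact
    distribution; tied data (the usual case here, since the set is part of
    the genome) through full permutation enumeration when the number of
    splits is tractable. Everything else uses the tie-corrected normal
    approximation.
    """
    n, m = len(x), len(y)
    small = min(n, m) <= 8
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if small and not has_ties:
        return float(mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    if small and math.comb(n + m, min(n, m)) <= 50_000:
        k = min(n, m)
        a, b = (x, y) if n <= m else (y, x)
        u_obs = float(np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))
        mean_u = k * len(b) / 2.0
        dev = abs(u_obs - mean_u) - 1e-12
        hits = total = 0
        for combo in itertools.combinations(range(n + m), k):
            total += 1
            sel = np.zeros(n + m, dtype=bool)
            sel[list(combo)] = True
            aa, bb = pooled[sel], pooled[~sel]
            u = float(np.sum(aa[:, None] > bb[None, :]) + 0.5 * np.sum(aa[:, None] == bb[None, :]))
            if abs(u - mean_u) >= dev:
                hits += 1
        return hits / total
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


@dataclass(frozen=True)
class GeneSetComparison:
    """One attribute of a gene set versus the genome."""

    attribute: str
    set_median: float
    genome_median: float
    p_value: float  # two-sided Mann-Whitney U, set vs all retained genes
    n_set: int
    n_genome: int


def compare_to_genome(
    gene_ids: Iterable[str],
    annotation: GenomeAnnotation,
    attribute: str,
    min_expression: float | None = None,
) -> GeneSetComparison:
    """Compare a gene set's attribute distribution to the genome's.

    The genome side is every annotated ORF (the set included); when
    ``min_expression`` is given, genes below that linear expression level
    are removed from both sides first, mirroring the expression floor used
    before such comparisons. The test is a two-sided Mann–Whitney U — exact
    for small tie-free samples, tie-corrected normal approximation
    otherwise.
    """
    genome = annotation.orfs
    if min_expression is not None:
        genome = [
            g
            for g in genome
            if g.expression_level is not None and g.expression_level >= min_expression
        ]
    by_id = {g.id: g for g in genome}
    ids = set(gene_ids)
    members = [by_id[g] for g in ids if g in by_id]
    if not members:
        raise ValueError("gene set empty after applying the expression floor")
    set_vals = _attribute_values(members, attribute)
    genome_vals = _attribute_values(genome, attribute)
    p = _mwu_two_sided(set_vals, genome_vals)
    return GeneSetComparison(
        attribute,
        float(np.median(set_vals)),
        float(np.median(genome_vals)),
        p,
        len(set_vals),
        len(genome_vals),
    )


def sliding_window_score(
    track: SmoothedTrack, gene: Feature, window_bp: int
) -> float | None:
    """Max mean signal over all window placements inside the ORF.

    Windows are anchored at probe positions (identical extrema on
    piecewise-constant probe data at a fraction of the cost of per-bp
    placement). ORFs shorter than the window are scored over their whole
    span. Genes with no probes return None.
    """
    pos = track.positions
    lo = np.searchsorted(pos, gene.start, side="left")
    hi = np.searchsorted(pos, gene.end, side="left")
    if hi <= lo:
        return None
    if gene.length < window_bp:
        return float(track.signal[lo:hi].mean())
    inside = pos[lo:hi]
    # candidate anchors: window content only changes when a boundary crosses
    # a probe, so placements starting at a probe or ending just before one
    # (plus the two gene-boundary placements) cover every distinct window
    anchors = np.unique(
        np.clip(
            np.concatenate([inside, inside - window_bp, [gene.start, gene.end - window_bp]]),
            gene.start,
            gene.end - window_bp,
        )
    )
    best = -np.inf
    for a in anchors:
        i = np.searchsorted(pos, a, side="left")
        j = np.searchsorted(pos, a + window_bp, side="left")
        if j > i:
            best = max(best, float(track.signal[i:j].mean()))
    if best == -np.inf:
        return float(track.signal[lo:hi].mean())
    return best


def top_n_by_sliding_window(
    smoothed: Mapping[str, SmoothedTrack],
    genes: Sequence[Feature],
    window_bp: int = 200,
    n: int = 500,
) -> list[tuple[str, float]]:
    """Rank genes by their best sliding-window mean signal; return the top n.

    Ties are broken by gene id; genes whose chromosome has no track or that
    contain no probes are skipped (with a warning).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    scored: list[tuple[str, float]] = []
    skipped = 0
    short = 0
    for gene in genes:
        track = smoothed.get(gene.chrom)
        score = sliding_window_score(track, gene, window_bp) if track else None
        if score is None:
            skipped += 1
            continue
        if gene.length < window_bp:
            short += 1
        scored.append((gene.id, score))
    if skipped:
        warnings.warn(f"{skipped} gene(s) without probes skipped from ranking")
    if short:
        warnings.warn(
            f"{short} gene(s) shorter than the {window_bp}-bp window scored over their whole ORF"
        )
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[: min(n, len(scored))]


def enrichment_expression_correlation(
    enrichment: Mapping[str, float], annotation: GenomeAnnotation
) -> float:
    """Pearson r between per-gene occupancy level and log2 expression."""
    pairs = [
        (level, gene.expression_level)
        for gene_id, level in enrichment.items()
        for gene in [annotation.orf(gene_id)]
        if level is not None and gene.expression_level is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 genes with both enrichment and expression")
    x = np.array([p[0] for p in pairs])
    y = np.log2([p[1] for p in pairs])
    if float(np.std(x)) == 0.0 or float(np.std(y)) == 0.0:
        raise ValueError("zero-variance input to correlation")
    return float(pearsonr(x, y).statistic)
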