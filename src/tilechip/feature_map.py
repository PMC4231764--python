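"""Mapping binding clusters onto annotated features.

Covers the feature-class tally (how many ORFs, centromeres, telomeres, ...
are touched by at least one cluster), per-gene enrichment calls with mean
occupancy levels, and hypergeometric significance of gene-set overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clusters import BindingCluster
from .genome import FEATURE_CLASSES, GenomeAnnotation
from .tiling import SmoothedTrack

__all__ = [
    "FeatureMapTable",
    "GeneEnrichment",
    "OverlapResult",
    "map_clusters_to_features",
    "call_enriched_genes",
    "enrichment_frame",
    "overlap_test",
]


@dataclass(frozen=True)
class FeatureMapTable:
    """Per feature class: features overlapped by >= 1 cluster, and totals."""

    mapped: dict[str, int]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        for cls, count in self.mapped.items():
            if count > self.totals.get(cls, 0):
                raise ValueError(f"{cls}: mapped count exceeds total")

    def to_frame(self) -> pd.DataFrame:
        classes = [c for c in FEATURE_CLASSES if c in self.totals]
        return pd.DataFrame(
            {
                "feature_class": classes,
                "mapped": [self.mapped[c] for c in classes],
                "total": [self.totals[c] for c in classes],
            }
        )


def _cluster_spans_by_chrom(
    clusters: Iterable[BindingCluster],
) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    return {k: np.array(sorted(v)) for k, v in by_chrom.items()}


def _overlaps_any(spans: np.ndarray | None, start: int, end: int) -> bool:
    if spans is None or spans.size == 0:
        return False
    # spans sorted by start; overlap iff span.start < end and span.end > start
    i = np.searchsorted(spans[:, 0], end, side="left")
    return bool(np.any(spans[:i, 1] > start))


def map_clusters_to_features(
    clusters: Sequence[BindingCluster], annotation: GenomeAnnotation
) -> FeatureMapTable:
    """Count, per feature class, the features touched by >= 1 bp of cluster."""
    spans = _cluster_spans_by_chrom(clusters)
    mapped = {c: 0 for c in FEATURE_CLASSES}
    totals = {c: 0 for c in FEATURE_CLASSES}
    for f in annotation.features:
        totals[f.feature_class] += 1
        if _overlaps_any(spans.get(f.chrom), f.start, f.end):
            mapped[f.feature_class] += 1
    return FeatureMapTable(mapped, totals)


@dataclass(frozen=True)
class GeneEnrichment:
    """Per-gene cluster-overlap call and mean smoothed occupancy."""

    gene_id: str
    enriched: bool
    enrichment_level: float | None  # mean smoothed log2 signal over ORF probes


def call_enriched_genes(
    clusters: Sequence[BindingCluster],
    smoothed: Mapping[str, SmoothedTrack],
    annotation: GenomeAnnotation,
) -> list[GeneEnrichment]:
    """Call a gene enriched iff >= 1 cluster overlaps its ORF by >= 1 bp.

    The enrichment level — the mean smoothed signal over probes inside the
    ORF span — is computed for every gene regardless of the call, so
    enriched and non-enriched genes can be compared on one scale. Genes with
    no probes get a level of None.
    """
    spans = _cluster_spans_by_chrom(clusters)
    out: list[GeneEnrichment] = []
    for gene in annotation.orfs:
        track = smoothed.get(gene.chrom)
        level: float | None = None
        if track is not None:
            lo = np.searchsorted(track.positions, gene.start, side="left")
            hi = np.searchsorted(track.positions, gene.end, side="left")
            if hi > lo:
                level = float(track.signal[lo:hi].mean())
        enriched = _overlaps_any(spans.get(gene.chrom), gene.start, gene.end)
        out.append(GeneEnrichment(gene.id, enriched, level))
    return out


def enrichment_frame(enrichments: Sequence[GeneEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in enrichments],
            "enriched": [e.enriched for e in enrichments],
            "enrichment_level": [e.enrichment_level for e in enrichments],
        }
    )


@dataclass(frozen=True)
class OverlapResult:
    n_overlap: int
    fraction: float  # overlap relative to the smaller set
    p_value: float


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Hypergeometric upper-tail test of two gene sets' overlap.

    P is the probability of observing at least the seen intersection when
    |B| genes are drawn uniformly without replacement from the universe, of
    which |A| are marked. Symmetric in A and B. The reported fraction is
    |A & B| / min(|A|, |B|) (the "coincident" share of the smaller set).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both gene sets must be subsets of the universe")
    k = len(a & b)
    if a and b:
        p = float(hypergeom.sf(k - 1, len(u), len(a), len(b)))
        fraction = k / min(len(a), len(b))
    else:
        p, fraction = 1.0, 0.0
    return OverlapResult(k, fraction, min(1.0, p))
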