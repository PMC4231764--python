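"""Gene-expression analysis: floor filtering, de-regulated-gene calling,
profile correlation and clustering, and qPCR-style relative quantitation.

Expression values are gene-level, linear-scale arbitrary units (model-based
array summaries). The de-regulation rule combines three filters: at least a
1.5-fold change between replicate means, an absolute difference above 100
A.U., and a difference P-value below 0.05 — after removing genes whose
value falls below the expression floor (600 A.U. by default) in at least
half of all samples. The difference P-value is a Welch t-test on log2
values across replicates, a robust stand-in for a model-based array
difference test at n = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, ttest_ind

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "apply_expression_floor",
    "call_de",
    "profile_correlation",
    "cluster_profiles",
    "ProfileClustering",
    "relative_quantitation",
    "RelativeQuant",
    "DifferentialExpression",
    "DEResults",
    "DEFAULT_FOLD",
    "DEFAULT_MIN_DIFFERENCE",
    "DEFAULT_ALPHA",
    "DEFAULT_FLOOR",
    "DEFAULT_FLOOR_FRACTION",
]

DEFAULT_FOLD = 1.5
DEFAULT_MIN_DIFFERENCE = 100.0
DEFAULT_ALPHA = 0.05
DEFAULT_FLOOR = 600.0
DEFAULT_FLOOR_FRACTION = 0.5


@dataclass
class ExpressionMatrix:
    """Genes x samples linear-scale expression with sample metadata.

    ``values`` is indexed by gene id with one column per sample;
    ``samples`` maps each column to (strain, replicate).
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # columns: sample, strain, replicate

    def __post_init__(self) -> None:
        if list(self.samples["sample"]) != list(self.values.columns):
            raise ValueError("sample metadata must match value columns in order")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression values must be positive (linear A.U.)")

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.samples["strain"]))

    def strain_columns(self, strain: str) -> list[str]:
        cols = list(self.samples.loc[self.samples["strain"] == strain, "sample"])
        if not cols:
            raise KeyError(f"no samples for strain {strain!r}")
        return cols

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with ``strain:replicate`` column headers."""
        out = self.values.copy()
        out.columns = [
            f"{s}:{r}" for s, r in zip(self.samples["strain"], self.samples["replicate"])
        ]
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene")
        strains, reps = zip(*(c.split(":", 1) for c in values.columns))
        samples = pd.DataFrame(
            {"sample": list(values.columns), "strain": strains, "replicate": reps}
        )
        return cls(values, samples)


def apply_expression_floor(
    matrix: ExpressionMatrix,
    floor: float = DEFAULT_FLOOR,
    fraction: float = DEFAULT_FLOOR_FRACTION,
) -> tuple[list[str], list[str]]:
    """Partition genes into (retained, filtered_low).

    A gene is filtered when its value falls below ``floor`` in at least
    ``fraction`` of all samples, pooled across strains.
    """
    vals = matrix.values.to_numpy()
    n_below = (vals < floor).sum(axis=1)
    # "at least" the given fraction: 3 of 6 samples counts at fraction 0.5
    low = n_below >= fraction * vals.shape[1]
    genes = list(matrix.values.index)
    retained = [g for g, flag in zip(genes, low) if not flag]
    filtered = [g for g, flag in zip(genes, low) if flag]
    return retained, filtered


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression record."""

    gene_id: str
    wt_mean: float
    mut_mean: float
    fold_change: float  # mutant/wild-type linear mean ratio
    abs_difference: float
    p_value: float
    call: str  # up | down | unchanged | filtered_low


def call_de(
    matrix: ExpressionMatrix,
    wild_type: str,
    mutant: str,
    fold: float = DEFAULT_FOLD,
    min_difference: float = DEFAULT_MIN_DIFFERENCE,
    alpha: float = DEFAULT_ALPHA,
    floor: float = DEFAULT_FLOOR,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> list[DERecord]:
    """Call de-regulated genes between a mutant and its wild type.

    Fold changes come from linear replicate means; the threshold is applied
    symmetrically (up: FC >= fold, down: FC <= 1/fold). P-values are
    two-sided Welch t-tests on log2 values. The expression floor is applied
    first, marking low genes ``filtered_low`` without testing them.
    """
    wt_cols = matrix.strain_columns(wild_type)
    mut_cols = matrix.strain_columns(mutant)
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise ValueError("need >= 2 replicates per strain for the difference test")
    retained, filtered = apply_expression_floor(matrix, floor, floor_fraction)
    filtered_set = set(filtered)

    wt = matrix.values[wt_cols].to_numpy()
    mut = matrix.values[mut_cols].to_numpy()
    wt_mean = wt.mean(axis=1)
    mut_mean = mut.mean(axis=1)
    fc = mut_mean / wt_mean
    diff = np.abs(mut_mean - wt_mean)
    pvals = ttest_ind(np.log2(mut), np.log2(wt), axis=1, equal_var=False).pvalue

    records = []
    for i, gene in enumerate(matrix.values.index):
        if gene in filtered_set:
            call = "filtered_low"
        elif fc[i] >= fold and diff[i] > min_difference and pvals[i] < alpha:
            call = "up"
        elif fc[i] <= 1.0 / fold and diff[i] > min_difference and pvals[i] < alpha:
            call = "down"
        else:
            call = "unchanged"
        records.append(
            DERecord(
                gene, float(wt_mean[i]), float(mut_mean[i]), float(fc[i]),
                float(diff[i]), float(pvals[i]), call,
            )
        )
    return records


def de_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")


def profile_correlation(
    de_a: Mapping[str, float] | Sequence[DERecord],
    de_b: Mapping[str, float] | Sequence[DERecord],
) -> float:
    """Pearson r of log2 fold-changes over the shared gene universe.

    Accepts either gene->fold-change (linear) mappings or DE record lists;
    genes called ``filtered_low`` in either input are excluded.
    """

    def _as_map(de) -> dict[str, float]:
        if isinstance(de, Mapping):
            return dict(de)
        return {r.gene_id: r.fold_change for r in de if r.call != "filtered_low"}

    a, b = _as_map(de_a), _as_map(de_b)
    shared = sorted(a.keys() & b.keys())
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes for a correlation")
    va = np.log2([a[g] for g in shared])
    vb = np.log2([b[g] for g in shared])
    return float(pearsonr(va, vb).statistic)


@dataclass(frozen=True)
class ProfileClustering:
    """Complete-linkage clustering of expression profiles (1 - Pearson r)."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy hierarchical-clustering format
    leaf_order: list[str]
    kept_genes: list[str]


def cluster_profiles(
    log2_fc: pd.DataFrame, top_fraction: float = 0.5
) -> ProfileClustering:
    """Cluster log2 fold-change profiles (columns) hierarchically.

    Genes are ranked by their maximum absolute log2 fold-change across
    profiles and the top ``top_fraction`` kept (the heatmap gene
    selection); profile distance is 1 - Pearson correlation; merges use
    complete linkage.
    """
    if log2_fc.shape[1] < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    score = log2_fc.abs().max(axis=1)
    n_keep = max(2, int(round(top_fraction * len(score))))
    kept = score.sort_values(ascending=False, kind="stable").index[:n_keep]
    sub = log2_fc.loc[kept]
    for col in sub.columns:
        if float(sub[col].std()) == 0.0:
            raise ValueError(f"profile {col!r} has zero variance among kept genes")
    corr = np.corrcoef(sub.to_numpy().T)
    dist = 1.0 - corr
    iu = np.triu_indices(dist.shape[0], k=1)
    z = linkage(dist[iu], method="complete")
    order = [log2_fc.columns[i] for i in leaves_list(z)]
    return ProfileClustering(list(log2_fc.columns), z, order, list(kept))


@dataclass(frozen=True)
class RelativeQuant:
    """Normalised qPCR-style quantitation: per-sample values, mean, SEM."""

    values: np.ndarray
    mean: float
    sem: float


def relative_quantitation(
    target, normalizer, reference_target=None, reference_normalizer=None
) -> RelativeQuant:
    """Relative quantitation of paired target/normalizer measurements.

    Per sample the ratio target/normalizer is formed (e.g. a gene vs the
    SCR1 reference transcript, or a ChIP region vs an intergenic control);
    when a reference condition is supplied, values are further divided by
    the reference's mean ratio (normalisation to wild-type levels). Returns
    the per-sample values with their mean and standard error (sd/sqrt(n),
    sample sd).
    """
    t = np.asarray(target, dtype=float)
    n = np.asarray(normalizer, dtype=float)
    if t.shape != n.shape or t.size == 0:
        raise ValueError("target and normalizer must be non-empty and paired")
    if np.any(n == 0):
        raise ValueError("normalizer measurements must be non-zero")
    ratios = t / n
    if reference_target is not None:
        rt = np.asarray(reference_target, dtype=float)
        rn = np.asarray(reference_normalizer, dtype=float)
        if np.any(rn == 0):
            raise ValueError("reference normalizer measurements must be non-zero")
        ratios = ratios / float(np.mean(rt / rn))
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else 0.0
    return RelativeQuant(ratios, mean, sem)


# ---------------------------------------------------------------------------
# Model-style wrapper


class DifferentialExpression:
    """De-regulated-gene model for one mutant vs wild-type contrast.

    A thin fit/results interface over :func:`call_de`::

        res = DifferentialExpression(matrix, "wild_type", "mutant").fit()
        print(res.summary())
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        wild_type: str,
        mutant: str,
        fold: float = DEFAULT_FOLD,
        min_difference: float = DEFAULT_MIN_DIFFERENCE,
        alpha: float = DEFAULT_ALPHA,
        floor: float = DEFAULT_FLOOR,
        floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    ) -> None:
        self.matrix = matrix
        self.wild_type = wild_type
        self.mutant = mutant
        self.params = dict(
            fold=fold,
            min_difference=min_difference,
            alpha=alpha,
            floor=floor,
            floor_fraction=floor_fraction,
        )

    def fit(self) -> "DEResults":
        records = call_de(self.matrix, self.wild_type, self.mutant, **self.params)
        return DEResults(self, records)


@dataclass
class DEResults:
    model: DifferentialExpression
    records: list[DERecord]
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.frame = de_frame(self.records)

    def genes(self, call: str) -> list[str]:
        return [r.gene_id for r in self.records if r.call == call]

    @property
    def counts(self) -> dict[str, int]:
        out = {"up": 0, "down": 0, "unchanged": 0, "filtered_low": 0}
        for r in self.records:
            out[r.call] += 1
        return out

    def summary(self) -> str:
        c = self.counts
        p = self.model.params
        lines = [
            "Differential expression: "
            f"{self.model.mutant} vs {self.model.wild_type}",
            f"  genes tested        {len(self.records) - c['filtered_low']}"
            f" (of {len(self.records)}; floor {p['floor']:g} A.U."
            f" in >= {p['floor_fraction']:.0%} of samples)",
            f"  up-regulated        {c['up']}",
            f"  down-regulated      {c['down']}",
            f"  unchanged           {c['unchanged']}",
            f"  thresholds          fold >= {p['fold']:g}, "
            f"|difference| > {p['min_difference']:g} A.U., P < {p['alpha']:g}",
        ]
        return "\n".join(lines)
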