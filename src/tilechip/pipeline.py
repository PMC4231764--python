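"""End-to-end pipeline: simulate -> normalize -> smooth -> call -> map ->
profile -> rank -> differential expression.

Every stage is a pure function of its inputs and the single seeded
generator behind the simulation, so re-running a configuration reproduces
every artefact byte for byte. Outputs are plain-text files plus one
machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .clusters import call_clusters_genome, cluster_set_stats, compare_cluster_lengths
from .expression import DifferentialExpression, profile_correlation
from .feature_map import call_enriched_genes, enrichment_frame, map_clusters_to_features, overlap_test
from .genestats import compare_to_genome, top_n_by_sliding_window, GENE_ATTRIBUTES
from .genome import write_gff3
from .metagene import BIN_LABELS, cluster_distribution_profile, signal_mean_profile
from .simulate import SimulationConfig, simulate_chip_tracks, simulate_expression, simulate_genome
from .tiling import quantile_normalize, smooth_track

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-study run (standard defaults)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bandwidth_bp: int = 150
    p_threshold: float = 0.01
    min_run_bp: int = 100
    max_gap_bp: int = 250
    fold: float = 1.5
    min_difference: float = 100.0
    alpha: float = 0.05
    floor: float = 600.0
    floor_fraction: float = 0.5
    window_bp: int = 200
    top_n: int = 500
    outdir: Path = Path("tilechip_out")

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 < self.p_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("p_threshold and alpha must lie in (0, 1)")
        if min(self.min_run_bp, self.max_gap_bp, self.bandwidth_bp, self.window_bp) < 0:
            raise ValueError("bp parameters must be non-negative")
        if self.fold < 1:
            raise ValueError("fold threshold must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in sorted(x.items())}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return None if np.isnan(x) else round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and write all artefacts to ``outdir``.

    Returns the summary dictionary that is also written as JSON.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    annotation = simulate_genome(sim)
    write_gff3(annotation, out / "annotation.gff3")
    (out / "chrom.sizes").write_text(
        "\n".join(f"{c}\t{l}" for c, l in annotation.chromosomes.items()) + "\n"
    )

    cluster_kwargs = dict(
        p_threshold=config.p_threshold,
        min_run_bp=config.min_run_bp,
        max_gap_bp=config.max_gap_bp,
    )
    summary: dict = {"chip": {}, "expression": {}}

    experiments = {
        "thp1_like": ("trex2", "wild_type", 0),
        "sac3_like": ("trex2", "wild_type", 1),
        "rrm3_wt": ("rrm3", "wild_type", 0),
        "rrm3_mutant": ("rrm3", "mutant", 0),
    }
    smoothed_all, clusters_all, enriched_all = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, (factor, condition, instance) in experiments.items():
            chip = simulate_chip_tracks(annotation, sim, factor, condition, instance)
            tracks = {c: quantile_normalize(t) for c, t in chip.tracks.items()}
            tio.write_probe_tracks(tracks, out / f"{name}")
            smoothed = {
                c: smooth_track(t, bandwidth_bp=config.bandwidth_bp)
                for c, t in tracks.items()
            }
            tio.write_smoothed(smoothed, out / f"{name}")
            clusters = call_clusters_genome(smoothed, **cluster_kwargs)
            tio.write_clusters_bed(clusters, out / f"{name}.clusters.bed")
            chip.planted_frame().to_csv(out / f"{name}.planted.tsv", sep="\t", index=False)

            stats = cluster_set_stats(clusters, annotation)
            table = map_clusters_to_features(clusters, annotation)
            table.to_frame().to_csv(out / f"{name}.feature_map.tsv", sep="\t", index=False)
            enriched = call_enriched_genes(clusters, smoothed, annotation)
            enrichment_frame(enriched).to_csv(out / f"{name}.enriched.tsv", sep="\t", index=False)

            genes = annotation.orfs
            profile_c = cluster_distribution_profile(clusters, genes, annotation.chromosomes)
            profile_s = signal_mean_profile(smoothed, genes, annotation.chromosomes)
            with open(out / f"{name}.metagene.tsv", "w") as fh:
                fh.write("bin\tcluster_percent\tsignal_mean\n")
                for label, cp, sm in zip(BIN_LABELS, profile_c.bins, profile_s.bins):
                    fh.write(f"{label}\t{float(cp)!r}\t{float(sm)!r}\n")

            ranked = top_n_by_sliding_window(
                smoothed, genes, window_bp=config.window_bp, n=config.top_n
            )
            with open(out / f"{name}.top_genes.tsv", "w") as fh:
                fh.write("gene_id\tscore\n")
                for gid, score in ranked:
                    fh.write(f"{gid}\t{float(score)!r}\n")

            smoothed_all[name] = smoothed
            clusters_all[name] = clusters
            enriched_all[name] = enriched
            summary["chip"][name] = {
                "n_clusters": stats.n_clusters,
                "mean_cluster_length_bp": stats.mean_length_bp,
                "genome_coverage_fraction": stats.genome_coverage_fraction,
                "fraction_peaks_in_orfs": stats.fraction_peaks_in_orfs,
                "n_enriched_genes": sum(e.enriched for e in enriched),
                "metagene_cluster_percent": list(profile_c.bins),
                "metagene_signal_mean": list(profile_s.bins),
                "top_gene_median_expression": float(
                    np.median([annotation.orf(g).expression_level for g, _ in ranked])
                )
                if ranked
                else None,
            }

        # cross-experiment comparisons
        universe = [g.id for g in annotation.orfs]
        set_a = {e.gene_id for e in enriched_all["thp1_like"] if e.enriched}
        set_b = {e.gene_id for e in enriched_all["sac3_like"] if e.enriched}
        if set_a and set_b:
            ov = overlap_test(set_a, set_b, universe)
            summary["chip"]["enriched_overlap"] = {
                "n_overlap": ov.n_overlap,
                "fraction": ov.fraction,
                "p_value": ov.p_value,
            }
        if clusters_all["rrm3_wt"] and clusters_all["rrm3_mutant"]:
            summary["chip"]["rrm3_mutant_vs_wt_length_p"] = compare_cluster_lengths(
                clusters_all["rrm3_mutant"], clusters_all["rrm3_wt"]
            )

        # expression analysis with two mutants of the same complex
        expr = simulate_expression(annotation, sim, n_mutants=2, shared_fraction=0.8)
        expr.matrix.to_tsv(out / "expression.tsv")
        expr.labels.to_csv(out / "de_labels.tsv", sep="\t", index=False)
        de_results = {}
        for strain in ("mutant1", "mutant2"):
            res = DifferentialExpression(
                expr.matrix,
                "wild_type",
                strain,
                fold=config.fold,
                min_difference=config.min_difference,
                alpha=config.alpha,
                floor=config.floor,
                floor_fraction=config.floor_fraction,
            ).fit()
            res.frame.to_csv(out / f"de_{strain}.tsv", sep="\t")
            de_results[strain] = res
            summary["expression"][strain] = res.counts
        summary["expression"]["mutant_profile_pearson_r"] = profile_correlation(
            de_results["mutant1"].records, de_results["mutant2"].records
        )
        down = de_results["mutant1"].genes("down")
        if len(down) >= 3:
            summary["expression"]["down_gene_stats"] = {
                attr: {
                    "set_median": cmp.set_median,
                    "genome_median": cmp.genome_median,
                    "p_value": cmp.p_value,
                }
                for attr in GENE_ATTRIBUTES
                for cmp in [compare_to_genome(down, annotation, attr)]
            }

    summary = _round(summary)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "config.json").write_text(
        json.dumps(
            _round(
                {
                    **{
                        k: v
                        for k, v in dataclasses.asdict(config).items()
                        if k not in ("simulation", "outdir")
                    },
                    "simulation": dataclasses.asdict(sim),
                }
            ),
            indent=2,
            sort_keys=True,
            default=str,
        )
        + "\n"
    )
    return summary
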