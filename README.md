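# tilechip

Analysis of ChIP-chip tiling-array occupancy data and matched gene-expression
matrices, of the kind used to map where a chromatin-associated factor sits on
a yeast genome and how its loss changes transcription. The package covers the
full chain — per-probe signal estimation, binding-cluster detection,
genomic-feature mapping, strand-aware metagene profiling, top-N
sliding-window gene ranking, and de-regulated-gene calling with overlap and
structural statistics — together with a synthetic-data generator that plants
every signal structure the pipeline is supposed to detect, so the whole
stack is testable end-to-end without any array download.

It is written for computational biologists who want either the library (each
stage is an importable function over plain `numpy`/`pandas` containers) or
the `tilechip` command-line pipeline over bedGraph/GFF/BED/TSV files.

## The statistics at the core

**Per-probe signal.** Probes report log2(IP/SUP) ratios (immunoprecipitate
over supernatant). At each probe position *p*, the ratios of all replicate
probes within a bandwidth *h* (default 150 bp, i.e. ~300 bp effective
resolution at 50-bp spacing) are pooled into a window sample
*x₁…xₙ*. The signal estimate is the Hodges–Lehmann pseudo-median

> θ̂(p) = median{ (xᵢ + xⱼ)/2 : i ≤ j },

and the change P-value is the one-sided Wilcoxon signed-rank probability of
a positive median (zeros dropped, midranks for ties; exact null distribution
for n ≤ 25 via the generating function over midranks, tie-corrected normal
approximation with continuity correction beyond).

**Binding clusters.** A probe qualifies when θ̂ > 0 and P < 0.01. Qualifying
probes chain while consecutive gaps are ≤ 250 bp *and* the estimated signal
stays positive across the whole spanned range; chains spanning < 100 bp are
discarded. Cluster sets are summarised by mean length, fraction of the
genome covered, and the fraction of cluster peaks inside ORFs; two sets'
length distributions are compared by a two-sided Mann–Whitney U test.

**Metagene profiles.** Each ORF is cut into 10 equal segments ordered
5′→3′ along transcription plus same-length promoter and terminator flanks.
Profiles report either the percentage of cluster–segment incidences per
segment (summing to 100) or the mean smoothed signal per segment, optionally
stratified by gene length.

**De-regulated genes.** Genes below 600 A.U. (linear model-based expression)
in ≥ 50% of samples are removed; the rest are called up/down when the
mutant/wild-type replicate-mean fold change is ≥ 1.5 (or ≤ 1/1.5), the
absolute difference exceeds 100 A.U., and a two-sided Welch t-test on log2
values gives P < 0.05. Gene-set structure (length, G+C, expression vs the
genome) uses Mann–Whitney U; set overlaps use the hypergeometric upper
tail; expression profiles are compared by Pearson correlation of log2
fold-changes and clustered by complete linkage on 1 − r distances.

## Worked example

```python
import numpy as np
import tilechip as tc

cfg = tc.SimulationConfig(seed=42)                     # 400-gene toy genome
ann = tc.simulate_genome(cfg)
chip = tc.simulate_chip_tracks(ann, cfg, factor="trex2")
tracks = {c: tc.quantile_normalize(t) for c, t in chip.tracks.items()}
smoothed = {c: tc.smooth_track(t, bandwidth_bp=150) for c, t in tracks.items()}
clusters = tc.call_clusters_genome(smoothed, p_threshold=0.01,
                                   min_run_bp=100, max_gap_bp=250)
stats = tc.cluster_set_stats(clusters, ann)
print(f"{stats.n_clusters} clusters, mean length {stats.mean_length_bp:.0f} bp, "
      f"{100*stats.genome_coverage_fraction:.1f}% genome coverage, "
      f"{100*stats.fraction_peaks_in_orfs:.1f}% of peaks inside ORFs")

profile = tc.cluster_distribution_profile(clusters, ann.orfs, ann.chromosomes)
print("cluster % per gene segment (5'->3'):", np.round(profile.bins[1:-1], 1))

expr = tc.simulate_expression(ann, cfg)
res = tc.DifferentialExpression(expr.matrix, "wild_type", "mutant").fit()
print(res.summary())
```

prints

```
199 clusters, mean length 1032 bp, 25.7% genome coverage, 98.0% of peaks inside ORFs
cluster % per gene segment (5'->3'): [ 3.5  7.8  9.4 10.3 10.5 10.8 10.9 11.  10.9 10.5]
Differential expression: mutant vs wild_type
  genes tested        214 (of 400; floor 600 A.U. in >= 50% of samples)
  up-regulated        5
  down-regulated      18
  unchanged           191
  thresholds          fold >= 1.5, |difference| > 100 A.U., P < 0.05
```

The cluster percentages rise from the 5′ towards the 3′ segments — the
planted co-transcriptional occupancy gradient recovered by the caller — and
the de-regulated genes are the planted subset that survives the expression
floor and the three-filter rule.

The same stages are available as CLI subcommands
(`tilechip simulate | normalize | smooth | callclusters | map | metagene |
rank | de | report`); `tilechip report` runs the whole pipeline and writes
per-stage text artefacts plus a machine-readable `summary.json` that is
byte-identical across re-runs with the same configuration.

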