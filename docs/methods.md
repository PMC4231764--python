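# Methods

## Scope and model

`tilechip` analyses two-channel tiling-array occupancy data. The observable
is, per probe, a log2(IP/SUP) ratio; the underlying model is a piecewise
occupancy field: zero outside bound regions, positive within them, with
independent Gaussian noise per replicate on the log2 scale (equivalently
log-normal on ratios — the standard assumption for two-channel ratio data).
All genomic coordinates are 0-based half-open internally; GFF3 (1-based
closed) and BED (half-open) are converted only at the I/O boundary.

## Per-probe estimation

At each probe, all replicate values at probes within ±bandwidth (default
150 bp) are pooled. The location estimate is the Hodges–Lehmann
pseudo-median — the median of all Walsh averages (xᵢ+xⱼ)/2, i ≤ j — which is
robust to outlying probes and consistent with the paired rank test. The
change P-value is the one-sided Wilcoxon signed-rank probability that the
window median exceeds zero. Conventions, chosen once and fixed:

- zeros are dropped before ranking; ties receive midranks;
- for ≤ 25 non-zero values the null distribution is exact, computed by the
  generating-function (polynomial) method over doubled midranks, so it is
  valid under ties and identical to full 2ⁿ sign enumeration (a property
  the test suite verifies up to n = 12);
- beyond 25 values a normal approximation with continuity correction and
  tie-corrected variance is used; it agrees with the exact tail to < 0.01
  at n = 20–25;
- a window holding a single non-zero value returns P = 1 (a lone probe
  carries no evidence) with a warning;
- one-sided enrichment is tested, since binding clusters are defined on
  positive signal only.

Exact tails are memoised per midrank multiset, which makes genome-wide
smoothing O(n) in practice because tie-free windows of equal size share one
null distribution.

Quantile normalization of replicates replaces, per rank, each replicate's
value with the across-replicate mean of rank-matched values (stable
argsort), so all replicates end with identical sorted value multisets; the
operation is idempotent.

## Cluster calling

A probe qualifies when signal > 0 and P < 0.01 (raw, no multiplicity
correction — deliberately mirroring standard tiling practice for this rule
set). Qualifying probes chain while the genomic gap between consecutive
qualifying probes is ≤ 250 bp **and** every intervening probe has positive
signal — the stricter reading of "positive in the whole range", preventing
chains from bridging a negative dip; a flag (`require_positive_span=False`)
gives the lenient gap-only behaviour. The cluster span is
[first qualifying probe, last qualifying probe + 1), with no half-spacing
padding; spans under 100 bp (genomic span, not probe count) are discarded.
The peak is the leftmost maximum-signal probe (deterministic tie-break);
the mean signal averages chained qualifying probes only. The scan
implementation is verified, over hundreds of random tracks, against a
brute-force enumeration of maximal qualifying chains.

Genome coverage uses merged (distinct) cluster bp over total genome bp.
Cluster-length comparisons use the two-sided Mann–Whitney U test.

## Feature mapping and gene sets

A feature is "mapped" by a cluster set when any cluster overlaps it by
≥ 1 bp (no minimum-fraction rule; the threshold is exposed in the API). A
gene is "enriched" when its ORF (not flanks) is mapped; its enrichment level
is the mean smoothed signal over probes inside the ORF, computed for all
genes so enriched and non-enriched genes share a scale. Set-overlap
significance is the hypergeometric upper tail P(X ≥ observed) for drawing
|B| genes from the universe with |A| marked; the default universe is the
annotated ORF complement (callers can restrict it to floor-passing genes).

Gene-set structure (length, G+C fraction, log-linear expression) is
compared set-versus-genome with a two-sided Mann–Whitney U (the set remains
part of the genome side, so a self-comparison is exactly null). Because
the pooled sample then always contains ties, the small-sample exact path
uses full permutation enumeration (when the number of splits is ≤ 50 000)
rather than the tie-free exact distribution; large samples use the
tie-corrected normal approximation.

## Metagene profiles

Each ORF is divided into 10 genomic segments of equal length, remainder bp
assigned one each to the 3′-most segments (deterministic; bias below one
probe spacing), plus upstream and downstream flanks of the unit segment
length, clipped at chromosome ends. Bins are ordered along transcription, so
minus-strand genes run right-to-left genomically. In cluster-percent mode a
cluster overlapping k bins of a gene contributes k incidences and
percentages are over incidences, which is what makes the 12 bins sum to
exactly 100 while clusters may span bins. In signal-mean mode probe signals
are pooled per bin across genes; a probe-free bin is reported absent (NaN)
with a warning. Length stratification splits genes into equal-count
quantile strata with ties broken by gene id. The 3′-gradient statistic is
the Spearman correlation of bin value against bin index over the 10 ORF
bins.

## Sliding-window gene ranking

A gene's occupancy score is the maximum, over all placements of a 200-bp
window fully inside the ORF, of the mean probe signal in the window. Since
window content changes only when a boundary crosses a probe, the exact
optimum over all per-bp placements is attained on the finite candidate set
{probe positions} ∪ {probe positions − window} ∪ {gene boundaries}, which
is what the implementation enumerates (verified against per-bp brute
force). ORFs shorter than the window are scored over their whole span, with
a warning. Ranking is descending score with gene-id tie-break.

## De-regulated-gene calling

Linear-scale gene expression (arbitrary units from model-based array
summarisation) with ≥ 2 replicates per strain. Genes below the floor
(600 A.U.) in at least half of all samples, pooled across strains, are
excluded as unexpressed. A gene is called up (down) when all three hold:
replicate-mean fold change ≥ 1.5 (≤ 1/1.5); absolute mean difference
> 100 A.U.; two-sided Welch t-test on log2 replicate values P < 0.05. The
Welch test is this package's difference test — a robust, standard choice
for n = 3 arrays. No multiple-testing correction is applied, matching the
three-filter design. Swapping the strain labels maps up↔down exactly, and
calls are invariant to sample column order.

Profile comparisons use Pearson r of log2 fold-change vectors over the
shared floor-passing universe. Heatmap clustering keeps the 50% of genes
with the largest |log2 fold change| across profiles and agglomerates
profiles by complete linkage on 1 − Pearson r. qPCR-style relative
quantitation divides target by normalizer per sample, optionally rescales
by a reference condition's mean ratio, and reports mean ± SEM (sample sd /
√n).

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
exercised; its defaults are fixed and the tests run at those conditions.

*Genome.* 4 chromosomes × 200 kb carrying 400 non-overlapping ORFs
(~65% genic, yeast-like density), lengths log-normal (median 1.2 kb,
log-sd 0.45) clipped to [600 bp, 8 kb], random strands, ≥ 200 bp intergenic
gaps with the slack spread multinomially; G+C ~ Beta(40, 60) (mean 0.40);
expression log-normal (median 800 A.U., log-sd 1.0, so roughly 40% of genes
fall below the 600 A.U. floor). Telomeres cap each chromosome, a centromere
sits in the most central gap, and ARS / sn-snoRNA / RNAPIII features are
carved from gaps; introns sit inside a twentieth of the ORFs. The 600-bp
ORF floor exists because genes shorter than about twice the effective
300-bp resolution cannot display within-gene structure at 50-bp probe
spacing.

*Occupancy.* Half of the genes (70% under the mutant condition of the
replication-obstacle factor) are bound, selected by a propensity
coupling·z(log expression) + N(0,1); amplitudes rise monotonically with
within-bound propensity rank from ~0 to `amplitude_max` (2.0 log2 units), a
continuum that makes weakly bound genes yield partial, 3′-only clusters as
in real data. Within a bound ORF the true signal is
amplitude × (1 + g·(2t − 1)), t ∈ [0, 1] the strand-aware relative position,
with gradient g = 1 — occupancy proportional to position along the gene,
i.e. co-transcriptional loading with poor promoter binding. Replicate
noise is Gaussian, sd 0.3 log2 units. The "mutant" condition of the
Rrm3-like factor widens planted spans 1.5-fold, boosts amplitudes 1.3-fold
and tightens the expression coupling (1.0 → 2.5), producing longer
clusters, higher coverage and a more expression-skewed top gene set —
the directional phenomena the cluster statistics must recover. The
`instance` parameter redraws selection and replicate noise to emulate an
independent ChIP experiment of the same planted truth.

*Expression.* Wild-type replicate values scatter log-normally (sd 0.15
log2 units, ~10–15% CV) around each gene's annotated level; 8% of genes are
planted down- and 8% up-regulated with folds uniform in [2, 4], sampled
with log-linear covariate biases (coefficient 2.0 on standardised length,
G+C and log expression; sign-flipped on G+C/expression for up-regulated
genes). The coefficient is chosen so the planted structural effect is
detectable at desk-scale set sizes (~40 down-calls). A second mutant strain
can reuse a configurable fraction (default 80%) of the first's planted
assignments, emulating two mutants of one complex.

*Named studies.* Three frozen configurations adapt the genome to what each
benchmark measures, with all occupancy parameters at their defaults:
`low_noise_recovery` (noise 0.1, amplitude floor 0.5 so every planted span
is above the detection limit, intergenic gaps ≥ 600 bp so neighbouring
spans cannot legitimately fuse across the 250-bp chaining distance plus
smoothing smear — one-to-one span recovery is otherwise ill-posed);
`gradient_study` (300 genes ≥ 1.2 kb so each of the 10 segments spans ≥ 2
probe spacings); `de_study` (800 genes, expression only). Everything is a
pure function of (config, seed) via `numpy` `SeedSequence` streams keyed by
stage, factor, condition and instance.

*What the generator does not emulate* — and hence what passing tests do not
establish about real arrays: probe-level cross-hybridisation, spatial array
artefacts, sequence/GC-dependent probe response, dye bias, copy-number
structure, and probe densities of real tiling platforms (which are an order
of magnitude higher; the 50-bp grid is a desk-scale stand-in).
Recovery results quantify the analysis chain under the stated noise model,
not platform chemistry.

## Numerical choices and degenerate inputs

- Exact signed-rank tails: float accumulation over ≤ 2^25-count polynomials
  (exact in double precision); tail probabilities never round to 0.
- P-values are kept in (0, 1]; smoothed tracks store them directly and the
  bedGraph representation uses −log10 P.
- Empty windows cannot occur (a window always contains its own probe);
  empty tracks yield empty cluster lists; empty cluster sets yield
  n_clusters = 0 with absent summary fields.
- Peak ties break leftmost; ranking ties break by gene id; stratification
  ties break by gene id — every ordering in the package is deterministic.
- The pipeline rounds summary floats to 6 decimals and writes sorted JSON
  keys, making `summary.json` byte-identical across re-runs.

## Problem sizes

Default studies simulate 0.8–1.2 Mb genomes (16–24 k probes, 300–800
genes), chosen so the full test suite and the acceptance script each
complete in about a minute on one CPU while keeping per-stratum and
per-gene-set counts large enough for the planted effects to be
statistically unambiguous.

## Known limitations

- The smoothing bandwidth smears cluster boundaries by up to ±150 bp, which
  flattens within-gene positional profiles for sub-kilobase genes; the
  metagene gradient analyses therefore use the ≥ 1.2 kb study.
- The raw P < 0.01 probe rule admits a floor of false clusters proportional
  to genome size divided by bandwidth (the signed-rank test is
  scale-free, so lowering noise does not remove them); precision of span
  recovery is bounded accordingly.
- The exact Mann–Whitney path enumerates splits only up to 50 000
  combinations; above that, tied data fall back to the asymptotic
  approximation even for small set sizes.
- Enrichment levels average over whole ORFs, diluting 3′-restricted signal
  for long genes; no within-ORF weighting is attempted.
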