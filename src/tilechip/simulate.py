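"""Synthetic genomes, tiling tracks and expression matrices with planted truth.

The generator emulates the signal structures of a yeast ChIP-chip /
expression study at desk scale: a toy multi-chromosome genome of
non-overlapping ORFs (log-normal lengths, beta-distributed G+C, log-normal
expression) plus a sprinkling of non-ORF features; probe tracks at ~50-bp
spacing in which a transcription-coupled factor occupies a subset of genes
with an occupancy gradient rising towards the 3' end and an amplitude that
grows with expression level; and triplicate expression matrices in which
planted up/down-regulated genes are biased towards long, G+C-rich,
highly-expressed genes. A second, replication-obstacle-marking factor
("Rrm3-like") co-localises with the first but, under a "mutant" condition,
occupies more genes with wider planted spans and a tighter coupling to
expression.

Every output is a pure function of (config, seed); ground truth (planted
spans, DE labels) is always returned machine-readably for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Feature, GenomeAnnotation, Interval
from .tiling import ProbeTrack

__all__ = [
    "DEConfig",
    "SimulationConfig",
    "PlantedSpan",
    "ChipSimulation",
    "ExpressionSimulation",
    "simulate_genome",
    "simulate_chip_tracks",
    "simulate_expression",
]

_FACTOR_CODES = {"trex2": 11, "rrm3": 12}
_CONDITION_CODES = {"wild_type": 21, "mutant": 22}


@dataclass(frozen=True)
class DEConfig:
    """Planted differential-expression structure.

    ``bias_*`` are log-linear weights on standardised gene covariates used
    when sampling which genes are de-regulated: down-regulated genes are
    drawn with probability increasing in length, G+C and expression (all
    three biases applied with positive sign), up-regulated genes with the
    length bias positive but the G+C and expression biases negated —
    mirroring the structural asymmetry seen for transcription/export-mutant
    expression changes. Folds are drawn uniformly from ``fold_range``.
    """

    fraction_up: float = 0.08
    fraction_down: float = 0.08
    fold_range: tuple[float, float] = (2.0, 4.0)
    bias_length: float = 2.0
    bias_gc: float = 2.0
    bias_expression: float = 2.0
    noise_sd_log2: float = 0.15  # replicate noise, ~10-15% CV typical of arrays

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_up + self.fraction_down <= 1:
            raise ValueError("DE fractions must sum to within [0, 1]")
        if self.fold_range[0] < 1:
            raise ValueError("planted folds must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults used throughout.

    Probe spacing 50 bp with the downstream 150-bp smoothing bandwidth gives
    an effective ~300-bp resolution. ``gradient_strength`` g tilts the
    within-ORF occupancy linearly from (1 - g) at the 5' end to (1 + g) at
    the 3' end; ``amplitude_max`` (log2 units) scales the occupancy of the
    most strongly bound gene, with a monotone link to expression rank.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length_bp: int = 200_000
    probe_spacing_bp: int = 50
    n_orfs: int = 400  # ~65% genic at the default genome size, yeast-like
    orf_length_log_mean: float = math.log(1200.0)
    orf_length_log_sd: float = 0.45
    # genes shorter than ~2x the effective 300-bp resolution cannot show
    # within-gene structure at 50-bp probe spacing, hence the 600-bp floor
    orf_length_range: tuple[int, int] = (600, 8000)
    min_intergenic_bp: int = 200
    gc_beta: tuple[float, float] = (40.0, 60.0)  # mean 0.40, yeast-like
    expression_log_mean: float = math.log(800.0)
    expression_log_sd: float = 1.0
    gradient_strength: float = 1.0
    amplitude_max: float = 2.0
    amplitude_floor_fraction: float = 0.0
    bound_fraction: float = 0.5
    expression_coupling: float = 1.0
    noise_sd: float = 0.3
    n_chip_replicates: int = 2
    n_expr_replicates: int = 3
    de: DEConfig = field(default_factory=DEConfig)
    # "mutant" Rrm3-like condition: wider planted spans over more genes,
    # higher amplitude, and occupancy more tightly coupled to expression.
    mutant_cluster_elongation: float = 1.5
    mutant_bound_fraction: float = 0.7
    mutant_amplitude_boost: float = 1.3
    mutant_expression_coupling: float = 2.5
    non_orf_signal: bool = False
    non_orf_amplitude: float = 1.5

    def __post_init__(self) -> None:
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        for name in ("bound_fraction", "mutant_bound_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.de.noise_sd_log2 < 0:
            raise ValueError("noise levels must be >= 0")
        if self.mutant_cluster_elongation < 1:
            raise ValueError("mutant_cluster_elongation must be >= 1")

    @classmethod
    def low_noise_recovery(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Study conditions for planted-span recovery benchmarks.

        Replicate noise at 0.1 log2 units and an amplitude floor of half
        the maximum, so every planted span is unambiguously above the
        detection limit — recovery then measures the cluster caller, not
        the visibility of the weakest planted genes. Intergenic gaps are
        kept wider than the cluster-chaining distance plus the smoothing
        smear, so neighbouring planted spans cannot legitimately fuse into
        one called cluster and one-to-one recovery is well-posed.
        """
        return cls(
            seed=seed,
            noise_sd=0.1,
            amplitude_floor_fraction=0.5,
            min_intergenic_bp=600,
            chrom_length_bp=240_000,
            **overrides,
        )

    @classmethod
    def de_study(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Study conditions for differential-expression analyses.

        Expression matrices are cheap to simulate, so this study uses a
        fuller gene complement (800 ORFs on a proportionally longer
        genome), giving gene-set statistics on the planted de-regulated
        genes sample sizes comparable to a real genome-wide screen.
        """
        return cls(seed=seed, n_orfs=800, chrom_length_bp=400_000, **overrides)

    @classmethod
    def gradient_study(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Study conditions for within-gene positional (metagene) analyses.

        Positional profiles need every one of the 10 gene segments to span
        at least ~2 probe spacings, so this study draws longer genes
        (>= 1.2 kb) on proportionally longer chromosomes; all occupancy
        parameters keep their defaults.
        """
        return cls(
            seed=seed,
            n_orfs=300,
            n_chroms=4,
            chrom_length_bp=300_000,
            orf_length_log_mean=math.log(2200.0),
            orf_length_log_sd=0.35,
            orf_length_range=(1200, 8000),
            **overrides,
        )


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


# ---------------------------------------------------------------------------
# Genome


def _carve(gaps: list[list[int]], size: int, rng: np.random.Generator):
    """Take a sub-interval of the given size out of a random large-enough gap."""
    candidates = [i for i, (s, e) in enumerate(gaps) if e - s >= size + 2]
    if not candidates:
        return None
    i = int(rng.choice(candidates))
    s, e = gaps[i]
    offset = int(rng.integers(s + 1, e - size))
    gaps[i] = [s, offset]
    gaps.append([offset + size, e])
    return offset, offset + size


def simulate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping ORFs and non-ORF features on a toy genome.

    ORFs are laid down chromosome by chromosome with at least
    ``min_intergenic_bp`` between them, extra intergenic space spread
    randomly; telomeres cap every chromosome, one centromere sits mid-
    chromosome, and a few ARS / intron / sn-snoRNA / RNAPIII features are
    carved out of intergenic gaps (introns inside ORFs). Deterministic
    given (config, seed).
    """
    rng = _rng(config, 1)
    chroms = {f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)}
    chrom_names = list(chroms)

    lengths = rng.lognormal(
        config.orf_length_log_mean, config.orf_length_log_sd, size=config.n_orfs
    )
    lengths = np.clip(np.round(lengths).astype(int), *config.orf_length_range)
    gc = rng.beta(*config.gc_beta, size=config.n_orfs)
    expr = rng.lognormal(
        config.expression_log_mean, config.expression_log_sd, size=config.n_orfs
    )

    per_chrom = np.array_split(np.arange(config.n_orfs), config.n_chroms)
    features: list[Feature] = []
    gaps_by_chrom: dict[str, list[list[int]]] = {}
    for chrom, idx in zip(chrom_names, per_chrom):
        L = chroms[chrom]
        total_orf = int(lengths[idx].sum())
        n = len(idx)
        slack = L - total_orf - (n + 1) * config.min_intergenic_bp
        if slack < 0:
            raise ValueError(
                f"cannot place {n} ORFs totalling {total_orf} bp on {chrom} "
                f"({L} bp); increase chrom_length_bp or lower n_orfs"
            )
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n >= 0 else []
        cursor = 0
        gaps: list[list[int]] = []
        for j, oi in enumerate(idx):
            gap = config.min_intergenic_bp + int(extra[j])
            gaps.append([cursor, cursor + gap])
            cursor += gap
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    id=f"G{oi:04d}",
                    chrom=chrom,
                    start=cursor,
                    end=cursor + int(lengths[oi]),
                    strand=strand,
                    feature_class="ORF",
                    expression_level=float(expr[oi]),
                    gc_fraction=float(gc[oi]),
                )
            )
            cursor += int(lengths[oi])
        gaps.append([cursor, L])
        gaps_by_chrom[chrom] = gaps

    # non-ORF features: telomeres at chromosome ends, centromere near the
    # middle gap, plus small features carved from intergenic space
    counters = {"ARS": 0, "snRNA_snoRNA": 0, "RNAPIII": 0, "intron": 0}
    for ci, chrom in enumerate(chrom_names):
        L = chroms[chrom]
        tel = min(500, L // 20)
        features.append(Feature(f"TEL{2 * ci + 1:02d}", chrom, 0, tel, ".", "telomere"))
        features.append(
            Feature(f"TEL{2 * ci + 2:02d}", chrom, L - tel, L, ".", "telomere")
        )
        gaps = [
            [max(s, tel), min(e, L - tel)]
            for s, e in gaps_by_chrom[chrom]
            if min(e, L - tel) - max(s, tel) > 0
        ]
        mid = L // 2
        cen_gap = min(gaps, key=lambda g: abs((g[0] + g[1]) // 2 - mid))
        cen_mid = (cen_gap[0] + cen_gap[1]) // 2
        cen = (max(cen_gap[0], cen_mid - 60), min(cen_gap[1], cen_mid + 60))
        if cen[1] > cen[0]:
            features.append(Feature(f"CEN{ci + 1}", chrom, cen[0], cen[1], ".", "centromere"))
        for cls, count, size in (
            ("ARS", 3, 200),
            ("snRNA_snoRNA", 2, 150),
            ("RNAPIII", 3, 120),
        ):
            for _ in range(count):
                span = _carve(gaps, size, rng)
                if span is None:
                    continue
                counters[cls] += 1
                strand = "." if cls == "ARS" else ("+" if rng.random() < 0.5 else "-")
                features.append(
                    Feature(f"{cls}_{counters[cls]:03d}", chrom, span[0], span[1], strand, cls)
                )

    # introns inside a subset of ORFs
    orfs = [f for f in features if f.feature_class == "ORF"]
    if orfs:
        n_introns = max(1, len(orfs) // 20)
        for host in rng.choice(len(orfs), size=min(n_introns, len(orfs)), replace=False):
            g = orfs[int(host)]
            if g.length < 400:
                continue
            s = g.start + int(rng.integers(50, g.length - 150))
            counters["intron"] += 1
            features.append(
                Feature(f"intron_{counters['intron']:03d}", g.chrom, s, s + 100, g.strand, "intron")
            )

    return GenomeAnnotation(chroms, features)


# ---------------------------------------------------------------------------
# ChIP tracks


@dataclass(frozen=True)
class PlantedSpan:
    """Ground-truth occupied span with its planted peak amplitude."""

    chrom: str
    start: int
    end: int
    feature_id: str
    amplitude: float

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class ChipSimulation:
    """Replicate probe tracks plus the planted truth behind them."""

    tracks: dict[str, ProbeTrack]
    planted: list[PlantedSpan]
    factor: str
    condition: str

    def planted_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.planted])


def _bound_genes_and_amplitudes(
    orfs: list[Feature],
    n_bound: int,
    coupling: float,
    amplitude_max: float,
    amplitude_floor_fraction: float,
    boost: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Pick occupied genes and their amplitudes via an expression-coupled
    propensity: propensity = coupling * z(log expression) + N(0,1); the
    top ``n_bound`` genes by propensity are bound, with amplitude rising
    monotonically with within-bound propensity rank from the floor fraction
    of ``amplitude_max`` up to ``amplitude_max`` (times the condition
    boost). A floor of 0 gives a continuum of occupancies reaching down to
    the noise level, as in real ChIP data; a higher floor makes every
    planted span detectable."""
    if n_bound == 0 or not orfs:
        return {}
    log_e = np.log([g.expression_level for g in orfs])
    z = (log_e - log_e.mean()) / (log_e.std() if log_e.std() > 0 else 1.0)
    propensity = coupling * z + rng.standard_normal(len(orfs))
    order = np.argsort(-propensity, kind="stable")
    bound_idx = order[:n_bound]
    # within-bound rank: top of order gets u = 1, weakest u = 1/n_bound
    u = (n_bound - np.arange(n_bound)) / n_bound
    lo = amplitude_floor_fraction
    return {
        orfs[int(i)].id: float(amplitude_max * (lo + (1.0 - lo) * ui) * boost)
        for i, ui in zip(bound_idx, u)
    }


def simulate_chip_tracks(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    factor: str = "trex2",
    condition: str = "wild_type",
    instance: int = 0,
) -> ChipSimulation:
    """Simulate replicate log2(IP/SUP) probe tracks for one factor.

    The true per-probe log2 occupancy is 0 outside planted spans; inside a
    gene's span it is amplitude * (1 + g * (2t - 1)) where t in [0, 1] is
    the relative position along the transcription axis (so the gradient
    rises towards the 3' end, strand-aware) and g is ``gradient_strength``.
    Each replicate adds independent Gaussian noise. For the Rrm3-like
    factor under the mutant condition, spans are widened symmetrically by
    ``mutant_cluster_elongation``, more genes are occupied, amplitudes are
    boosted, and the expression coupling is tighter. ``instance``
    distinguishes independent ChIP experiments of the same planted truth
    (fresh noise and gene-selection randomness).
    """
    if factor not in _FACTOR_CODES:
        raise ValueError(f"factor must be one of {sorted(_FACTOR_CODES)}")
    if condition not in _CONDITION_CODES:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_CODES)}")
    rng = _rng(config, 2, _FACTOR_CODES[factor], _CONDITION_CODES[condition], instance)

    mutant = condition == "mutant" and factor == "rrm3"
    bound_fraction = config.mutant_bound_fraction if mutant else config.bound_fraction
    coupling = config.mutant_expression_coupling if mutant else config.expression_coupling
    boost = config.mutant_amplitude_boost if mutant else 1.0
    elongation = config.mutant_cluster_elongation if mutant else 1.0

    orfs = sorted(annotation.orfs, key=lambda g: g.id)
    n_bound = int(round(bound_fraction * len(orfs)))
    amplitudes = _bound_genes_and_amplitudes(
        orfs,
        n_bound,
        coupling,
        config.amplitude_max,
        config.amplitude_floor_fraction,
        boost,
        rng,
    )

    planted: list[PlantedSpan] = []
    for gene in orfs:
        amp = amplitudes.get(gene.id)
        if amp is None:
            continue
        pad = int(round((elongation - 1.0) / 2.0 * gene.length))
        start = max(0, gene.start - pad)
        end = min(annotation.chromosomes[gene.chrom], gene.end + pad)
        planted.append(PlantedSpan(gene.chrom, start, end, gene.id, amp))

    if config.non_orf_signal:
        classes = ("telomere", "RNAPIII", "snRNA_snoRNA", "ARS", "centromere")
        include_p = 0.9 if mutant else 0.5
        for cls in classes:
            for f in annotation.by_class(cls):
                if rng.random() < include_p:
                    planted.append(
                        PlantedSpan(f.chrom, f.start, f.end, f.id, config.non_orf_amplitude)
                    )

    gene_by_id = {g.id: g for g in orfs}
    tracks: dict[str, ProbeTrack] = {}
    half = config.probe_spacing_bp // 2
    for chrom, length in annotation.chromosomes.items():
        positions = np.arange(half, length, config.probe_spacing_bp, dtype=np.int64)
        truth = np.zeros(positions.size)
        for span in (p for p in planted if p.chrom == chrom):
            lo = np.searchsorted(positions, span.start, side="left")
            hi = np.searchsorted(positions, span.end, side="left")
            if hi <= lo:
                continue
            gene = gene_by_id.get(span.feature_id)
            if gene is None:
                level = np.full(hi - lo, span.amplitude)  # flat non-ORF signal
            else:
                pos = positions[lo:hi].astype(float)
                t = (pos - gene.start) / gene.length
                if gene.strand == "-":
                    t = 1.0 - t
                t = np.clip(t, 0.0, 1.0)
                level = span.amplitude * (1.0 + config.gradient_strength * (2.0 * t - 1.0))
            truth[lo:hi] = np.maximum(truth[lo:hi], level)
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_chip_replicates, positions.size))
        tracks[chrom] = ProbeTrack(chrom, positions, truth[None, :] + noise)

    return ChipSimulation(tracks, planted, factor, condition)


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class ExpressionSimulation:
    """Expression matrix plus ground-truth DE labels per mutant strain."""

    matrix: "pd.DataFrame | object"  # ExpressionMatrix; typed loosely to avoid cycle
    labels: pd.DataFrame  # columns: gene_id, strain, status, fold


def _de_weights(orfs: list[Feature], de: DEConfig, direction: str) -> np.ndarray:
    def z(vals: np.ndarray) -> np.ndarray:
        sd = vals.std()
        return (vals - vals.mean()) / (sd if sd > 0 else 1.0)

    z_len = z(np.log([g.length for g in orfs]))
    z_gc = z(np.array([g.gc_fraction for g in orfs]))
    z_expr = z(np.log([g.expression_level for g in orfs]))
    if direction == "down":
        score = de.bias_length * z_len + de.bias_gc * z_gc + de.bias_expression * z_expr
    else:
        score = de.bias_length * z_len - de.bias_gc * z_gc - de.bias_expression * z_expr
    w = np.exp(score - score.max())
    return w / w.sum()


def simulate_expression(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    n_mutants: int = 1,
    shared_fraction: float = 0.8,
) -> ExpressionSimulation:
    """Simulate replicate expression matrices with planted de-regulation.

    The wild-type mean of each gene is its annotated expression level;
    planted down-regulated genes have their mutant mean divided by a drawn
    fold (up-regulated multiplied), and replicates scatter log-normally
    around the strain mean. With ``n_mutants`` > 1, later mutants reuse a
    ``shared_fraction`` of the first mutant's planted (gene, status, fold)
    assignments and redraw the rest — emulating two mutants of one complex.
    """
    from .expression import ExpressionMatrix

    rng = _rng(config, 3)
    orfs = sorted(annotation.orfs, key=lambda g: g.id)
    if not orfs:
        raise ValueError("annotation carries no ORFs")
    if any(g.expression_level is None or g.gc_fraction is None for g in orfs):
        raise ValueError("ORFs must carry expression and G+C metadata")
    gene_ids = [g.id for g in orfs]
    base = np.array([g.expression_level for g in orfs])
    de = config.de
    n = len(orfs)
    n_down = int(round(de.fraction_down * n))
    n_up = int(round(de.fraction_up * n))

    def draw_de() -> dict[str, tuple[str, float]]:
        chosen: dict[str, tuple[str, float]] = {}
        if n_down:
            w = _de_weights(orfs, de, "down")
            for i in rng.choice(n, size=n_down, replace=False, p=w):
                chosen[gene_ids[int(i)]] = ("down", float(rng.uniform(*de.fold_range)))
        if n_up:
            w = _de_weights(orfs, de, "up").copy()
            taken = [i for i, g in enumerate(gene_ids) if g in chosen]
            w[taken] = 0.0
            w = w / w.sum()
            for i in rng.choice(n, size=n_up, replace=False, p=w):
                chosen[gene_ids[int(i)]] = ("up", float(rng.uniform(*de.fold_range)))
        return chosen

    de_by_strain: dict[str, dict[str, tuple[str, float]]] = {}
    first: dict[str, tuple[str, float]] | None = None
    for m in range(n_mutants):
        strain = f"mutant{m + 1}" if n_mutants > 1 else "mutant"
        if m == 0 or first is None:
            assignment = draw_de()
            first = assignment
        else:
            keep_ids = list(first)
            n_keep = int(round(shared_fraction * len(keep_ids)))
            kept = {
                g: first[g]
                for g in (
                    rng.choice(keep_ids, size=n_keep, replace=False) if n_keep else []
                )
            }
            fresh = draw_de()
            extra = {g: v for g, v in fresh.items() if g not in kept}
            # keep totals comparable: take as many fresh genes as were dropped
            n_extra = len(first) - len(kept)
            assignment = dict(kept)
            for g in list(extra)[:n_extra]:
                assignment[g] = extra[g]
        de_by_strain[strain] = assignment

    strains = ["wild_type", *de_by_strain.keys()]
    columns, col_meta, data = [], [], []
    for strain in strains:
        means = base.copy()
        if strain != "wild_type":
            for gi, gene in enumerate(gene_ids):
                status_fold = de_by_strain[strain].get(gene)
                if status_fold is None:
                    continue
                status, fold = status_fold
                means[gi] = means[gi] * fold if status == "up" else means[gi] / fold
        for r in range(1, config.n_expr_replicates + 1):
            noise = rng.normal(0.0, de.noise_sd_log2, size=n)
            data.append(means * np.exp2(noise))
            columns.append(f"{strain}_r{r}")
            col_meta.append((strain, str(r)))

    values = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene"), columns=columns)
    samples = pd.DataFrame(
        {
            "sample": columns,
            "strain": [m[0] for m in col_meta],
            "replicate": [m[1] for m in col_meta],
        }
    )
    label_rows = []
    for strain, assignment in de_by_strain.items():
        for gene in gene_ids:
            status, fold = assignment.get(gene, ("unchanged", 1.0))
            label_rows.append((gene, strain, status, fold))
    labels = pd.DataFrame(label_rows, columns=["gene_id", "strain", "status", "fold"])
    return ExpressionSimulation(ExpressionMatrix(values, samples), labels)
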