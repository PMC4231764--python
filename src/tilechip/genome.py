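"""Genome annotation model and interval arithmetic.

All coordinates inside the package are 0-based half-open. GFF3's 1-based
closed convention and BED's native half-open convention are converted at the
I/O boundary only, so downstream code never has to reason about conventions.

G+C fractions and expression levels are gene metadata carried on features;
they arrive with the annotation (or from the simulator), never computed from
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "FEATURE_CLASSES",
    "STRANDED_CLASSES",
    "Interval",
    "Feature",
    "GenomeAnnotation",
    "overlap_bp",
    "read_chrom_sizes",
    "read_annotation",
    "write_gff3",
    "write_bed",
    "DEFAULT_GFF_TYPE_MAP",
]

FEATURE_CLASSES = (
    "ORF",
    "centromere",
    "telomere",
    "ARS",
    "intron",
    "snRNA_snoRNA",
    "RNAPIII",
)

#: Classes that carry a transcription direction; all others use strand '.'.
STRANDED_CLASSES = frozenset({"ORF", "intron", "snRNA_snoRNA", "RNAPIII"})

#: Mapping from GFF3 "type" column (SGD-style vocabulary) to the feature
#: classes this package models. Table-driven and overridable because the SGD
#: type vocabulary varies across annotation releases.
DEFAULT_GFF_TYPE_MAP: dict[str, str] = {
    "gene": "ORF",
    "ORF": "ORF",
    "CDS": "ORF",
    "mRNA": "ORF",
    "centromere": "centromere",
    "telomere": "telomere",
    "ARS": "ARS",
    "origin_of_replication": "ARS",
    "intron": "intron",
    "snRNA": "snRNA_snoRNA",
    "snoRNA": "snRNA_snoRNA",
    "snRNA_gene": "snRNA_snoRNA",
    "snoRNA_gene": "snRNA_snoRNA",
    "tRNA": "RNAPIII",
    "tRNA_gene": "RNAPIII",
    "RNAPIII": "RNAPIII",
    "ncRNA_gene": "RNAPIII",
}


@dataclass(frozen=True)
class Interval:
    """A genomic span: chromosome plus 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_bp(a: Interval | "Feature", b: Interval | "Feature") -> int:
    """Number of base pairs shared by two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Feature:
    """A typed genomic feature (ORF, centromere, telomere, ...).

    ORFs optionally carry gene-level metadata: linear-scale expression
    (arbitrary units, as produced by model-based array summarisation) and
    G+C fraction.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "ORF"
    expression_level: float | None = None
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.id}: unknown feature class {self.feature_class!r}"
            )
        if self.strand == "." and self.feature_class in STRANDED_CLASSES:
            raise ValueError(
                f"feature {self.id}: class {self.feature_class} requires a strand"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(
                f"feature {self.id}: gc_fraction {self.gc_fraction} outside [0, 1]"
            )
        if self.expression_level is not None and self.expression_level <= 0:
            raise ValueError(
                f"feature {self.id}: expression must be positive (linear A.U.)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus the typed features living on them."""

    chromosomes: dict[str, int]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise ValueError(
                    f"feature {f.id} lies on unknown chromosome {f.chrom!r}"
                )
            if f.end > self.chromosomes[f.chrom] or f.start < 0:
                raise ValueError(
                    f"feature {f.id} span [{f.start}, {f.end}) outside "
                    f"chromosome {f.chrom} of length {self.chromosomes[f.chrom]}"
                )
            key = (f.feature_class, f.id)
            if key in seen:
                raise ValueError(
                    f"duplicate feature id {f.id!r} within class {f.feature_class}"
                )
            seen.add(key)

    @property
    def genome_bp(self) -> int:
        return sum(self.chromosomes.values())

    def by_class(self, feature_class: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def orfs(self) -> list[Feature]:
        return self.by_class("ORF")

    def orf(self, gene_id: str) -> Feature:
        for f in self.features:
            if f.feature_class == "ORF" and f.id == gene_id:
                return f
        raise KeyError(gene_id)

    def to_frame(self):
        """Feature table as a pandas DataFrame (one row per feature)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [f.id for f in self.features],
                "chrom": [f.chrom for f in self.features],
                "start": [f.start for f in self.features],
                "end": [f.end for f in self.features],
                "strand": [f.strand for f in self.features],
                "feature_class": [f.feature_class for f in self.features],
                "length": [f.length for f in self.features],
                "gc_fraction": [f.gc_fraction for f in self.features],
                "expression_level": [f.expression_level for f in self.features],
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path, type_map: Mapping[str, str]) -> list[Feature]:
    features: list[Feature] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
        if ftype not in type_map:
            continue  # unmodelled types (chromosome, region, ...) are skipped
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        a = _parse_gff_attributes(attrs)
        fclass = type_map[ftype]
        features.append(
            Feature(
                id=a.get("ID", f"{ftype}_{lineno}"),
                chrom=chrom,
                start=start_i - 1,  # GFF is 1-based closed
                end=end_i,
                strand=strand if strand in ("+", "-") else ".",
                feature_class=fclass,
                expression_level=float(a["expression"]) if "expression" in a else None,
                gc_fraction=float(a["gc"]) if "gc" in a else None,
            )
        )
    return features


def _read_bed(path: Path, feature_class: str) -> list[Feature]:
    features: list[Feature] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs at least 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) > 3 else f"{feature_class}_{lineno}"
        strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
        if strand == "." and feature_class in STRANDED_CLASSES:
            strand = "+"
        features.append(
            Feature(name, chrom, start, end, strand, feature_class)
        )
    return features


def read_annotation(
    path: str | Path,
    chrom_sizes: str | Path | Mapping[str, int],
    fmt: str | None = None,
    type_map: Mapping[str, str] | None = None,
    bed_feature_class: str = "ORF",
) -> GenomeAnnotation:
    """Read a GFF3 or BED annotation against a chromosome-size table.

    The format is inferred from the file suffix unless ``fmt`` is given.
    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention; BED is already half-open. For BED input every
    record is assigned ``bed_feature_class`` (BED carries no type column).
    """
    path = Path(path)
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if fmt == "gff3":
        features = _read_gff3(path, type_map or DEFAULT_GFF_TYPE_MAP)
    elif fmt == "bed":
        features = _read_bed(path, bed_feature_class)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GenomeAnnotation(dict(chrom_sizes), features)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation as GFF3 (round-trips with :func:`read_annotation`)."""
    class_to_type = {
        "ORF": "gene",
        "centromere": "centromere",
        "telomere": "telomere",
        "ARS": "ARS",
        "intron": "intron",
        "snRNA_snoRNA": "snoRNA",
        "RNAPIII": "tRNA",
    }
    lines = ["##gff-version 3"]
    for chrom, length in annotation.chromosomes.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for f in annotation.features:
        attrs = [f"ID={f.id}"]
        if f.expression_level is not None:
            attrs.append(f"expression={f.expression_level!r}")
        if f.gc_fraction is not None:
            attrs.append(f"gc={f.gc_fraction!r}")
        lines.append(
            "\t".join(
                [
                    f.chrom,
                    "tilechip",
                    class_to_type[f.feature_class],
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    """Write features as BED6 (score column fixed at 0)."""
    lines = [
        "\t".join([f.chrom, str(f.start), str(f.end), f.id, "0", f.strand])
        for f in features
    ]
    Path(path).write_text("\n".join(lines) + "\n")
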