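"""File formats for tracks, smoothed signals and clusters.

Probe-level data travel as bedGraph (one value column; probes written as
1-bp intervals at their positions), smoothed tracks as a bedGraph pair
(signal and -log10 P), clusters as BED6 with the mean signal encoded in
the score column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .clusters import BindingCluster
from .tiling import ProbeTrack, SmoothedTrack

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_probe_tracks",
    "read_probe_tracks",
    "write_smoothed",
    "read_smoothed",
    "write_clusters_bed",
    "read_clusters_bed",
]


def write_bedgraph(values_by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]], path: str | Path) -> None:
    """Write {chrom: (positions, values)} as bedGraph of 1-bp intervals."""
    lines = []
    for chrom in sorted(values_by_chrom):
        positions, values = values_by_chrom[chrom]
        for p, v in zip(positions, values):
            lines.append(f"{chrom}\t{int(p)}\t{int(p) + 1}\t{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[list[int], list[float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = parts[0]
        out.setdefault(chrom, ([], []))
        out[chrom][0].append(int(parts[1]))
        out[chrom][1].append(float(parts[3]))
    return {
        c: (np.array(p, dtype=np.int64), np.array(v)) for c, (p, v) in out.items()
    }


def write_probe_tracks(tracks: Mapping[str, ProbeTrack], prefix: str | Path) -> list[Path]:
    """Write one bedGraph per replicate: ``<prefix>.rep<k>.bedgraph``."""
    prefix = Path(prefix)
    n_reps = next(iter(tracks.values())).n_replicates
    paths = []
    for rep in range(n_reps):
        path = prefix.with_name(prefix.name + f".rep{rep + 1}.bedgraph")
        write_bedgraph(
            {c: (t.positions, t.values[rep]) for c, t in tracks.items()}, path
        )
        paths.append(path)
    return paths


def read_probe_tracks(paths: Iterable[str | Path]) -> dict[str, ProbeTrack]:
    """Read replicate bedGraphs (identical grids) into multi-replicate tracks."""
    per_rep = [read_bedgraph(p) for p in paths]
    if not per_rep:
        raise ValueError("no bedGraph paths given")
    out = {}
    for chrom in per_rep[0]:
        singles = [
            ProbeTrack(chrom, rep[chrom][0], rep[chrom][1][None, :]) for rep in per_rep
        ]
        out[chrom] = ProbeTrack.from_replicates(singles)
    return out


def write_smoothed(tracks: Mapping[str, SmoothedTrack], prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    sig_path = prefix.with_name(prefix.name + ".signal.bedgraph")
    p_path = prefix.with_name(prefix.name + ".mlog10p.bedgraph")
    write_bedgraph({c: (t.positions, t.signal) for c, t in tracks.items()}, sig_path)
    write_bedgraph(
        {c: (t.positions, -np.log10(t.p_value)) for c, t in tracks.items()}, p_path
    )
    return sig_path, p_path


def read_smoothed(sig_path: str | Path, p_path: str | Path, bandwidth_bp: int) -> dict[str, SmoothedTrack]:
    sig = read_bedgraph(sig_path)
    mp = read_bedgraph(p_path)
    out = {}
    for chrom in sig:
        positions, signal = sig[chrom]
        p_value = np.power(10.0, -mp[chrom][1])
        out[chrom] = SmoothedTrack(chrom, positions, signal, p_value, bandwidth_bp)
    return out


def write_clusters_bed(clusters: Iterable[BindingCluster], path: str | Path) -> None:
    """BED6: name = cluster id, score = 1000 * mean signal clipped to [0, 1000]."""
    lines = []
    for i, c in enumerate(clusters, start=1):
        score = int(np.clip(1000 * c.mean_signal, 0, 1000))
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i:05d}\t{score}\t."
            f"\t{c.peak_pos}\t{float(c.mean_signal)!r}\t{c.n_probes}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_clusters_bed(path: str | Path) -> list[BindingCluster]:
    clusters = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{lineno}: expected extended cluster BED")
        clusters.append(
            BindingCluster(
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                peak_pos=int(parts[6]),
                mean_signal=float(parts[7]),
                n_probes=int(parts[8]),
            )
        )
    return clusters
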