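"""Windowed genome landscapes and compositional summaries.

Chromosomes are tiled with fixed, non-overlapping windows (default 200 kb,
final window may be shorter). Each feature — fragment, band, gene, cut
site — is assigned to exactly one window by its start coordinate; GC
content is averaged over the ACGT bases of each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .digest import Band, CutSite, RestrictionFragment
from .errors import InputError
from .genome_io import GeneSet, Genome

DEFAULT_WINDOW = 200_000

_GC_BYTES = (ord("G"), ord("C"))
_ACGT_BYTES = tuple(ord(c) for c in "ACGT")


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _positions(features) -> list[tuple[str, int]]:
    """Window-assignment coordinate of each feature: cut sites by position,
    intervals by start, bands by their representative's start."""
    out = []
    for f in features:
        if isinstance(f, CutSite):
            out.append((f.chromosome, f.position))
        elif isinstance(f, Band):
            out.append((f.representative.chromosome, f.representative.start))
        elif isinstance(f, tuple):
            out.append((f[0], int(f[1])))
        else:  # RestrictionFragment, Gene, anything with chromosome/start
            out.append((f.chromosome, f.start))
    return out


def window_bounds(chrom_length: int, window_size: int) -> "tuple[np.ndarray, np.ndarray]":
    if window_size < 1:
        raise InputError("window size must be >= 1")
    starts = np.arange(0, chrom_length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, chrom_length)
    return starts, ends


def window_counts(
    features, genome: Genome, window_size: int = DEFAULT_WINDOW
) -> dict[str, np.ndarray]:
    """Per-window feature counts for every chromosome of *genome*.

    Every feature is counted exactly once, in the window containing its
    start coordinate (half-open windows). Features beyond a chromosome end
    are an error.
    """
    counts = {
        c: np.zeros(len(window_bounds(genome.length(c), window_size)[0]), dtype=np.int64)
        for c in genome
    }
    for chrom, pos in _positions(features):
        if chrom not in counts:
            raise InputError(f"feature on unknown chromosome {chrom!r}")
        if not 0 <= pos < genome.length(chrom):
            raise InputError(
                f"feature at {chrom}:{pos} beyond chromosome end "
                f"({genome.length(chrom)})"
            )
        counts[chrom][pos // window_size] += 1
    return counts


def window_gc(genome: Genome, window_size: int = DEFAULT_WINDOW) -> dict[str, np.ndarray]:
    """Per-window GC fraction, (G+C)/(A+C+G+T); NaN where a window has no
    ACGT bases."""
    out = {}
    for chrom in genome:
        arr = _seq_array(genome.sequence(chrom))
        starts, ends = window_bounds(len(arr), window_size)
        gc = np.zeros(len(starts))
        for i, (s, e) in enumerate(zip(starts, ends)):
            w = arr[s:e]
            acgt = sum(int(np.count_nonzero(w == b)) for b in _ACGT_BYTES)
            g_c = sum(int(np.count_nonzero(w == b)) for b in _GC_BYTES)
            gc[i] = g_c / acgt if acgt else np.nan
        out[chrom] = gc
    return out


@dataclass
class WindowTrack:
    """All window layers for one chromosome."""

    chromosome: str
    window_size: int
    starts: np.ndarray
    ends: np.ndarray
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def build_landscape(
    genome: Genome,
    window_size: int = DEFAULT_WINDOW,
    fragments: "Sequence[RestrictionFragment] | None" = None,
    bands: "Sequence[Band] | None" = None,
    geneset: "GeneSet | None" = None,
    rare_sites: "dict[str, list[CutSite]] | None" = None,
    frequent_sites: "dict[str, list[CutSite]] | None" = None,
) -> dict[str, WindowTrack]:
    """Assemble per-chromosome WindowTracks from whichever inputs are given.

    Layers produced (when inputs present): ``fragments``, ``bands``,
    ``genes``, ``rare_sites``, ``frequent_sites``, always ``gc``.
    """
    tracks = {}
    for chrom in genome:
        starts, ends = window_bounds(genome.length(chrom), window_size)
        tracks[chrom] = WindowTrack(chrom, window_size, starts, ends)
    layer_inputs = {
        "fragments": fragments,
        "bands": bands,
        "genes": list(geneset) if geneset is not None else None,
        "rare_sites": (
            [s for ss in rare_sites.values() for s in ss] if rare_sites else None
        ),
        "frequent_sites": (
            [s for ss in frequent_sites.values() for s in ss] if frequent_sites else None
        ),
    }
    for name, feats in layer_inputs.items():
        if feats is None:
            continue
        counts = window_counts(feats, genome, window_size)
        for chrom in genome:
            tracks[chrom].layers[name] = counts[chrom]
    gc = window_gc(genome, window_size)
    for chrom in genome:
        tracks[chrom].layers["gc"] = gc[chrom]
    return tracks


def write_bedgraph(
    tracks: dict[str, WindowTrack], layer: str, path: "str | Path"
) -> None:
    with open(path, "w") as fh:
        for chrom, tr in tracks.items():
            vals = tr.layers[layer]
            for s, e, v in zip(tr.starts, tr.ends, vals):
                if np.isnan(float(v)):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_landscape_tsv(tracks: dict[str, WindowTrack], path: "str | Path") -> None:
    layers = sorted({l for tr in tracks.values() for l in tr.layers})
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\t" + "\t".join(layers) + "\n")
        for chrom, tr in tracks.items():
            for i in range(tr.n_windows):
                row = [chrom, str(tr.starts[i]), str(tr.ends[i])]
                for l in layers:
                    v = tr.layers.get(l)
                    row.append("NA" if v is None else f"{v[i]:g}")
                fh.write("\t".join(row) + "\n")


def genic_intergenic_gc(genome: Genome, geneset: GeneSet) -> tuple[float, float]:
    """GC fraction over the union of gene intervals and over its complement,
    counting only ACGT bases; NaN for an empty compartment."""
    if len(geneset) == 0:
        raise InputError("empty geneset")
    genic_gc = genic_acgt = inter_gc = inter_acgt = 0
    for chrom in genome:
        arr = _seq_array(genome.sequence(chrom))
        mask = np.zeros(len(arr), dtype=bool)
        for s, e in geneset.union_intervals(chrom):
            mask[s:e] = True
        is_acgt = np.isin(arr, _ACGT_BYTES)
        is_gc = np.isin(arr, _GC_BYTES)
        genic_acgt += int(np.count_nonzero(is_acgt & mask))
        genic_gc += int(np.count_nonzero(is_gc & mask))
        inter_acgt += int(np.count_nonzero(is_acgt & ~mask))
        inter_gc += int(np.count_nonzero(is_gc & ~mask))
    g = genic_gc / genic_acgt if genic_acgt else float("nan")
    i = inter_gc / inter_acgt if inter_acgt else float("nan")
    return g, i


def gene_length_stats(geneset: GeneSet) -> tuple[float, float]:
    """Mean and population SD of gene lengths, in bp."""
    if len(geneset) == 0:
        raise InputError("empty geneset")
    lengths = np.array([g.length for g in geneset], dtype=float)
    return float(lengths.mean()), float(lengths.std(ddof=0))


def mean_intermarker_distance(markers, genome: "Genome | None" = None) -> "float | None":
    """Mean start-to-start gap between consecutive markers within each
    chromosome, pooled over chromosomes. None (with a warning) when no
    chromosome carries two markers."""
    by: dict[str, list[int]] = {}
    for chrom, pos in _positions(markers):
        by.setdefault(chrom, []).append(pos)
    gaps: list[np.ndarray] = []
    for positions in by.values():
        if len(positions) >= 2:
            gaps.append(np.diff(np.sort(np.array(positions, dtype=np.int64))))
    if not gaps:
        warnings.warn("fewer than 2 markers on every chromosome", stacklevel=2)
        return None
    return float(np.concatenate(gaps).mean())


def markers_per_genome_mb(markers, genome: Genome) -> float:
    """Alternative density measure: marker count / genome size in Mb."""
    n = len(list(markers))
    return n / (genome.total_length / 1e6)


@dataclass
class CompositionSummary:
    """Table-1-style compositional summary of one genome + marker set."""

    genome_size_bp: int
    genic_gc: float
    intergenic_gc: float
    n_genes: int
    gene_length_mean_bp: float
    gene_length_sd_bp: float
    n_markers: int
    mean_intermarker_bp: "float | None"


def composition_summary(
    genome: Genome, geneset: GeneSet, markers
) -> CompositionSummary:
    markers = list(markers)
    ggc, igc = genic_intergenic_gc(genome, geneset)
    mean_len, sd_len = gene_length_stats(geneset)
    return CompositionSummary(
        genome_size_bp=genome.total_length,
        genic_gc=ggc,
        intergenic_gc=igc,
        n_genes=len(geneset),
        gene_length_mean_bp=mean_len,
        gene_length_sd_bp=sd_len,
        n_markers=len(markers),
        mean_intermarker_bp=mean_intermarker_distance(markers)
        if len(markers) >= 2
        else None,
    )
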