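"""Marker-to-gene geometry and observed/expected distance statistics.

Distances are gap distances between half-open intervals: 0 when the marker
overlaps (shares at least one base with) a gene, otherwise the smallest
end-to-start gap to any gene on the same chromosome. Markers on
chromosomes without genes are at infinite distance but stay in the
denominators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .genome_io import Gene, GeneSet, Genome

#: Genome-wide distance thresholds (bp), as reported per species.
GENOME_THRESHOLDS = (0, 1_000, 10_000)
#: Thresholds for candidate-gene subsets (adds 100 kb).
CANDIDATE_THRESHOLDS = (0, 1_000, 10_000, 100_000)

Interval = "tuple[str, int, int]"


def _as_intervals(markers) -> list[tuple[str, int, int]]:
    """Accept fragments/bands/genes/(chrom,start,end) triples uniformly."""
    out = []
    for m in markers:
        if isinstance(m, tuple):
            out.append((m[0], int(m[1]), int(m[2])))
        else:
            out.append((m.chromosome, m.start, m.end))
    return out


def _interval_arrays_by_chrom(
    intervals: Sequence[tuple[str, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by.setdefault(c, []).append((s, e))
    out = {}
    for c, iv in by.items():
        iv.sort()
        out[c] = (
            np.array([s for s, _ in iv], dtype=np.int64),
            np.array([e for _, e in iv], dtype=np.int64),
        )
    return out


def _nearest_distances(
    queries: Sequence[tuple[str, int, int]],
    targets: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Gap distance from each query interval to its nearest target interval
    on the same chromosome (0 on overlap, inf when none exists)."""
    out = np.full(len(queries), np.inf)
    # targets sorted by start; cummax of ends locates the farthest-right
    # end among targets starting left of a query
    cummaxes = {c: np.maximum.accumulate(e) for c, (_, e) in targets.items()}
    for i, (chrom, a, b) in enumerate(queries):
        if chrom not in targets or len(targets[chrom][0]) == 0:
            continue
        starts, ends = targets[chrom]
        cummax = cummaxes[chrom]
        idx = int(np.searchsorted(starts, b))
        best = np.inf
        if idx > 0:
            if cummax[idx - 1] > a:
                out[i] = 0.0
                continue
            best = a - cummax[idx - 1]
        if idx < len(starts):
            best = min(best, starts[idx] - b)
        out[i] = max(best, 0.0)
    return out


def distance_to_nearest_gene(
    marker_interval: "tuple[str, int, int]", geneset: GeneSet
) -> float:
    """Distance in bp from one marker interval to the nearest gene.

    Returns 0 on any overlap, the minimum gap otherwise, and ``inf`` when
    the marker's chromosome carries no genes.
    """
    targets = {c: geneset.coordinate_arrays(c) for c in geneset.chromosomes}
    return float(_nearest_distances([marker_interval], targets)[0])


def marker_gene_distances(markers, geneset: GeneSet) -> np.ndarray:
    """Vector of nearest-gene distances, one per marker."""
    targets = {c: geneset.coordinate_arrays(c) for c in geneset.chromosomes}
    return _nearest_distances(_as_intervals(markers), targets)


def gene_marker_distances(markers, geneset: GeneSet) -> np.ndarray:
    """Vector of nearest-marker distances, one per gene."""
    targets = _interval_arrays_by_chrom(_as_intervals(markers))
    queries = [(g.chromosome, g.start, g.end) for g in geneset]
    return _nearest_distances(queries, targets)


def pct_markers_within(
    markers, geneset: GeneSet, thresholds: Sequence[int] = GENOME_THRESHOLDS
) -> "list[float] | None":
    """Cumulative percentage of markers within each distance threshold of a
    gene. ``None`` (with a warning) when there are no markers."""
    intervals = _as_intervals(markers)
    if not intervals:
        warnings.warn("no markers: percentage undefined", stacklevel=2)
        return None
    d = marker_gene_distances(intervals, geneset)
    return [100.0 * float(np.count_nonzero(d <= t)) / len(d) for t in thresholds]


def pct_genes_with_marker_within(
    markers, geneset: GeneSet, thresholds: Sequence[int] = GENOME_THRESHOLDS
) -> "list[float] | None":
    """Cumulative percentage of genes whose nearest marker is within each
    threshold (0 = at least one marker overlapping the gene)."""
    if len(geneset) == 0:
        warnings.warn("empty geneset: percentage undefined", stacklevel=2)
        return None
    d = gene_marker_distances(markers, geneset)
    return [100.0 * float(np.count_nonzero(d <= t)) / len(d) for t in thresholds]


def _n_overlap(intervals: list[tuple[int, int]], runs: list[tuple[int, int]]) -> int:
    """Total bases shared between two sorted disjoint interval lists."""
    total = 0
    j = 0
    for s, e in intervals:
        while j < len(runs) and runs[j][1] <= s:
            j += 1
        k = j
        while k < len(runs) and runs[k][0] < e:
            total += min(e, runs[k][1]) - max(s, runs[k][0])
            k += 1
    return total


def gene_union_coverage(geneset: GeneSet, genome: Genome) -> float:
    """Fraction of the sequenced genome covered by the union of gene
    intervals (N bases excluded from both sides)."""
    seq_total = genome.total_sequenced_length
    if seq_total <= 0:
        raise InputError("genome has no sequenced bases")
    covered = 0
    for chrom in genome:
        union = geneset.union_intervals(chrom)
        covered += sum(e - s for s, e in union)
        covered -= _n_overlap(union, genome.n_runs[chrom])
    return covered / seq_total


def expected_pct_markers_random(geneset: GeneSet, genome: Genome) -> float:
    """Random-placement expectation for the percentage of markers at 0 kb:
    the percentage of the sequenced genome covered by gene sequences."""
    return 100.0 * gene_union_coverage(geneset, genome)


def fragments_per_gene(markers, geneset: GeneSet) -> np.ndarray:
    """Number of markers overlapping each gene (order of ``geneset.genes``)."""
    by = _interval_arrays_by_chrom(_as_intervals(markers))
    counts = np.zeros(len(geneset), dtype=np.int64)
    sorted_ends = {c: np.sort(e) for c, (_, e) in by.items()}
    for i, g in enumerate(geneset):
        if g.chromosome not in by:
            continue
        starts, _ = by[g.chromosome]
        ends = sorted_ends[g.chromosome]
        # overlap iff marker.start < gene.end and marker.end > gene.start
        counts[i] = np.searchsorted(starts, g.end) - np.searchsorted(
            ends, g.start, side="right"
        )
    return counts


def poisson_expected_pct_genes(markers, geneset: GeneSet) -> tuple[float, float]:
    """Poisson expectation for the percentage of genes with >= 1 marker.

    lambda is the observed mean number of overlapping markers per gene; the
    expected percentage is 100 * (1 - exp(-lambda)).
    """
    if len(geneset) == 0:
        raise InputError("empty geneset")
    lam = float(fragments_per_gene(markers, geneset).mean())
    return lam, 100.0 * (1.0 - math.exp(-lam))


@dataclass
class GeneFragmentHistogram:
    """Observed genes-per-marker-count distribution vs the Poisson model."""

    counts: np.ndarray  # counts[k] = number of genes with exactly k markers
    observed_pct: np.ndarray
    poisson_pct: np.ndarray  # 100 * Poisson(lambda).pmf(k)
    lam: float

    def write_tsv(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            fh.write("k\tn_genes\tobserved_pct\tpoisson_pct\n")
            for k in range(len(self.counts)):
                fh.write(
                    f"{k}\t{self.counts[k]}\t{self.observed_pct[k]:.4f}\t"
                    f"{self.poisson_pct[k]:.4f}\n"
                )


def gene_fragment_histogram(markers, geneset: GeneSet) -> GeneFragmentHistogram:
    """Distribution of genes by number of overlapping markers, with the
    Poisson(lambda) percentages for comparison."""
    per_gene = fragments_per_gene(markers, geneset)
    lam = float(per_gene.mean()) if len(per_gene) else 0.0
    kmax = int(per_gene.max()) if len(per_gene) else 0
    counts = np.bincount(per_gene, minlength=kmax + 1)
    observed = 100.0 * counts / counts.sum()
    poisson = 100.0 * stats.poisson.pmf(np.arange(kmax + 1), lam)
    return GeneFragmentHistogram(
        counts=counts, observed_pct=observed, poisson_pct=poisson, lam=lam
    )


@dataclass
class DistanceSummary:
    """Observed and expected marker/gene distance statistics for one marker
    set against one gene set (one species x one enzyme pair)."""

    thresholds: tuple[int, ...]
    pct_markers_within: "list[float] | None"
    pct_genes_with_marker_within: "list[float] | None"
    expected_pct_markers_at_0: float
    expected_pct_genes_at_0: float
    lam: float
    n_markers: int
    n_genes: int

    def write_tsv(self, path: "str | Path") -> None:
        def fmt(v):
            return "NA" if v is None else f"{v:.4f}"

        with open(path, "w") as fh:
            fh.write("statistic\tthreshold_bp\tvalue\n")
            fh.write(f"n_markers\t.\t{self.n_markers}\n")
            fh.write(f"n_genes\t.\t{self.n_genes}\n")
            for i, t in enumerate(self.thresholds):
                v = None if self.pct_markers_within is None else self.pct_markers_within[i]
                fh.write(f"pct_markers_within\t{t}\t{fmt(v)}\n")
            fh.write(
                f"expected_pct_markers_at_0\t0\t{self.expected_pct_markers_at_0:.4f}\n"
            )
            for i, t in enumerate(self.thresholds):
                v = (
                    None
                    if self.pct_genes_with_marker_within is None
                    else self.pct_genes_with_marker_within[i]
                )
                fh.write(f"pct_genes_with_marker_within\t{t}\t{fmt(v)}\n")
            fh.write(f"expected_pct_genes_at_0\t0\t{self.expected_pct_genes_at_0:.4f}\n")
            fh.write(f"lambda\t.\t{self.lam:.6f}\n")


def distance_summary(
    markers,
    geneset: GeneSet,
    genome: Genome,
    thresholds: Sequence[int] = GENOME_THRESHOLDS,
) -> DistanceSummary:
    """Full observed/expected summary for one marker set vs one gene set."""
    intervals = _as_intervals(markers)
    if len(geneset) == 0:
        raise InputError("empty geneset")
    lam, exp_genes = poisson_expected_pct_genes(intervals, geneset)
    return DistanceSummary(
        thresholds=tuple(thresholds),
        pct_markers_within=pct_markers_within(intervals, geneset, thresholds),
        pct_genes_with_marker_within=pct_genes_with_marker_within(
            intervals, geneset, thresholds
        ),
        expected_pct_markers_at_0=expected_pct_markers_random(geneset, genome),
        expected_pct_genes_at_0=exp_genes,
        lam=lam,
        n_markers=len(intervals),
        n_genes=len(geneset),
    )


def candidate_subset_summary(
    markers,
    candidate_geneset: GeneSet,
    genome: Genome,
    thresholds: Sequence[int] = CANDIDATE_THRESHOLDS,
) -> DistanceSummary:
    """Distance summary against a candidate-gene subset with the extended
    0/1k/10k/100k thresholds; the random expectation uses the candidates'
    own union coverage."""
    if len(candidate_geneset) == 0:
        raise InputError("candidate gene set is empty")
    return distance_summary(markers, candidate_geneset, genome, thresholds)


def write_marker_distances_tsv(
    markers, geneset: GeneSet, path: "str | Path"
) -> None:
    """Per-marker nearest-gene distance table (marker, nearest gene, bp)."""
    intervals = _as_intervals(markers)
    dists = marker_gene_distances(intervals, geneset)
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tnearest_gene\tdistance_bp\n")
        for (chrom, a, b), d in zip(intervals, dists):
            gid = _nearest_gene_id(chrom, a, b, geneset) if math.isfinite(d) else "."
            dd = int(d) if math.isfinite(d) else "no_gene_on_chromosome"
            fh.write(f"{chrom}\t{a}\t{b}\t{gid}\t{dd}\n")


def _nearest_gene_id(chrom: str, a: int, b: int, geneset: GeneSet) -> str:
    best_id, best_d = ".", math.inf
    for g in geneset.on_chromosome(chrom):
        if g.start < b and g.end > a:
            return g.id
        d = g.start - b if g.start >= b else a - g.end
        if d < best_d:
            best_id, best_d = g.id, d
    return best_id
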