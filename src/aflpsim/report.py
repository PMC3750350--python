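"""Species-level reports: Table-1/Table-2-style summaries, cross-species
marker-density regression, and the physical-to-genetic density conversion."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import annotate, digest, landscape
from .annotate import CANDIDATE_THRESHOLDS, GENOME_THRESHOLDS, DistanceSummary
from .digest import EnzymePair
from .errors import InputError
from .genome_io import GeneSet, Genome, genes_per_chromosome, select_genes
from .landscape import CompositionSummary


@dataclass
class RegressionResult:
    """OLS fit of marker count on genome size (markers per Mb)."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    excluded: tuple[str, ...] = ()


def density_regression(
    points: Sequence[tuple[float, float]],
    labels: "Sequence[str] | None" = None,
    exclude: Sequence[str] = (),
    through_origin: bool = False,
) -> RegressionResult:
    """Regress marker count on genome size (Mb).

    *points* are (size_mb, marker_count) pairs; when *labels* are given,
    points whose label is in *exclude* are dropped before fitting. Ordinary
    least squares with intercept by default; ``through_origin`` forces the
    fit through (0, 0).
    """
    pts = list(points)
    if labels is not None:
        if len(labels) != len(pts):
            raise InputError("labels and points differ in length")
        drop = set(exclude)
        pts = [p for p, l in zip(pts, labels) if l not in drop]
    if len(pts) < 3:
        raise InputError(f"need >= 3 points after exclusion, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if through_origin:
        slope = float((x @ y) / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    fitted = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=len(pts),
        excluded=tuple(exclude),
    )


def markers_per_cM(density_per_kb: float, kb_per_cM: float) -> float:
    """Markers per centimorgan from a physical density (markers/kb) and a
    genetic-to-physical ratio (kb/cM)."""
    if density_per_kb <= 0 or kb_per_cM <= 0:
        raise InputError("density and kb/cM must both be > 0")
    return density_per_kb * kb_per_cM


@dataclass
class SpeciesSummary:
    """One species' full report: composition plus per-pair marker blocks."""

    label: str
    genome_size_bp: int
    composition: CompositionSummary
    marker_counts: dict[str, int] = field(default_factory=dict)
    distance_summaries: dict[str, DistanceSummary] = field(default_factory=dict)


def build_table1(
    genome: Genome,
    geneset: GeneSet,
    pairs: Sequence[EnzymePair],
    min_len: int = digest.DEFAULT_MIN_LEN,
    max_len: int = digest.DEFAULT_MAX_LEN,
    label: str = "genome",
) -> tuple[SpeciesSummary, list[tuple[str, str]]]:
    """Run the full pipeline for each enzyme pair and assemble the
    species-level report rows.

    The first pair gets the full distance block; subsequent pairs are
    reported with marker count and at-0-kb percentage only (as in the
    species table's trailing rows). Returns the summary object and the
    report as (row label, value) pairs ready for TSV writing.
    """
    if not pairs:
        raise InputError("need at least one enzyme pair")
    summary = None
    rows: list[tuple[str, str]] = []
    first_markers = None
    for i, pair in enumerate(pairs):
        markers = digest.digest_pipeline(genome, pair, min_len, max_len)
        ds = annotate.distance_summary(markers, geneset, genome, GENOME_THRESHOLDS)
        if i == 0:
            first_markers = markers
            comp = landscape.composition_summary(genome, geneset, markers)
            summary = SpeciesSummary(
                label=label,
                genome_size_bp=genome.total_length,
                composition=comp,
            )
            rows += [
                ("Genome size (Mb)", f"{genome.total_length / 1e6:.0f}"),
                ("GC% (gene sequences)", f"{comp.genic_gc:.3f}"),
                ("GC% (intergenic sequences)", f"{comp.intergenic_gc:.3f}"),
                ("Number of genes", str(comp.n_genes)),
                (
                    "Mean (stand. dev.) gene length (kb)",
                    f"{comp.gene_length_mean_bp / 1e3:.1f} "
                    f"({comp.gene_length_sd_bp / 1e3:.1f})",
                ),
            ]
        summary.marker_counts[pair.name] = len(markers)
        summary.distance_summaries[pair.name] = ds
        rows.append((f"[{pair.name}] Number of AFLPs", str(len(markers))))
        if i == 0:
            mid = landscape.mean_intermarker_distance(markers) if len(markers) >= 2 else None
            rows.append(
                (
                    f"[{pair.name}] Mean distance between AFLPs (kb)",
                    "NA" if mid is None else f"{mid / 1e3:.1f}",
                )
            )
            rows += _distance_block(pair.name, ds, precision=0)
        else:
            v = ds.pct_markers_within
            rows.append(
                (
                    f"[{pair.name}] % AFLPs at 0 kb from genes",
                    "NA" if v is None else f"{v[0]:.0f}",
                )
            )
    return summary, rows


def _distance_block(
    pair_name: str, ds: DistanceSummary, precision: int
) -> list[tuple[str, str]]:
    rows = []

    def fmt(v):
        return "NA" if v is None else f"{v:.{precision}f}"

    for i, t in enumerate(ds.thresholds):
        kb = t // 1000
        obs = None if ds.pct_markers_within is None else ds.pct_markers_within[i]
        if t == 0:
            rows.append(
                (
                    f"[{pair_name}] % AFLPs at 0 kb (EXP*)",
                    f"{fmt(obs)} ({ds.expected_pct_markers_at_0:.{precision}f})",
                )
            )
        else:
            rows.append((f"[{pair_name}] % AFLPs at {kb} kb", fmt(obs)))
    for i, t in enumerate(ds.thresholds):
        kb = t // 1000
        obs = (
            None
            if ds.pct_genes_with_marker_within is None
            else ds.pct_genes_with_marker_within[i]
        )
        if t == 0:
            rows.append(
                (
                    f"[{pair_name}] % Genes with AFLPs at 0 kb (EXP**)",
                    f"{fmt(obs)} ({ds.expected_pct_genes_at_0:.{precision}f})",
                )
            )
        else:
            rows.append((f"[{pair_name}] % Genes with AFLPs at {kb} kb", fmt(obs)))
    return rows


def build_table2(
    genome: Genome,
    geneset: GeneSet,
    candidate_ids: Sequence[str],
    pair: EnzymePair,
    min_len: int = digest.DEFAULT_MIN_LEN,
    max_len: int = digest.DEFAULT_MAX_LEN,
    label: str = "candidates",
) -> tuple[DistanceSummary, list[tuple[str, str]], list[str]]:
    """Candidate-gene report: per-chromosome counts, length stats and the
    extended-threshold distance summary. Unmatched IDs are returned for the
    run log; zero resolved candidates is an error."""
    selection = select_genes(geneset, candidate_ids)
    candidates = selection.geneset
    if len(candidates) == 0:
        raise InputError("no candidate IDs matched any gene")
    markers = digest.digest_pipeline(genome, pair, min_len, max_len)
    ds = annotate.candidate_subset_summary(
        markers, candidates, genome, CANDIDATE_THRESHOLDS
    )
    mean_len, sd_len = landscape.gene_length_stats(candidates)
    per_chrom = genes_per_chromosome(candidates, candidates.chromosomes)
    rows: list[tuple[str, str]] = [
        ("Number of candidate genes", str(len(candidates))),
        (
            "Candidate genes per chromosome",
            ", ".join(
                f"{c}:{n}" for c, n in zip(candidates.chromosomes, per_chrom)
            ),
        ),
        (
            "Mean (stand. dev.) gene length (kb)",
            f"{mean_len / 1e3:.1f} ({sd_len / 1e3:.1f})",
        ),
    ]
    prec = 2  # candidate-subset percentages carry two decimals
    for i, t in enumerate(ds.thresholds):
        kb = t // 1000
        obs = ds.pct_markers_within[i] if ds.pct_markers_within else None
        val = "NA" if obs is None else f"{obs:.{prec}f}"
        if t == 0:
            val += f" ({ds.expected_pct_markers_at_0:.{prec}f})"
        rows.append((f"% AFLPs at {kb} kb", val))
    for i, t in enumerate(ds.thresholds):
        kb = t // 1000
        obs = (
            ds.pct_genes_with_marker_within[i]
            if ds.pct_genes_with_marker_within
            else None
        )
        val = "NA" if obs is None else f"{obs:.0f}"
        if t == 0:
            val += f" ({ds.expected_pct_genes_at_0:.0f})"
        rows.append((f"% Genes with AFLPs at {kb} kb", val))
    return ds, rows, selection.unmatched


def write_rows_tsv(rows: Sequence[tuple[str, str]], path: "str | Path") -> None:
    with open(path, "w") as fh:
        for name, value in rows:
            fh.write(f"{name}\t{value}\n")
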