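"""Synthetic annotated genomes with the structure the analysis assumes.

Generated genomes have (a) higher GC in genic than intergenic sequence,
(b) optional (peri)centromeric tandem-repeat arrays whose unit can be made
to yield exactly one AFLP fragment per copy for a chosen enzyme pair, and
(c) gene lengths drawn from a log-normal with configurable mean/SD — all
deterministic for a fixed seed, with every planted quantity recorded in a
truth record.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .digest import Enzyme, EnzymePair, reverse_complement
from .errors import InfeasibleConfigError, InputError
from .genome_io import Gene, GeneSet, Genome, write_genes, write_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    if not 0.0 <= gc <= 1.0:
        raise InputError(f"GC fraction {gc} outside [0, 1]")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(_BASES, size=n, p=p)


@dataclass
class CentromereSpec:
    """A tandem-repeat array: *copies* exact copies of a *unit_length*-bp
    unit at *position*. When *pair* is set, every unit carries one
    rare-enzyme and one frequent-enzyme site spaced so each copy yields one
    AFLP fragment of *fragment_length* bp."""

    chromosome: str
    position: int
    unit_length: int = 147
    copies: int = 63
    unit_gc: float = 0.6
    pair: "EnzymePair | None" = None
    fragment_length: int = 117

    @property
    def array_length(self) -> int:
        return self.unit_length * self.copies


@dataclass
class NRunSpec:
    """Un-sequenced gaps: *count* N runs with uniform lengths in
    [min_length, max_length], per genome."""

    count: int
    min_length: int = 200
    max_length: int = 2_000


@dataclass
class PlantedSite:
    """An explicit enzyme recognition occurrence for deterministic tests."""

    chromosome: str
    position: int
    enzyme: Enzyme


@dataclass
class SyntheticGenomeConfig:
    seed: int = 0
    chromosome_lengths: Sequence[int] = (1_000_000,)
    n_genes: int = 0
    gene_length_mean: float = 2_100.0
    gene_length_sd: float = 1_600.0
    genic_gc: float = 0.45
    intergenic_gc: float = 0.35
    centromeres: Sequence[CentromereSpec] = field(default_factory=list)
    n_runs: "NRunSpec | None" = None
    planted_sites: Sequence[PlantedSite] = field(default_factory=list)
    max_placement_attempts: int = 200

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]


@dataclass
class GeneratedGenome:
    """A generated genome, its annotation, and the planted ground truth."""

    genome: Genome
    geneset: GeneSet
    truth: dict

    def write(self, out_dir: "str | Path") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "truth": out / "truth.tsv",
        }
        write_genome(self.genome, paths["fasta"])
        write_genes(self.geneset, paths["gff3"], "gff3")
        _write_truth_tsv(self.truth, paths["truth"])
        return paths


def _lognormal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Integer gene lengths from a log-normal with the given arithmetic
    mean and SD (degenerate at *mean* when sd == 0)."""
    if mean <= 0:
        raise InputError("gene length mean must be > 0")
    if sd == 0:
        return np.full(n, max(1, round(mean)), dtype=np.int64)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    lengths = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    return np.maximum(1, np.round(lengths)).astype(np.int64)


class _Occupancy:
    """Sorted disjoint reserved intervals per chromosome (for placement)."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def overlaps(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, end)
        return i > 0 and self.ends[i - 1] > start

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _place_interval(
    rng: np.random.Generator,
    length: int,
    chrom_len: int,
    occupied: _Occupancy,
    attempts: int,
    what: str,
) -> int:
    if length > chrom_len:
        raise InfeasibleConfigError(f"{what} of {length} bp exceeds chromosome")
    for _ in range(attempts):
        start = int(rng.integers(0, chrom_len - length + 1))
        if not occupied.overlaps(start, start + length):
            occupied.add(start, start + length)
            return start
    raise InfeasibleConfigError(
        f"could not place {what} of {length} bp after {attempts} attempts"
    )


def _write_motif(arr: np.ndarray, pos: int, motif: str) -> None:
    arr[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)


def _find_all(hay: str, motifs: Sequence[str]) -> list[tuple[int, str]]:
    hits = []
    for motif in motifs:
        start = hay.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = hay.find(motif, start + 1)
    return hits


def _build_repeat_unit(spec: CentromereSpec, rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """One sanitised repeat unit; returns (unit, rare_motif_pos, freq_motif_pos).

    When the unit is flagged for an enzyme pair, the two recognition sites
    are placed so the rare->frequent cut distance equals the requested
    fragment length, and a post-write scan mutates away any accidental
    occurrence of either motif (on either strand) in the tandem context so
    the copy number of planted sites is exact.
    """
    U = spec.unit_length
    unit = _random_bases(rng, U, spec.unit_gc)
    if spec.pair is None:
        return unit, -1, -1
    rare, freq = spec.pair.rare, spec.pair.frequent
    a = 1
    fpos = a + spec.fragment_length - freq.cut_offset + rare.cut_offset
    if fpos < a + len(rare.site) or fpos + len(freq.site) > U:
        raise InfeasibleConfigError(
            f"unit of {U} bp cannot host a {spec.fragment_length}-bp fragment "
            f"for {spec.pair.name}"
        )
    _write_motif(unit, a, rare.site)
    _write_motif(unit, fpos, freq.site)

    motifs = {rare.site, freq.site, reverse_complement(rare.site), reverse_complement(freq.site)}
    planted = {(a, rare.site), (fpos, freq.site), (a + U, rare.site), (fpos + U, freq.site)}
    protected: set[int] = set()
    for p, m in ((a, rare.site), (fpos, freq.site)):
        protected.update(range(p, p + len(m)))

    for _ in range(10 * U):
        doubled = (np.concatenate([unit, unit])).tobytes().decode()
        accidental = [
            (s, m) for s, m in _find_all(doubled, sorted(motifs)) if (s, m) not in planted
        ]
        if not accidental:
            return unit, a, fpos
        s, m = accidental[0]
        mutable = [p % U for p in range(s, s + len(m)) if (p % U) not in protected]
        if not mutable:
            raise InfeasibleConfigError(
                "accidental recognition occurrence overlaps only planted sites"
            )
        p = mutable[int(rng.integers(0, len(mutable)))]
        current = unit[p]
        choices = _BASES[_BASES != current]
        unit[p] = choices[int(rng.integers(0, len(choices)))]
    raise InfeasibleConfigError("could not sanitise repeat unit")


def generate(
    config: SyntheticGenomeConfig, out_dir: "str | Path | None" = None
) -> GeneratedGenome:
    """Generate a synthetic genome + annotation from *config*.

    Deterministic for a fixed seed. Intergenic bases are i.i.d. with the
    intergenic GC, gene bodies with the genic GC; centromeric arrays are
    exact tandem copies; N runs overwrite sequence; planted sites are
    written last. The truth record stores every planted quantity.
    """
    rng = np.random.default_rng(config.seed)
    names = config.chromosome_names
    lengths = {n: int(l) for n, l in zip(names, config.chromosome_lengths)}
    for n, l in lengths.items():
        if l < 1:
            raise InputError(f"chromosome {n!r}: non-positive length")

    arrays = {
        n: _random_bases(rng, lengths[n], config.intergenic_gc) for n in names
    }
    occupancy = {n: _Occupancy() for n in names}

    # centromeric tandem arrays (fixed positions, reserved first)
    centro_truth = []
    for spec in config.centromeres:
        if spec.chromosome not in arrays:
            raise InputError(f"centromere on unknown chromosome {spec.chromosome!r}")
        end = spec.position + spec.array_length
        if end > lengths[spec.chromosome]:
            raise InfeasibleConfigError("centromere array exceeds chromosome")
        if occupancy[spec.chromosome].overlaps(spec.position, end):
            raise InfeasibleConfigError("overlapping centromere arrays")
        occupancy[spec.chromosome].add(spec.position, end)
        unit, rare_off, freq_off = _build_repeat_unit(spec, rng)
        arrays[spec.chromosome][spec.position : end] = np.tile(unit, spec.copies)
        record = {
            "chromosome": spec.chromosome,
            "array_start": spec.position,
            "array_end": end,
            "unit_length": spec.unit_length,
            "copies": spec.copies,
        }
        if spec.pair is not None:
            rare = spec.pair.rare
            first_cut = spec.position + rare_off + rare.cut_offset
            record.update(
                pair=spec.pair.name,
                fragment_length=spec.fragment_length,
                fragment_starts=[
                    first_cut + k * spec.unit_length for k in range(spec.copies)
                ],
            )
        centro_truth.append(record)

    # N runs (avoid centromeres)
    n_run_truth = []
    if config.n_runs is not None:
        spec = config.n_runs
        if not 1 <= spec.min_length <= spec.max_length:
            raise InputError("invalid N-run length bounds")
        for _ in range(spec.count):
            chrom = names[int(rng.integers(0, len(names)))]
            run_len = int(rng.integers(spec.min_length, spec.max_length + 1))
            start = _place_interval(
                rng, run_len, lengths[chrom], occupancy[chrom],
                config.max_placement_attempts, "N run",
            )
            arrays[chrom][start : start + run_len] = ord("N")
            n_run_truth.append((chrom, start, start + run_len))

    # genes: chromosome chosen in proportion to length, placed without overlap
    genes: list[Gene] = []
    if config.n_genes:
        glens = _lognormal_lengths(
            rng, config.n_genes, config.gene_length_mean, config.gene_length_sd
        )
        weights = np.array([lengths[n] for n in names], dtype=float)
        weights /= weights.sum()
        chrom_idx = rng.choice(len(names), size=config.n_genes, p=weights)
        for i in range(config.n_genes):
            chrom = names[int(chrom_idx[i])]
            glen = int(glens[i])
            start = _place_interval(
                rng, glen, lengths[chrom], occupancy[chrom],
                config.max_placement_attempts, f"gene of {glen} bp",
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{i + 1:05d}", chrom, start, start + glen, strand))
            arrays[chrom][start : start + glen] = _random_bases(
                rng, glen, config.genic_gc
            )
    genes.sort(key=lambda g: (names.index(g.chromosome), g.start))

    # explicit planted sites last (deterministic overrides)
    site_truth = []
    for ps in config.planted_sites:
        if ps.chromosome not in arrays:
            raise InputError(f"planted site on unknown chromosome {ps.chromosome!r}")
        if ps.position + len(ps.enzyme.site) > lengths[ps.chromosome]:
            raise InfeasibleConfigError("planted site exceeds chromosome")
        _write_motif(arrays[ps.chromosome], ps.position, ps.enzyme.site)
        site_truth.append((ps.chromosome, ps.position, ps.enzyme.name))

    genome = Genome(
        [(n, arrays[n].tobytes().decode("ascii")) for n in names]
    )
    geneset = GeneSet(genes)
    truth = {
        "seed": config.seed,
        "genic_gc": config.genic_gc,
        "intergenic_gc": config.intergenic_gc,
        "gene_length_mean": config.gene_length_mean,
        "gene_length_sd": config.gene_length_sd,
        "genes": [(g.id, g.chromosome, g.start, g.end) for g in genes],
        "centromeres": centro_truth,
        "n_runs": n_run_truth,
        "planted_sites": site_truth,
    }
    result = GeneratedGenome(genome=genome, geneset=geneset, truth=truth)
    if out_dir is not None:
        result.write(out_dir)
    return result


def _write_truth_tsv(truth: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tfields\n")
        for key in ("seed", "genic_gc", "intergenic_gc", "gene_length_mean",
                    "gene_length_sd"):
            fh.write(f"{key}\t{truth[key]}\n")
        for gid, chrom, s, e in truth["genes"]:
            fh.write(f"gene\t{gid};{chrom};{s};{e}\n")
        for rec in truth["centromeres"]:
            fields = ";".join(f"{k}={v}" for k, v in rec.items() if k != "fragment_starts")
            fh.write(f"centromere\t{fields}\n")
            if "fragment_starts" in rec:
                starts = ",".join(map(str, rec["fragment_starts"]))
                fh.write(f"centromere_fragment_starts\t{starts}\n")
        for chrom, s, e in truth["n_runs"]:
            fh.write(f"n_run\t{chrom};{s};{e}\n")
        for chrom, pos, enz in truth["planted_sites"]:
            fh.write(f"planted_site\t{chrom};{pos};{enz}\n")


def generate_species_panel(
    density_per_mb: float,
    genome_sizes_mb: Sequence[float],
    seed: int = 0,
    noise_sd_frac: float = 0.02,
) -> list[tuple[float, float]]:
    """Synthetic (genome size Mb, marker count) points on a known density
    line with multiplicative Gaussian noise — for regression recovery tests."""
    if density_per_mb <= 0:
        raise InputError("density must be > 0")
    if len(genome_sizes_mb) < 3:
        raise InputError("need at least 3 genome sizes")
    rng = np.random.default_rng(seed)
    panel = []
    for size in genome_sizes_mb:
        count = density_per_mb * size
        if noise_sd_frac > 0:
            count *= 1.0 + rng.normal(0.0, noise_sd_frac)
        panel.append((float(size), float(max(0.0, round(count)))))
    return panel
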