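"""Genome and gene-annotation I/O.

Reads FASTA genomes and GFF3/BED gene annotations into a single internal
coordinate model (0-based, half-open intervals everywhere) and tracks
un-sequenced nucleotides (runs of N) per chromosome.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .errors import InputError

# ACGT plus N plus the other IUPAC ambiguity codes.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class Gene:
    """A gene interval [start, end) on one chromosome."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"gene {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise InputError(f"gene {self.id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class Genome:
    """Ordered chromosome sequences with N-run tracking.

    Sequences are uppercased on construction; only the characters in
    :data:`IUPAC_CODES` are accepted. Runs of ``N`` are indexed as
    half-open intervals and define the un-sequenced portion of each
    chromosome.
    """

    def __init__(self, chromosomes: "dict[str, str] | Iterable[tuple[str, str]]"):
        items = chromosomes.items() if isinstance(chromosomes, dict) else chromosomes
        self.chromosomes: dict[str, str] = {}
        self.n_runs: dict[str, list[tuple[int, int]]] = {}
        for name, seq in items:
            if not name:
                raise InputError("empty chromosome name")
            if name in self.chromosomes:
                raise InputError(f"duplicate chromosome name {name!r}")
            if not seq:
                raise InputError(f"chromosome {name!r}: empty sequence")
            seq = seq.upper()
            bad = set(seq) - IUPAC_CODES
            if bad:
                raise InputError(
                    f"chromosome {name!r}: non-IUPAC characters {sorted(bad)}"
                )
            self.chromosomes[name] = seq
            self.n_runs[name] = [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def sequence(self, name: str) -> str:
        return self.chromosomes[name]

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def n_bases(self, name: str) -> int:
        return sum(e - s for s, e in self.n_runs[name])

    def sequenced_length(self, name: str) -> int:
        return self.length(name) - self.n_bases(name)

    @property
    def total_sequenced_length(self) -> int:
        return sum(self.sequenced_length(c) for c in self.chromosomes)


def read_genome(source: "str | Path | IO[str]") -> Genome:
    """Read a multi-record FASTA file into a :class:`Genome`.

    Record order is preserved; duplicate record names, empty files and
    non-IUPAC characters are rejected with the offending record named.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(source, "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {source!r}")
    return Genome(records)


def write_genome(genome: Genome, path: "str | Path", width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def unsequenced_percentage(genome: Genome) -> float:
    """Percentage of the genome made of N bases, in [0, 100]."""
    total = genome.total_length
    n = sum(genome.n_bases(c) for c in genome.chromosomes)
    return 100.0 * n / total


class GeneSet:
    """A collection of genes with per-chromosome sorted indexes."""

    def __init__(self, genes: Sequence[Gene]):
        ids = [g.id for g in genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate gene IDs: {dup[:5]}")
        self.genes: list[Gene] = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        for gs in self._by_chrom.values():
            gs.sort(key=lambda g: (g.start, g.end))
        # sorted coordinate arrays for vectorised queries
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (
                np.array([g.start for g in gs], dtype=np.int64),
                np.array([g.end for g in gs], dtype=np.int64),
            )
            for c, gs in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.genes]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def on_chromosome(self, name: str) -> list[Gene]:
        return self._by_chrom.get(name, [])

    def coordinate_arrays(self, name: str) -> "tuple[np.ndarray, np.ndarray]":
        """(starts, ends) sorted by start for one chromosome; empty if none."""
        empty = np.empty(0, dtype=np.int64)
        return self._arrays.get(name, (empty, empty))

    def union_intervals(self, name: str) -> list[tuple[int, int]]:
        """Merged (union) gene intervals on one chromosome."""
        merged: list[tuple[int, int]] = []
        for g in self.on_chromosome(name):
            if merged and g.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], g.end))
            else:
                merged.append((g.start, g.end))
        return merged

    def validate_against(self, genome: Genome) -> list[Gene]:
        """Genes lying on chromosomes absent from *genome* (flagged, not fatal);
        coordinates beyond a known chromosome end are fatal."""
        missing = []
        for g in self.genes:
            if g.chromosome not in genome:
                missing.append(g)
            elif g.end > genome.length(g.chromosome):
                raise InputError(
                    f"gene {g.id!r} extends past end of {g.chromosome!r} "
                    f"({g.end} > {genome.length(g.chromosome)})"
                )
        return missing


def _parse_gff3_attributes(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(lines: Iterable[str]) -> Iterator[Gene]:
    n_anon = 0
    for ln, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise InputError(f"GFF3 line {ln}: expected >= 8 tab-separated columns")
        if cols[2] != "gene":
            continue
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError as e:
            raise InputError(f"GFF3 line {ln}: non-integer coordinates") from e
        attrs = _parse_gff3_attributes(cols[8]) if len(cols) > 8 else {}
        gid = attrs.get("ID") or attrs.get("Name")
        if gid is None:
            n_anon += 1
            gid = f"gene{n_anon}"
        strand = cols[6] if cols[6] in ("+", "-") else "."
        # GFF3 is 1-based inclusive -> 0-based half-open
        yield Gene(id=gid, chromosome=cols[0], start=start1 - 1, end=end1, strand=strand)


def _read_bed(lines: Iterable[str]) -> Iterator[Gene]:
    n_anon = 0
    for ln, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith(("track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise InputError(f"BED line {ln}: expected >= 3 columns")
        name = cols[3] if len(cols) > 3 else None
        if name is None:
            n_anon += 1
            name = f"gene{n_anon}"
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
        yield Gene(
            id=name,
            chromosome=cols[0],
            start=int(cols[1]),
            end=int(cols[2]),
            strand=strand,
        )


def read_genes(
    source: "str | Path | IO[str]",
    format: str = "gff3",
    genome: "Genome | None" = None,
) -> GeneSet:
    """Read gene intervals from GFF3 (``gene`` features) or BED.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is native. If *genome* is given,
    genes on unknown chromosomes are flagged with a warning and
    out-of-bounds coordinates raise :class:`InputError`.
    """
    readers = {"gff3": _read_gff3, "gff": _read_gff3, "bed": _read_bed}
    fmt = format.lower()
    if fmt not in readers:
        raise InputError(f"unknown annotation format {format!r}")
    if hasattr(source, "read"):
        genes = list(readers[fmt](source))
    else:
        with open(source) as fh:
            genes = list(readers[fmt](fh))
    geneset = GeneSet(genes)
    if genome is not None:
        missing = geneset.validate_against(genome)
        if missing:
            warnings.warn(
                f"{len(missing)} gene(s) on chromosomes absent from the genome "
                f"(e.g. {missing[0].id!r} on {missing[0].chromosome!r})",
                stacklevel=2,
            )
    return geneset


def write_genes(geneset: GeneSet, path: "str | Path", format: str = "gff3") -> None:
    """Write a GeneSet back out as GFF3 or BED6."""
    fmt = format.lower()
    with open(path, "w") as fh:
        if fmt in ("gff3", "gff"):
            fh.write("##gff-version 3\n")
            for g in geneset:
                fh.write(
                    f"{g.chromosome}\taflpsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand if g.strand != '.' else '.'}\t.\tID={g.id}\n"
                )
        elif fmt == "bed":
            for g in geneset:
                fh.write(
                    f"{g.chromosome}\t{g.start}\t{g.end}\t{g.id}\t0\t"
                    f"{g.strand if g.strand != '.' else '.'}\n"
                )
        else:
            raise InputError(f"unknown annotation format {format!r}")


def read_id_list(source: "str | Path | IO[str]") -> list[str]:
    """Candidate-gene ID list: one ID per line, '#' comments allowed."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    ids = []
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


@dataclass
class GeneSelection:
    """Result of selecting genes by ID: the subset plus unmatched IDs."""

    geneset: GeneSet
    unmatched: list[str] = field(default_factory=list)

    @property
    def n_requested(self) -> int:
        return len(self.geneset) + len(self.unmatched)


def select_genes(geneset: GeneSet, id_list: Sequence[str]) -> GeneSelection:
    """Subset a GeneSet by gene IDs; unmatched IDs are reported, not fatal."""
    if not id_list:
        raise InputError("empty candidate-ID list")
    wanted = set(id_list)
    subset = [g for g in geneset if g.id in wanted]
    matched = {g.id for g in subset}
    unmatched = [i for i in id_list if i not in matched]
    return GeneSelection(GeneSet(subset), unmatched)


def genes_per_chromosome(
    geneset: GeneSet, chromosome_order: Sequence[str]
) -> list[int]:
    """Gene counts in the given chromosome order; sums to ``len(geneset)``."""
    order = list(chromosome_order)
    known = set(order)
    for g in geneset:
        if g.chromosome not in known:
            raise InputError(
                f"gene {g.id!r} on chromosome {g.chromosome!r} missing from order"
            )
    return [len(geneset.on_chromosome(c)) for c in order]
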