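"""Double-digest simulation: cut sites, AFLP fragments, bands.

A complete double digestion with a rare-cutter / frequent-cutter pair is
simulated per chromosome; fragments bounded by one rare and one frequent
cut (either orientation) are the AFLP fragment pool, which can then be
size-selected, subsampled with selective nucleotides, and collapsed into
electrophoretic bands by identical sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError
from .genome_io import Genome

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: Offset added to a restriction-fragment length to obtain the length of the
#: PCR product once the standard adapters+primers are attached (40 -> 72,
#: 440 -> 472).
PCR_LENGTH_OFFSET = 32

#: Default size-selection window on restriction-fragment lengths (inclusive).
DEFAULT_MIN_LEN = 40
DEFAULT_MAX_LEN = 440


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.site or set(self.site) - set("ACGT"):
            raise InputError(f"enzyme {self.name!r}: recognition site must be ACGT")
        if not (0 <= self.cut_offset <= len(self.site)):
            raise InputError(f"enzyme {self.name!r}: cut offset out of range")

    @property
    def palindromic(self) -> bool:
        return self.site == reverse_complement(self.site)

    @property
    def gc_count(self) -> int:
        return self.site.count("G") + self.site.count("C")


#: Built-in catalogue. Cut offsets follow the standard cut chemistry where
#: known (EcoRI G^AATTC, MseI T^TAA, TaqI T^CGA, SacI GAGCT^C, HpaII C^CGG);
#: BsmI cuts outside its recognition site and is assigned the 3' boundary.
CATALOGUE: dict[str, Enzyme] = {
    e.name: e
    for e in [
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("MseI", "TTAA", 1),
        Enzyme("BsmI", "GAATGC", 6),
        Enzyme("TaqI", "TCGA", 1),
        Enzyme("SacI", "GAGCTC", 5),
        Enzyme("HpaII", "CCGG", 1),
    ]
}


def load_enzyme_config(source: "str | Path") -> dict[str, Enzyme]:
    """Load extra enzymes from a plain-text config: ``name motif cut_offset``
    per line, '#' comments allowed. Returns catalogue entries merged over the
    built-ins."""
    catalogue = dict(CATALOGUE)
    for ln, line in enumerate(Path(source).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise InputError(f"enzyme config line {ln}: expected 'name motif offset'")
        name, motif, off = parts
        catalogue[name] = Enzyme(name, motif.upper(), int(off))
    return catalogue


def get_enzyme(name: str, catalogue: "dict[str, Enzyme] | None" = None) -> Enzyme:
    cat = catalogue or CATALOGUE
    try:
        return cat[name]
    except KeyError:
        raise InputError(f"unknown enzyme {name!r}") from None


@dataclass(frozen=True)
class EnzymePair:
    """A rare-cutter / frequent-cutter pair defining one AFLP system.

    ``selective_rare`` / ``selective_frequent`` are the allowed interior
    bases next to each recognition remnant (empty = no selection on that
    end).
    """

    rare: Enzyme
    frequent: Enzyme
    selective_rare: frozenset = frozenset()
    selective_frequent: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.rare.site == self.frequent.site:
            raise InputError("enzyme pair must use distinct recognition sequences")

    @classmethod
    def from_names(
        cls,
        rare: str,
        frequent: str,
        selective_rare: Iterable[str] = (),
        selective_frequent: Iterable[str] = (),
        catalogue: "dict[str, Enzyme] | None" = None,
    ) -> "EnzymePair":
        return cls(
            get_enzyme(rare, catalogue),
            get_enzyme(frequent, catalogue),
            frozenset(b.upper() for b in selective_rare),
            frozenset(b.upper() for b in selective_frequent),
        )

    @property
    def name(self) -> str:
        return f"{self.rare.name}/{self.frequent.name}"

    def with_selective(
        self, rare_bases: Iterable[str], frequent_bases: Iterable[str]
    ) -> "EnzymePair":
        return replace(
            self,
            selective_rare=frozenset(b.upper() for b in rare_bases),
            selective_frequent=frozenset(b.upper() for b in frequent_bases),
        )


def pair_gc_fraction(pair: EnzymePair) -> float:
    """G+C fraction across the two recognition sequences (EcoRI/MseI 2/10,
    BsmI/TaqI 5/10, SacI/HpaII 8/10)."""
    total = len(pair.rare.site) + len(pair.frequent.site)
    return (pair.rare.gc_count + pair.frequent.gc_count) / total


@dataclass(frozen=True)
class CutSite:
    """One cut point produced by one recognition occurrence.

    ``occurrence_start`` locates the matched recognition sequence on the
    top strand (needed to read the selective interior base later).
    """

    chromosome: str
    position: int
    enzyme: str
    strand: str = "+"
    occurrence_start: int = -1


def _motif_occurrences(seq: str, motif: str) -> Iterable[int]:
    # lookahead regex so overlapping occurrences are all reported
    return (m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq))


def find_cut_sites(
    genome: "Genome | str", enzyme: Enzyme, chromosome: str = "chr"
) -> dict[str, list[CutSite]]:
    """All cut sites of *enzyme*, per chromosome, sorted and deduplicated.

    The top strand is scanned for the recognition sequence; non-palindromic
    enzymes are additionally scanned for its reverse complement (digestion
    is strand-symmetric). Occurrences containing non-ACGT bases never match.
    A string may be passed instead of a Genome for convenience.
    """
    if isinstance(genome, str):
        items = [(chromosome, genome.upper())]
    else:
        items = list(genome.chromosomes.items())
    motif = enzyme.site
    L = len(motif)
    out: dict[str, list[CutSite]] = {}
    for chrom, seq in items:
        sites: dict[int, CutSite] = {}
        for s in _motif_occurrences(seq, motif):
            pos = s + enzyme.cut_offset
            if 0 < pos < len(seq) and pos not in sites:
                sites[pos] = CutSite(chrom, pos, enzyme.name, "+", s)
        if not enzyme.palindromic:
            rc = reverse_complement(motif)
            for s in _motif_occurrences(seq, rc):
                pos = s + (L - enzyme.cut_offset)  # mirrored offset
                if 0 < pos < len(seq) and pos not in sites:
                    sites[pos] = CutSite(chrom, pos, enzyme.name, "-", s)
        out[chrom] = [sites[p] for p in sorted(sites)]
    return out


@dataclass(frozen=True)
class RestrictionFragment:
    """A fragment between two adjacent cut points of a double digest."""

    chromosome: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    sequence: str = field(repr=False, default="")
    left_site: "CutSite | None" = field(repr=False, default=None)
    right_site: "CutSite | None" = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pcr_length(self) -> int:
        return pcr_length(self.length)

    def is_aflp(self, pair: EnzymePair) -> bool:
        return {self.left_enzyme, self.right_enzyme} == {
            pair.rare.name,
            pair.frequent.name,
        }


def pcr_length(restriction_fragment_length: int) -> int:
    """Length of the PCR product for a restriction fragment (adds the primer
    and adapter bases: 40 -> 72, 440 -> 472)."""
    if restriction_fragment_length < 1:
        raise InputError("fragment length must be >= 1")
    return restriction_fragment_length + PCR_LENGTH_OFFSET


_ACGT_ONLY = re.compile(r"^[ACGT]+$")


def double_digest(
    genome: "Genome | str",
    pair: EnzymePair,
    aflp_only: bool = True,
    chromosome: str = "chr",
) -> list[RestrictionFragment]:
    """Simulate complete double digestion with *pair*.

    Cut positions of both enzymes are merged per chromosome; each pair of
    adjacent cuts bounds one fragment labelled with its flanking enzymes.
    With ``aflp_only`` (the default) only rare-frequent fragments are
    returned, fragments containing non-ACGT bases are discarded, and
    chromosome-terminal segments (one cut only) are never fragments.
    With ``aflp_only=False`` every internal fragment is returned regardless
    of type or sequence content (useful for tiling checks).
    """
    if isinstance(genome, str):
        seqs = {chromosome: genome.upper()}
    else:
        seqs = genome.chromosomes
    rare_sites = find_cut_sites(genome, pair.rare, chromosome)
    freq_sites = find_cut_sites(genome, pair.frequent, chromosome)
    rare_name, freq_name = pair.rare.name, pair.frequent.name

    fragments: list[RestrictionFragment] = []
    for chrom, seq in seqs.items():
        by_pos: dict[int, dict[str, CutSite]] = {}
        for cs in rare_sites.get(chrom, []) + freq_sites.get(chrom, []):
            by_pos.setdefault(cs.position, {})[cs.enzyme] = cs
        positions = sorted(by_pos)
        for p1, p2 in zip(positions, positions[1:]):
            left, right = by_pos[p1], by_pos[p2]
            # choose flanking labels, preferring a rare-frequent assignment
            if rare_name in left and freq_name in right:
                le, re_ = rare_name, freq_name
            elif freq_name in left and rare_name in right:
                le, re_ = freq_name, rare_name
            else:
                le, re_ = next(iter(left)), next(iter(right))
            frag = RestrictionFragment(
                chromosome=chrom,
                start=p1,
                end=p2,
                left_enzyme=le,
                right_enzyme=re_,
                sequence=seq[p1:p2],
                left_site=left[le],
                right_site=right[re_],
            )
            if aflp_only:
                if not frag.is_aflp(pair):
                    continue
                if not _ACGT_ONLY.match(frag.sequence):
                    continue
            fragments.append(frag)
    return fragments


def size_select(
    fragments: Sequence[RestrictionFragment],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[RestrictionFragment]:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive)."""
    if min_len < 1 or min_len > max_len:
        raise InputError(f"invalid size-selection window [{min_len}, {max_len}]")
    return [f for f in fragments if min_len <= f.length <= max_len]


def _interior_base(
    frag: RestrictionFragment, end: str, motif_lens: dict[str, int]
) -> "str | None":
    """Base immediately interior to the recognition remnant at one fragment
    end, read 5'->3' from the strand the primer anneals to (i.e. the
    right-hand base is complemented). None if the fragment is too short."""
    ls, rs = frag.left_site, frag.right_site
    if ls is None or rs is None or ls.occurrence_start < 0 or rs.occurrence_start < 0:
        raise InputError("fragment lacks cut-site provenance for selective filtering")
    # occurrences span [occurrence_start, occurrence_start + motif_len);
    # interior bases sit just outside those spans, inside the fragment
    lpos = ls.occurrence_start + motif_lens[frag.left_enzyme]
    rpos = rs.occurrence_start - 1
    if lpos > rpos:  # no base beyond both recognition remnants
        return None
    if end == "left":
        if not frag.start <= lpos < frag.end:
            return None
        return frag.sequence[lpos - frag.start]
    if not frag.start <= rpos < frag.end:
        return None
    return reverse_complement(frag.sequence[rpos - frag.start])


def apply_selective(
    fragments: Sequence[RestrictionFragment], pair: EnzymePair
) -> list[RestrictionFragment]:
    """Keep fragments whose interior bases match the pair's selective spec.

    The base immediately interior to the rare-enzyme recognition occurrence
    must lie in ``selective_rare`` and the one interior to the frequent
    occurrence in ``selective_frequent``; an empty set places no constraint
    on that end. The base at the right-hand end is read as its complement
    (the primer anneals to the opposite strand). Fragments too short to
    expose an interior base beyond both remnants fail the filter.
    """
    if not pair.selective_rare and not pair.selective_frequent:
        raise InputError("selective spec is empty on both ends")
    motif_lens = {
        pair.rare.name: len(pair.rare.site),
        pair.frequent.name: len(pair.frequent.site),
    }
    kept = []
    for frag in fragments:
        ok = True
        for end, enzyme in (("left", frag.left_enzyme), ("right", frag.right_enzyme)):
            allowed = (
                pair.selective_rare
                if enzyme == pair.rare.name
                else pair.selective_frequent
            )
            if not allowed:
                continue
            base = _interior_base(frag, end, motif_lens)
            if base is None or base not in allowed:
                ok = False
                break
        if ok:
            kept.append(frag)
    return kept


@dataclass(frozen=True)
class Band:
    """An electrophoretic band: the class of identical co-migrating fragments."""

    representative: RestrictionFragment
    multiplicity: int

    @property
    def length(self) -> int:
        return self.representative.length

    @property
    def chromosome(self) -> str:
        return self.representative.chromosome

    @property
    def start(self) -> int:
        return self.representative.start


def collapse_bands(
    fragments: Sequence[RestrictionFragment], by: str = "sequence"
) -> list[Band]:
    """Collapse fragments into bands by identical sequence (default) or,
    for homoplasy studies, by identical length.

    The representative of a band is the member with the lowest
    (chromosome order of appearance, start). Bands are returned sorted by
    representative position. Sum of multiplicities equals the fragment
    count.
    """
    if by not in ("sequence", "length"):
        raise InputError(f"unknown band-collapse key {by!r}")
    groups: dict[object, list[RestrictionFragment]] = {}
    chrom_rank: dict[str, int] = {}
    for frag in fragments:
        chrom_rank.setdefault(frag.chromosome, len(chrom_rank))
        key = frag.sequence if by == "sequence" else frag.length
        groups.setdefault(key, []).append(frag)
    bands = []
    for members in groups.values():
        rep = min(members, key=lambda f: (chrom_rank[f.chromosome], f.start))
        bands.append(Band(representative=rep, multiplicity=len(members)))
    bands.sort(key=lambda b: (chrom_rank[b.chromosome], b.start))
    return bands


def digest_pipeline(
    genome: Genome,
    pair: EnzymePair,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    selective: bool = False,
) -> list[RestrictionFragment]:
    """Full marker pipeline: double digest, size-select, optional selective
    nucleotides. The result is the AFLP marker set used downstream."""
    frags = double_digest(genome, pair)
    frags = size_select(frags, min_len, max_len)
    if selective and (pair.selective_rare or pair.selective_frequent):
        frags = apply_selective(frags, pair)
    return frags


def write_fragments_bed(
    fragments: Sequence[RestrictionFragment], path: "str | Path"
) -> None:
    """Fragments as BED6; name = leftEnzyme-rightEnzyme:length."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.chromosome}\t{f.start}\t{f.end}\t"
                f"{f.left_enzyme}-{f.right_enzyme}:{f.length}\t0\t+\n"
            )


def write_bands_bed(bands: Sequence[Band], path: "str | Path") -> None:
    """Bands as BED6 at their representative position; score = multiplicity."""
    with open(path, "w") as fh:
        for b in bands:
            r = b.representative
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t"
                f"{r.left_enzyme}-{r.right_enzyme}:{r.length}\t{b.multiplicity}\t+\n"
            )
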