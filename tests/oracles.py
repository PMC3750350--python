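"""Independent brute-force oracles used by the tests.

These deliberately re-derive results position by position / pair by pair,
sharing no code with the package implementation.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_cut_positions(seq: str, motif: str, cut_offset: int) -> list[int]:
    """Every cut position of one enzyme, testing every offset on both strands."""
    L = len(motif)
    positions = set()
    for i in range(len(seq) - L + 1):
        if seq[i : i + L] == motif:
            p = i + cut_offset
            if 0 < p < len(seq):
                positions.add(p)
    rc = revcomp(motif)
    if rc != motif:
        for i in range(len(seq) - L + 1):
            if seq[i : i + L] == rc:
                p = i + (L - cut_offset)
                if 0 < p < len(seq):
                    positions.add(p)
    return sorted(positions)


def naive_double_digest(seq, rare_motif, rare_off, freq_motif, freq_off):
    """(start, end, type) for every internal fragment; type is a frozenset of
    the enzymes cutting at each boundary, as a 2-tuple."""
    rare = set(naive_cut_positions(seq, rare_motif, rare_off))
    freq = set(naive_cut_positions(seq, freq_motif, freq_off))
    cuts = sorted(rare | freq)
    out = []
    for a, b in zip(cuts, cuts[1:]):
        left = frozenset(
            n for n, s in (("rare", rare), ("freq", freq)) if a in s
        )
        right = frozenset(
            n for n, s in (("rare", rare), ("freq", freq)) if b in s
        )
        out.append((a, b, left, right))
    return out


def naive_aflp_fragments(seq, rare_motif, rare_off, freq_motif, freq_off):
    """AFLP-typed fragments only: one rare and one frequent end, ACGT-clean."""
    out = []
    for a, b, left, right in naive_double_digest(
        seq, rare_motif, rare_off, freq_motif, freq_off
    ):
        if ("rare" in left and "freq" in right) or (
            "freq" in left and "rare" in right
        ):
            if all(c in "ACGT" for c in seq[a:b]):
                out.append((a, b))
    return out


def all_pairs_min_distance(marker, genes):
    """Minimum gap between one (start, end) marker and a list of gene
    intervals; 0 on overlap, inf when the list is empty."""
    best = float("inf")
    a, b = marker
    for s, e in genes:
        if s < b and e > a:
            return 0
        best = min(best, s - b if s >= b else a - e)
    return best
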