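import math

import numpy as np
import pytest
from scipy import stats

from aflpsim.annotate import (
    candidate_subset_summary,
    distance_summary,
    distance_to_nearest_gene,
    expected_pct_markers_random,
    fragments_per_gene,
    gene_fragment_histogram,
    marker_gene_distances,
    pct_genes_with_marker_within,
    pct_markers_within,
    poisson_expected_pct_genes,
)
from aflpsim.genome_io import Gene, GeneSet, Genome
from conftest import random_dna
from oracles import all_pairs_min_distance


def _genome(n=100_000, chrom="c1", rng=None):
    rng = rng or np.random.default_rng(0)
    return Genome([(chrom, random_dna(rng, n))])


def _random_layout(rng, n_markers=50, n_genes=20, size=100_000):
    markers = []
    for _ in range(n_markers):
        s = int(rng.integers(0, size - 200))
        markers.append(("c1", s, s + int(rng.integers(40, 200))))
    genes = []
    for i in range(n_genes):
        s = int(rng.integers(0, size - 3000))
        genes.append(Gene(f"g{i}", "c1", s, s + int(rng.integers(100, 3000))))
    return markers, GeneSet(genes)


class TestDistanceToNearestGene:
    def test_marker_inside_gene(self):
        gs = GeneSet([Gene("g", "c1", 50, 500)])
        assert distance_to_nearest_gene(("c1", 100, 200), gs) == 0

    def test_partial_overlap_is_zero(self):
        gs = GeneSet([Gene("g", "c1", 150, 500)])
        assert distance_to_nearest_gene(("c1", 100, 200), gs) == 0

    def test_gap_arithmetic(self):
        gs = GeneSet([Gene("g", "c1", 700, 900)])
        assert distance_to_nearest_gene(("c1", 100, 200), gs) == 500

    def test_gene_left_of_marker(self):
        gs = GeneSet([Gene("g", "c1", 0, 80)])
        assert distance_to_nearest_gene(("c1", 100, 200), gs) == 20

    def test_no_gene_on_chromosome(self):
        gs = GeneSet([Gene("g", "c2", 0, 80)])
        assert distance_to_nearest_gene(("c1", 100, 200), gs) == math.inf

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            markers, gs = _random_layout(rng)
            got = marker_gene_distances(markers, gs)
            gene_iv = [(g.start, g.end) for g in gs]
            for (c, a, b), d in zip(markers, got):
                assert d == all_pairs_min_distance((a, b), gene_iv)


class TestPctMarkersWithin:
    def test_all_inside_genes(self):
        gs = GeneSet([Gene("g", "c1", 0, 10_000)])
        markers = [("c1", i * 100, i * 100 + 50) for i in range(10)]
        assert pct_markers_within(markers, gs, [0, 1000, 10_000]) == [100, 100, 100]

    def test_no_genes(self):
        gs = GeneSet([])
        markers = [("c1", 0, 50)]
        assert pct_markers_within(markers, gs, [0, 1000, 10_000]) == [0, 0, 0]

    def test_no_markers_warns_none(self):
        gs = GeneSet([Gene("g", "c1", 0, 10)])
        with pytest.warns(UserWarning):
            assert pct_markers_within([], gs) is None

    def test_nondecreasing_in_threshold(self, rng):
        markers, gs = _random_layout(rng)
        pct = pct_markers_within(markers, gs, [0, 100, 1000, 10_000, 10**9])
        assert pct == sorted(pct)
        assert pct[-1] == 100.0  # threshold beyond chromosome length

    def test_matches_counting_oracle(self, rng):
        markers, gs = _random_layout(rng)
        gene_iv = [(g.start, g.end) for g in gs]
        for t in (0, 500, 5000):
            n = sum(
                1
                for (c, a, b) in markers
                if all_pairs_min_distance((a, b), gene_iv) <= t
            )
            (got,) = pct_markers_within(markers, gs, [t])
            assert got == pytest.approx(100 * n / len(markers))


class TestExpectedPctMarkersRandom:
    def test_direct_fraction(self):
        genome = _genome(1000)
        gs = GeneSet([Gene("g", "c1", 0, 590)])
        assert expected_pct_markers_random(gs, genome) == pytest.approx(59.0)

    def test_union_semantics(self):
        genome = _genome(1000)
        one = GeneSet([Gene("g", "c1", 0, 590)])
        two = GeneSet([Gene("g1", "c1", 0, 590), Gene("g2", "c1", 100, 400)])
        assert expected_pct_markers_random(two, genome) == expected_pct_markers_random(
            one, genome
        )

    def test_with_ns_matches_per_base_oracle(self, rng):
        seq = list(random_dna(rng, 5000))
        seq[1000:1500] = "N" * 500
        seq[3000:3100] = "N" * 100
        genome = Genome([("c1", "".join(seq))])
        genes = [Gene("g1", "c1", 900, 1200), Gene("g2", "c1", 2500, 3500)]
        gs = GeneSet(genes)
        covered = sequenced = 0
        for i, b in enumerate(genome.sequence("c1")):
            if b == "N":
                continue
            sequenced += 1
            if any(g.start <= i < g.end for g in genes):
                covered += 1
        assert expected_pct_markers_random(gs, genome) == pytest.approx(
            100 * covered / sequenced
        )


class TestPctGenesWithMarker:
    def test_every_gene_contains_marker(self):
        gs = GeneSet([Gene(f"g{i}", "c1", i * 1000, i * 1000 + 500) for i in range(5)])
        markers = [("c1", i * 1000 + 10, i * 1000 + 60) for i in range(5)]
        assert pct_genes_with_marker_within(markers, gs, [0])[0] == 100.0

    def test_no_markers(self):
        gs = GeneSet([Gene("g", "c1", 0, 10)])
        assert pct_genes_with_marker_within([], gs, [0, 1000]) == [0, 0]

    def test_empty_geneset_warns(self):
        with pytest.warns(UserWarning):
            assert pct_genes_with_marker_within([("c1", 0, 5)], GeneSet([])) is None

    def test_matches_all_pairs_oracle(self, rng):
        markers, gs = _random_layout(rng)
        marker_iv = [(a, b) for (c, a, b) in markers]
        for t in (0, 500, 5000):
            n = sum(
                1
                for g in gs
                if all_pairs_min_distance((g.start, g.end), marker_iv) <= t
            )
            (got,) = pct_genes_with_marker_within(markers, gs, [t])
            assert got == pytest.approx(100 * n / len(gs))


class TestPoissonExpectation:
    def test_lambda_zero(self):
        gs = GeneSet([Gene("g", "c1", 0, 100)])
        lam, pct = poisson_expected_pct_genes([], gs)
        assert lam == 0 and pct == 0

    def test_lambda_ln2_gives_50(self):
        # 10 genes, one marker overlapping ceil-free: construct lambda = ln 2
        # via the closed form directly
        lam = math.log(2)
        assert 100 * (1 - math.exp(-lam)) == pytest.approx(50)
        # and the implementation applies exactly that closed form
        gs = GeneSet([Gene(f"g{i}", "c1", i * 100, i * 100 + 50) for i in range(2)])
        markers = [("c1", 10, 20)]  # one pair over two genes -> lambda = .5
        lam, pct = poisson_expected_pct_genes(markers, gs)
        assert lam == pytest.approx(0.5)
        assert pct == pytest.approx(100 * (1 - math.exp(-0.5)))

    def test_marker_overlapping_two_genes_counts_twice(self):
        gs = GeneSet([Gene("a", "c1", 0, 100), Gene("b", "c1", 50, 150)])
        markers = [("c1", 40, 60)]
        assert fragments_per_gene(markers, gs).tolist() == [1, 1]
        lam, _ = poisson_expected_pct_genes(markers, gs)
        assert lam == 1.0

    def test_uniform_markers_match_poisson_within_3sd(self, rng):
        # equal-length genes + uniformly scattered point markers: the model's
        # own assumption, so observed ~ 100(1 - e^-lambda)
        size, n_genes, glen, n_markers = 1_000_000, 200, 2_000, 3_000
        genes = [
            Gene(f"g{i}", "c1", i * (size // n_genes), i * (size // n_genes) + glen)
            for i in range(n_genes)
        ]
        gs = GeneSet(genes)
        pos = rng.integers(0, size - 1, size=n_markers)
        markers = [("c1", int(p), int(p) + 1) for p in pos]
        lam, exp_pct = poisson_expected_pct_genes(markers, gs)
        (obs,) = pct_genes_with_marker_within(markers, gs, [0])
        p = exp_pct / 100
        sd = 100 * math.sqrt(p * (1 - p) / n_genes)
        assert abs(obs - exp_pct) <= 3 * sd


class TestGeneFragmentHistogram:
    def test_no_markers_all_k0(self):
        gs = GeneSet([Gene(f"g{i}", "c1", i * 100, i * 100 + 50) for i in range(4)])
        h = gene_fragment_histogram([], gs)
        assert h.counts.tolist() == [4]
        assert h.observed_pct[0] == 100

    def test_poisson_consistent_not_rejected(self, rng):
        size, n_genes, glen = 2_000_000, 400, 2_000
        genes = [
            Gene(f"g{i}", "c1", i * (size // n_genes), i * (size // n_genes) + glen)
            for i in range(n_genes)
        ]
        gs = GeneSet(genes)
        pos = rng.integers(0, size - 1, size=8_000)
        markers = [("c1", int(p), int(p) + 1) for p in pos]
        h = gene_fragment_histogram(markers, gs)
        # chi-square goodness of fit, classes pooled to expected >= 5
        expected = h.poisson_pct / 100 * n_genes
        tail = n_genes - expected.sum()
        obs, exp = [], []
        o_acc = e_acc = 0.0
        for k in range(len(h.counts)):
            o_acc += h.counts[k]
            e_acc += expected[k]
            if e_acc >= 5:
                obs.append(o_acc)
                exp.append(e_acc)
                o_acc = e_acc = 0.0
        obs[-1] += o_acc
        exp[-1] += e_acc + tail
        exp = np.array(exp) * (sum(obs) / sum(exp))
        chi2 = (((np.array(obs) - exp) ** 2) / exp).sum()
        dof = len(obs) - 2  # lambda estimated from the data
        assert chi2 < stats.chi2.ppf(0.99, max(dof, 1))

    def test_heterogeneous_lengths_overdispersed(self, rng):
        # strongly unequal gene lengths: observed k=0 exceeds Poisson k=0
        size = 2_000_000
        genes = []
        pos = 0
        for i in range(200):
            glen = 200 if i % 2 else 18_000
            genes.append(Gene(f"g{i}", "c1", pos, pos + glen))
            pos += glen + 1_000
        gs = GeneSet(genes)
        mpos = rng.integers(0, size - 1, size=4_000)
        markers = [("c1", int(p), int(p) + 1) for p in mpos]
        h = gene_fragment_histogram(markers, gs)
        assert h.observed_pct[0] > h.poisson_pct[0]


class TestCandidateSubset:
    def test_subset_equals_whole(self, rng):
        markers, gs = _random_layout(rng)
        genome = _genome()
        full = distance_summary(markers, gs, genome, [0, 1000, 10_000, 100_000])
        cand = candidate_subset_summary(markers, gs, genome)
        assert cand.pct_markers_within == full.pct_markers_within
        assert cand.pct_genes_with_marker_within == full.pct_genes_with_marker_within
        assert cand.expected_pct_markers_at_0 == full.expected_pct_markers_at_0

    def test_single_candidate_uniform_markers(self, rng):
        # candidate covering 0.04% of genome; uniform markers land there at
        # about that rate (the EXP* construction)
        size = 1_000_000
        genome = Genome([("c1", random_dna(rng, size))])
        gs = GeneSet([Gene("cand", "c1", 500_000, 500_400)])
        exp = candidate_subset_summary(
            [("c1", 0, 1)], gs, genome
        ).expected_pct_markers_at_0
        assert exp == pytest.approx(0.04)
        pos = rng.integers(0, size - 1, size=200_000)
        markers = [("c1", int(p), int(p) + 1) for p in pos]
        ds = candidate_subset_summary(markers, gs, genome)
        assert ds.pct_markers_within[0] == pytest.approx(0.04, abs=0.02)

    def test_empty_marker_set_warns(self, rng, recwarn):
        _, gs = _random_layout(rng)
        ds = candidate_subset_summary([], gs, _genome())
        assert ds.pct_markers_within is None
        assert ds.pct_genes_with_marker_within == [0, 0, 0, 0]

    def test_thresholds_are_extended(self, rng):
        markers, gs = _random_layout(rng)
        ds = candidate_subset_summary(markers, gs, _genome())
        assert ds.thresholds == (0, 1_000, 10_000, 100_000)


class TestSpacerSymmetry:
    def test_doubling_coordinates_preserves_d0(self, rng):
        # inserting neutral spacer between all features (doubling every
        # coordinate) cannot change overlap classifications
        markers, gs = _random_layout(rng)
        (p0,) = pct_markers_within(markers, gs, [0])
        markers2 = [(c, 2 * a, 2 * b) for (c, a, b) in markers]
        gs2 = GeneSet([Gene(g.id, g.chromosome, 2 * g.start, 2 * g.end) for g in gs])
        (p1,) = pct_markers_within(markers2, gs2, [0])
        assert p0 == p1
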