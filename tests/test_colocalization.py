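"""Hypergeometric overlap statistics, randomization nulls, clustering."""
import math

import numpy as np
import pytest

from combind.colocalization_stats import (
    SimilarityMatrix,
    UniverseModel,
    cluster_experiments,
    hypergeom_overlap,
    mc_overlap_null,
    randomize_positions,
    similarity_matrix,
    threshold_network,
)
from combind.core import BindingMatrix, Locus
from combind.errors import ConfigError

from conftest import make_peakset, random_intervals


def enum_tail(N, n_a, n_b, k):
    """Direct summation of the hypergeometric mass function from binomials."""
    total = 0.0
    for i in range(k, min(n_a, n_b) + 1):
        total += (
            math.comb(n_a, i) * math.comb(N - n_a, n_b - i) / math.comb(N, n_b)
        )
    return total


def matrix_with_counts(N_rows, n_a, n_b, k):
    """A two-experiment matrix realizing the given marginals and overlap."""
    col_a = np.zeros(N_rows, dtype=bool)
    col_b = np.zeros(N_rows, dtype=bool)
    col_a[:n_a] = True
    col_b[:k] = True
    col_b[n_a : n_a + n_b - k] = True
    loci = [Locus.from_span("chr1", 10 * i, 10 * i + 5) for i in range(N_rows)]
    return BindingMatrix(loci, ["A", "B"], ["FA", "FB"], np.column_stack([col_a, col_b]))


def test_expected_value_closed_form():
    m = matrix_with_counts(30, 10, 20, 5)
    stats = hypergeom_overlap(m, "A", "B", UniverseModel(100))
    assert stats.expected == pytest.approx(2.0)


@pytest.mark.parametrize("N,n_a,n_b,k", [(100, 10, 20, 5), (50, 25, 12, 9), (40, 38, 3, 3)])
def test_tail_and_z_match_enumeration(N, n_a, n_b, k):
    m = matrix_with_counts(max(n_a + n_b, 60), n_a, n_b, k)
    stats = hypergeom_overlap(m, "A", "B", UniverseModel(N))
    assert stats.p_upper == pytest.approx(enum_tail(N, n_a, n_b, k), rel=1e-10)
    expected = n_a * n_b / N
    var = expected * (N - n_a) / N * (N - n_b) / (N - 1)
    assert stats.z == pytest.approx((k - expected) / math.sqrt(var))


def test_zero_marginal_is_degenerate():
    m = matrix_with_counts(20, 0, 5, 0)
    stats = hypergeom_overlap(m, "A", "B", UniverseModel(50))
    assert stats.degenerate and stats.z == 0.0 and stats.expected == 0.0


def test_universe_too_small_errors():
    m = matrix_with_counts(30, 10, 20, 5)
    with pytest.raises(ConfigError, match="universe"):
        hypergeom_overlap(m, "A", "B", UniverseModel(15))


def test_tail_non_increasing_in_k():
    for N in (20, 57, 113, 200):
        n_a, n_b = N // 3, N // 2
        tails = [enum_tail(N, n_a, n_b, k) for k in range(min(n_a, n_b) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


def test_randomize_preserves_widths_and_is_seed_deterministic():
    rng = np.random.default_rng(0)
    ps = make_peakset(random_intervals(rng, 200))
    r1 = randomize_positions(ps, seed=42)
    r2 = randomize_positions(ps, seed=42)
    r3 = randomize_positions(ps, seed=43)
    assert sorted(r1.widths()) == sorted(ps.widths())
    assert r1.df.equals(r2.df)
    assert not r1.df.equals(r3.df)
    assert len(r1) == len(ps)


def test_randomize_rejects_oversized_peak():
    ps = make_peakset([("chr1", 0, 500_000)])
    with pytest.raises(ConfigError, match="effective genome"):
        randomize_positions(ps, effective_genome=100_000)


def test_mc_null_degenerate_on_empty_set():
    a = make_peakset([("chr1", 0, 100)], experiment="a")
    b = make_peakset([], experiment="b")
    res = mc_overlap_null(a, b, n_iter=100, seed=1)
    assert res.observed == 0 and res.degenerate


def test_mc_null_detects_planted_cooccupancy():
    # two factors placed at the same hotspots half the time
    rng = np.random.default_rng(8)
    sizes = {"chr1": 2_000_000}
    hot = [int(rng.integers(0, 1_990_000)) for _ in range(120)]
    a = make_peakset([("chr1", h, h + 400) for h in hot], experiment="a", chrom_sizes=sizes)
    shared = hot[:60] + [int(rng.integers(0, 1_990_000)) for _ in range(60)]
    b = make_peakset([("chr1", h, h + 400) for h in shared], experiment="b", chrom_sizes=sizes)
    res = mc_overlap_null(a, b, n_iter=200, seed=3)
    assert res.mc_z is not None and res.mc_z > 3


def test_similarity_symmetric_and_matches_pairwise_calls(small_bundle):
    from combind.locus_integration import build_matrix, integrate_loci

    sets = list(small_bundle.source_peaks.values())
    m = build_matrix(integrate_loci(sets), sets)
    universe = UniverseModel.from_loci(m.loci, small_bundle.config.genome_size)
    sim = similarity_matrix(m, universe)
    np.testing.assert_allclose(sim.z_values, sim.z_values.T)
    a, b = m.experiments[0], m.experiments[3]
    assert sim.z(a, b) == pytest.approx(hypergeom_overlap(m, a, b, universe).z)


def test_clustering_recovers_block_structure_and_singletons():
    exps = ["a1", "a2", "a3", "b1", "b2", "b3"]
    z = np.full((6, 6), 0.0)
    z[:3, :3] = 50.0
    z[3:, 3:] = 50.0
    np.fill_diagonal(z, np.nan)
    sim = SimilarityMatrix(exps, z)
    labels = cluster_experiments(sim, 2)
    assert len({labels[e] for e in exps[:3]}) == 1
    assert len({labels[e] for e in exps[3:]}) == 1
    assert labels["a1"] != labels["b1"]
    singletons = cluster_experiments(sim, 6)
    assert len(set(singletons.values())) == 6


def test_network_threshold_monotonicity():
    exps = ["a", "b", "c"]
    z = np.array([[np.nan, 5.0, 1.0], [5.0, np.nan, 3.0], [1.0, 3.0, np.nan]])
    sim = SimilarityMatrix(exps, z)
    assert threshold_network(sim, 10.0).edges == []
    assert len(threshold_network(sim, -np.inf).edges) == 3
    counts = [len(threshold_network(sim, t).edges) for t in (-1, 0, 2, 4, 6)]
    assert counts == sorted(counts, reverse=True)
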