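"""Signal-to-noise ranking and the weighted-KS enrichment score."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from combind.core import ExpressionTable
from combind.enrichment_gsea import (
    RankedList,
    enrichment_score,
    permutation_p,
    signal_to_noise,
)
from combind.errors import CombindError, ConfigError


def table_from(values, n_a=2, n_b=2):
    values = np.asarray(values, dtype=float)
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
    df = pd.DataFrame(values, columns=cols,
                      index=pd.Index([f"g{i}" for i in range(len(values))], name="gene_id"))
    return ExpressionTable(df, groups)


def test_identical_groups_score_zero():
    t = table_from([[3, 5, 3, 5]])
    assert signal_to_noise(t).stats[0] == 0.0


def test_snr_direct_formula():
    # mean_A=4, mean_B=2, sd_A=sd_B=sqrt(2) -> floors (0.2*mean) inactive
    t = table_from([[3, 5, 1, 3]])
    sd = np.std([3, 5], ddof=1)
    assert signal_to_noise(t).stats[0] == pytest.approx(2 / (2 * sd))


def test_snr_floor_activates_on_tiny_variance():
    # sd ~ 0 but mean 10 -> floor 0.2*10=2 per group
    t = table_from([[10.0, 10.0, 5.0, 5.0]])
    assert signal_to_noise(t).stats[0] == pytest.approx(5 / (2 + 1))


def test_snr_ordering_matches_independent_recomputation():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 10, size=(30, 6))
    t = table_from(vals, n_a=3, n_b=3)
    ranked = signal_to_noise(t)
    def snr(row):
        a, b = row[:3], row[3:]
        sa = max(np.std(a, ddof=1), 0.2 * abs(np.mean(a)), 0.2)
        sb = max(np.std(b, ddof=1), 0.2 * abs(np.mean(b)), 0.2)
        return (np.mean(a) - np.mean(b)) / (sa + sb)
    expected = sorted(
        ((snr(vals[i]), f"g{i}") for i in range(30)), key=lambda t_: (-t_[0], t_[1])
    )
    assert ranked.genes == [g for _, g in expected]
    np.testing.assert_allclose(ranked.stats, [s for s, _ in expected])


def brute_force_walk(stats, hit_flags, p):
    """Step-by-step walk, independent of the vectorized implementation."""
    n = len(stats)
    n_h = sum(hit_flags)
    denom = sum(abs(s) ** p for s, h in zip(stats, hit_flags) if h)
    running, best = 0.0, 0.0
    for s, h in zip(stats, hit_flags):
        running += (abs(s) ** p / denom) if h else -1.0 / (n - n_h)
        if abs(running) > abs(best):
            best = running
    return best


def test_es_matches_brute_force_walk_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(100):
        stats = np.sort(rng.normal(0, 1, 20))[::-1]
        genes = [f"g{i}" for i in range(20)]
        ranked = RankedList(genes, stats)
        hit_idx = rng.choice(20, size=5, replace=False)
        gene_set = {genes[i] for i in hit_idx}
        hits = [g in gene_set for g in genes]
        for p in (0.0, 1.0, 1.5):
            es, running = enrichment_score(ranked, gene_set, weight_p=p)
            assert es == pytest.approx(brute_force_walk(stats, hits, p))
            assert -1 <= es <= 1
            assert running[-1] == pytest.approx(0.0, abs=1e-12)


def test_p0_limit_equals_classical_ks_statistic():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = 40
        stats = np.sort(rng.normal(0, 1, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, stats)
        hit_idx = rng.choice(n, size=8, replace=False)
        gene_set = {genes[i] for i in hit_idx}
        es, _ = enrichment_score(ranked, gene_set, weight_p=0.0)
        positions = np.arange(n)
        hits = np.array([g in gene_set for g in genes])
        ks = ks_2samp(positions[hits], positions[~hits]).statistic
        assert abs(es) == pytest.approx(ks)


def test_top_gene_singleton_set_reaches_es_one():
    ranked = RankedList([f"g{i}" for i in range(10)], np.linspace(5, -5, 10))
    es, _ = enrichment_score(ranked, {"g0"}, weight_p=0.0)
    assert es == pytest.approx(1.0)


def test_degenerate_sets_rejected():
    ranked = RankedList(["g0", "g1"], np.array([1.0, 0.5]))
    with pytest.raises(CombindError):
        enrichment_score(ranked, set())
    with pytest.raises(CombindError):
        enrichment_score(ranked, {"g0", "g1"})


def test_group_swap_negates_es():
    rng = np.random.default_rng(3)
    vals = rng.uniform(1, 10, size=(40, 8))
    t = table_from(vals, n_a=4, n_b=4)
    swapped = ExpressionTable(
        t.values, {s: ("B" if g == "A" else "A") for s, g in t.groups.items()}
    )
    gene_set = {f"g{i}" for i in range(0, 40, 5)}
    es1, _ = enrichment_score(signal_to_noise(t), gene_set)
    es2, _ = enrichment_score(signal_to_noise(swapped), gene_set)
    assert es1 == pytest.approx(-es2)


def test_permutation_same_seed_identical_and_p_positive():
    rng = np.random.default_rng(4)
    vals = rng.uniform(1, 10, size=(60, 10))
    t = table_from(vals, n_a=5, n_b=5)
    gene_set = {f"g{i}" for i in range(12)}
    r1 = permutation_p(t, gene_set, n_perm=100, seed=9)
    r2 = permutation_p(t, gene_set, n_perm=100, seed=9)
    assert r1 == r2
    assert 0 < r1.p_value <= 1


def test_small_design_falls_back_to_gene_set_mode(caplog):
    rng = np.random.default_rng(5)
    t = table_from(rng.uniform(1, 10, size=(30, 4)), n_a=2, n_b=2)
    res = permutation_p(t, {f"g{i}" for i in range(6)}, n_perm=100, seed=1)
    assert res.mode == "gene_set"


def test_nperm_validation():
    t = table_from(np.ones((10, 4)))
    with pytest.raises(ConfigError):
        permutation_p(t, {"g0"}, n_perm=10)
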