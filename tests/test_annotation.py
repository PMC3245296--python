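"""Proximity classification, region enrichment, and signal metaprofiles."""
import numpy as np
import pandas as pd
import pytest

from combind.annotation import classify_proximity, region_overlap_enrichment, signal_profile
from combind.core import GeneAnnotation, Locus, SignalTrack
from combind.errors import CombindError, ConfigError

SIZES = {"chr1": 1_000_000}


def genes_at(positions, chrom="chr1"):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(positions))],
                "chrom": chrom,
                "tss": positions,
                "strand": "+",
            }
        )
    )


def test_proximal_distal_boundary():
    loci = [Locus.from_span("chr1", 0, 200)]  # midpoint 100
    near = classify_proximity(loci, genes_at([600]))
    assert near.iloc[0]["klass"] == "proximal" and near.iloc[0]["distance"] == 500
    far = classify_proximity(loci, genes_at([1101]))
    assert far.iloc[0]["klass"] == "distal" and far.iloc[0]["distance"] == 1001


def test_missing_chromosome_flagged_distal():
    loci = [Locus.from_span("chr2", 0, 100)]
    out = classify_proximity(loci, genes_at([500]))
    assert out.iloc[0]["flagged"] and out.iloc[0]["klass"] == "distal"


def test_nearest_tss_matches_brute_force_and_partitions():
    rng = np.random.default_rng(6)
    loci = [
        Locus.from_span("chr1", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 900_000, 80), rng.integers(50, 500, 80))
    ]
    tss = sorted(int(t) for t in rng.integers(0, 1_000_000, 60))
    out = classify_proximity(loci, genes_at(tss))
    for locus, row in zip(loci, out.itertuples(index=False)):
        mid = locus.interval.midpoint
        best = min(range(len(tss)), key=lambda i: (abs(tss[i] - mid), tss[i]))
        assert row.nearest_gene == f"g{best}"
        assert row.distance == tss[best] - mid
    assert (out["klass"].isin(["proximal", "distal"])).all()
    assert (out["klass"] == "proximal").sum() + (out["klass"] == "distal").sum() == len(loci)


def test_region_fraction_extremes():
    loci = [Locus.from_span("chr1", 1000 * i, 1000 * i + 100) for i in range(20)]
    whole = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
    frac, z, _ = region_overlap_enrichment(loci, whole, SIZES, n_iter=100, seed=0)
    assert frac == 1.0
    disjoint = pd.DataFrame({"chrom": ["chr1"], "start": [900_000], "end": [900_100]})
    frac, z, _ = region_overlap_enrichment(loci, disjoint, SIZES, n_iter=100, seed=0)
    assert frac == 0.0
    assert z is None or z <= 0


def test_region_fraction_invariant_to_splitting():
    loci = [Locus.from_span("chr1", 500, 600), Locus.from_span("chr1", 5000, 5100)]
    one = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [700]})
    split = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [400, 500, 600], "end": [500, 600, 700]})
    f1, _, _ = region_overlap_enrichment(loci, one, SIZES, n_iter=100, seed=1)
    f2, _, _ = region_overlap_enrichment(loci, split, SIZES, n_iter=100, seed=1)
    assert f1 == f2 == 0.5


def constant_track(value, end=1_000_000):
    return SignalTrack("g", {"chr1": (np.array([0]), np.array([end]), np.array([value]))})


def test_profile_constant_track():
    loci = [Locus.from_span("chr1", 10_000, 10_400), Locus.from_span("chr1", 50_000, 50_200)]
    prof = signal_profile(loci, constant_track(3.5))
    np.testing.assert_allclose(prof.values, 3.5)
    assert prof.n_loci == 2 and prof.values.size == 60


def test_profile_single_central_bump():
    locus = Locus.from_span("chr1", 10_000, 10_000 + 200)  # midpoint 10100
    # nonzero exactly over the bin [midpoint, midpoint+100) with 60 bins over +-3000
    track = SignalTrack(
        "g", {"chr1": (np.array([10_100]), np.array([10_200]), np.array([7.0]))}
    )
    prof = signal_profile([locus], track)
    nonzero = np.flatnonzero(prof.values)
    assert nonzero.tolist() == [30]
    assert prof.values[30] == pytest.approx(7.0)


def test_profile_linearity_in_track():
    rng = np.random.default_rng(2)
    starts = np.sort(rng.choice(np.arange(0, 500_000, 100), 50, replace=False))
    runs = (starts, starts + 80, rng.uniform(0, 5, 50))
    track = SignalTrack("g", {"chr1": runs})
    scaled = SignalTrack("g", {"chr1": (runs[0], runs[1], 2.5 * runs[2])})
    loci = [Locus.from_span("chr1", int(s), int(s) + 300) for s in rng.integers(4000, 400_000, 30)]
    p1 = signal_profile(loci, track)
    p2 = signal_profile(loci, scaled)
    np.testing.assert_allclose(p2.values, 2.5 * p1.values)


def test_profile_matches_per_base_oracle():
    rng = np.random.default_rng(4)
    starts = np.sort(rng.choice(np.arange(0, 40_000, 10), 120, replace=False))
    widths = rng.integers(1, 10, 120)
    values = rng.uniform(0, 3, 120)
    ends = np.minimum(starts + widths, np.append(starts[1:], 40_000))
    keep = ends > starts
    track = SignalTrack("g", {"chr1": (starts[keep], ends[keep], values[keep])})
    base = np.zeros(60_000)
    for s, e, v in zip(starts[keep], ends[keep], values[keep]):
        base[s:e] = v
    loci = [Locus.from_span("chr1", int(s), int(s) + 100) for s in rng.integers(6000, 30_000, 10)]
    prof = signal_profile(loci, track, window=3000, n_bins=20)
    bin_width = 300
    expected = np.zeros(20)
    for b in range(20):
        acc = []
        for locus in loci:
            a = locus.interval.midpoint
            lo = a - 3000 + b * bin_width
            acc.append(base[lo : lo + bin_width].mean())
        expected[b] = np.mean(acc)
    np.testing.assert_allclose(prof.values, expected, atol=1e-12)


def test_profile_input_validation():
    with pytest.raises(CombindError):
        signal_profile([], constant_track(1.0))
    with pytest.raises(ConfigError, match="divide"):
        signal_profile([Locus.from_span("chr1", 0, 10)], constant_track(1.0), window=3000, n_bins=7)
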