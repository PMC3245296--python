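"""Block-map remapping and cross-species conservation calls."""
import numpy as np
import pandas as pd
import pytest

from combind.conservation import (
    OrthologyMap,
    call_conserved,
    conservation_by_combination,
    conserved_combination_matrix,
    map_loci,
    map_locus,
    read_map,
    write_map,
)
from combind.core import Locus
from combind.errors import FormatError
from combind.locus_integration import build_matrix, integrate_loci

from conftest import make_peakset

COLS = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end", "strand"]


def omap_from(rows):
    return OrthologyMap(pd.DataFrame(rows, columns=COLS))


def test_simple_offset_mapping():
    omap = omap_from([("chr1", 100, 200, "chrT", 1100, 1200, "+")])
    mapped = map_locus(Locus.from_span("chr1", 120, 180), omap)
    assert mapped.status == "mapped"
    assert (mapped.target.chrom, mapped.target.start, mapped.target.end) == ("chrT", 1120, 1180)


def test_split_across_chromosomes_is_ambiguous():
    omap = omap_from(
        [("chr1", 120, 150, "chrT", 0, 30, "+"), ("chr1", 150, 180, "chrU", 0, 30, "+")]
    )
    assert map_locus(Locus.from_span("chr1", 120, 180), omap).status == "ambiguous"


def test_low_coverage_is_below_minmatch():
    omap = omap_from([("chr1", 0, 50, "chrT", 0, 50, "+")])
    mapped = map_locus(Locus.from_span("chr1", 0, 1000), omap, minmatch=0.1)
    assert mapped.status == "below_minmatch"
    # 5% coverage passes a 5% minmatch
    assert map_locus(Locus.from_span("chr1", 0, 1000), omap, minmatch=0.05).status == "mapped"


def test_no_block_is_unmapped():
    omap = omap_from([("chr2", 0, 100, "chrT", 0, 100, "+")])
    assert map_locus(Locus.from_span("chr1", 0, 50), omap).status == "unmapped"


def test_far_split_on_same_chromosome_is_ambiguous():
    omap = omap_from(
        [("chr1", 0, 50, "chrT", 0, 50, "+"), ("chr1", 50, 100, "chrT", 100_000, 100_050, "+")]
    )
    assert map_locus(Locus.from_span("chr1", 0, 100), omap).status == "ambiguous"


def test_negative_strand_reflection_and_roundtrip():
    omap = omap_from([("chr1", 100, 200, "chrT", 500, 600, "-")])
    mapped = map_locus(Locus.from_span("chr1", 120, 150), omap)
    # bases 120..149 reflect to 550..580 on the forward strand
    assert (mapped.target.start, mapped.target.end) == (550, 580)
    back = omap_from([("chrT", 500, 600, "chr1", 100, 200, "-")])
    again = map_locus(Locus.from_span("chrT", 550, 580), back)
    assert (again.target.start, again.target.end) == (120, 150)


def test_identity_map_is_identity_property():
    sizes = {"chr1": 10_000, "chr2": 5_000}
    omap = OrthologyMap.identity(sizes)
    rng = np.random.default_rng(0)
    for _ in range(50):
        c = "chr1" if rng.random() < 0.5 else "chr2"
        s = int(rng.integers(0, sizes[c] - 100))
        w = int(rng.integers(1, 100))
        mapped = map_locus(Locus.from_span(c, s, s + w), omap)
        assert mapped.status == "mapped"
        assert (mapped.target.chrom, mapped.target.start, mapped.target.end) == (c, s, s + w)


def test_overlapping_source_blocks_rejected():
    with pytest.raises(FormatError, match="overlap"):
        omap_from([("chr1", 0, 100, "chrT", 0, 100, "+"), ("chr1", 50, 150, "chrT", 200, 300, "+")])


def test_length_mismatch_rejected():
    with pytest.raises(FormatError, match="length"):
        omap_from([("chr1", 0, 100, "chrT", 0, 90, "+")])


def test_map_roundtrip_file(tmp_path):
    omap = omap_from([("chr1", 0, 100, "chrT", 50, 150, "+")])
    write_map(omap, tmp_path / "m.tsv")
    again = read_map(tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(again.blocks, omap.blocks)


def test_minmatch_monotonicity(default_bundle):
    loci = integrate_loci([default_bundle.source_peaks[f] for f in default_bundle.config.factors])
    counts = []
    for minmatch in (0.05, 0.1, 0.5, 1.0):
        mapped = map_loci(loci, default_bundle.truth.omap, minmatch)
        counts.append(sum(m.status == "mapped" for m in mapped))
    assert counts == sorted(counts, reverse=True)


def _matrices(peaksets):
    loci = integrate_loci(peaksets)
    return build_matrix(loci, peaksets)


def test_identity_self_conservation():
    ps = make_peakset([("chr1", 100, 300), ("chr1", 5000, 5400), ("chr2", 70, 200)], factor="FA")
    m = _matrices([ps])
    omap = OrthologyMap.identity(ps.chrom_sizes)
    flags = call_conserved(m, m, omap, "FA")
    assert flags["conserved"].all()
    assert (flags["status"] == "mapped").all()


def test_empty_target_matrix_conserves_nothing():
    ps = make_peakset([("chr1", 100, 300)], factor="FA")
    empty = make_peakset([], experiment="t", factor="FA")
    m_src = _matrices([ps])
    m_tgt = build_matrix([], [empty])
    omap = OrthologyMap.identity(ps.chrom_sizes)
    flags = call_conserved(m_src, m_tgt, omap, "FA")
    assert not flags["conserved"].any()


def test_conserved_matrix_diagonal_and_normalized():
    rng = np.random.default_rng(3)
    sets = []
    base = [(int(s), int(s) + 200) for s in rng.integers(0, 900_000, 40) * 1]
    for i, fac in enumerate(["FA", "FB", "FC"]):
        ivs = [("chr1", s, e) for s, e in base]  # all factors at all loci: triple everywhere
        sets.append(make_peakset(ivs, experiment=f"e{i}", factor=fac))
    m = _matrices(sets)
    omap = OrthologyMap.identity(sets[0].chrom_sizes)
    table = conserved_combination_matrix(m, m, omap, ["FA", "FB", "FC"])
    triple_row = table[table["source_combination"] == "FA+FB+FC"].iloc[0]
    assert triple_row["target_3_factors"] == pytest.approx(1.0)
    fractions = table[[f"target_{j}_factors" for j in range(4)]].dropna()
    np.testing.assert_allclose(fractions.sum(axis=1), 1.0)


def test_whole_genome_stratification_matches_unstratified(small_bundle):
    factors = list(small_bundle.config.factors)
    src_sets = [small_bundle.source_peaks[f] for f in factors]
    tgt_sets = [small_bundle.target_peaks[f] for f in factors]
    m_src = _matrices(src_sets)
    m_tgt = _matrices(tgt_sets)
    whole = pd.DataFrame(
        [(c, 0, size) for c, size in small_bundle.truth.chrom_sizes_src.items()],
        columns=["chrom", "start", "end"],
    )
    plain = conservation_by_combination(m_src, m_tgt, small_bundle.truth.omap, factors)
    strat = conservation_by_combination(
        m_src, m_tgt, small_bundle.truth.omap, factors, extra_condition=whole
    )
    pd.testing.assert_frame_equal(plain, strat)
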