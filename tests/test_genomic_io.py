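"""Format readers/writers: strict parsing, exact coordinate round-trips."""
import numpy as np
import pandas as pd
import pytest

from combind.core import BindingMatrix, Locus
from combind.errors import ConsistencyError, FormatError
from combind.genomic_io import (
    read_expression,
    read_loci,
    read_peaks,
    read_signal,
    read_tss,
    write_expression,
    write_loci,
    write_peaks,
)

SIZES = {"chr1": 1000}


def test_read_bed3_maps_fields_directly(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\n")
    ps = read_peaks(p, "e", "F", SIZES)
    peak = next(ps.peaks)
    assert (peak.interval.chrom, peak.interval.start, peak.interval.end) == ("chr1", 100, 200)
    assert peak.score == 0.0


@pytest.mark.parametrize(
    "line",
    [
        "chr1\t200\t100",  # start >= end
        "chr1\t100",  # too few columns
        "chr9\t100\t200",  # unknown chromosome
        "chr1\t900\t1100",  # beyond chromosome end
    ],
)
def test_read_peaks_rejects_malformed_lines(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text(line + "\n")
    with pytest.raises(FormatError, match=":1"):
        read_peaks(p, "e", "F", SIZES)


def test_read_narrowpeak_score_and_summit(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t200\tpk1\t800\t.\t12.3\t7.5\t6.1\t25\n")
    peak = next(read_peaks(p, "e", "F", SIZES).peaks)
    assert peak.score == 7.5
    assert peak.summit_offset == 25


def test_peaks_sorted_after_loading(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t500\t600\nchr1\t100\t200\n")
    ps = read_peaks(p, "e", "F", SIZES)
    assert ps.df["start"].tolist() == [100, 500]


def test_peak_roundtrip_preserves_coordinates(tmp_path):
    src = tmp_path / "in.bed"
    src.write_text("chr1\t100\t200\nchr1\t300\t450\n")
    ps = read_peaks(src, "e", "F", SIZES)
    out = tmp_path / "out.bed"
    write_peaks(ps, out)
    again = read_peaks(out, "e", "F", SIZES)
    pd.testing.assert_frame_equal(ps.df[["chrom", "start", "end"]], again.df[["chrom", "start", "end"]])


def test_read_signal_single_run_and_empty(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t10\t2.0\n")
    track = read_signal(p)
    assert track.mean_value("chr1", 0, 10) == 2.0
    empty = tmp_path / "empty.bedgraph"
    empty.write_text("")
    assert read_signal(empty).mean_value("chr1", 0, 100) == 0.0


def test_read_signal_rejects_overlapping_spans(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t15\t2.0\n")
    with pytest.raises(FormatError, match="overlap"):
        read_signal(p)


def _toy_matrix():
    loci = [Locus.from_span("chr1", 0, 15), Locus.from_span("chr1", 20, 30)]
    entries = np.array([[1, 1], [0, 1]], dtype=bool)
    return loci, BindingMatrix(loci, ["expA", "expB"], ["FA", "FB"], entries)


def test_write_loci_roundtrip(tmp_path):
    loci, matrix = _toy_matrix()
    path = tmp_path / "loci.csv"
    write_loci(loci, matrix, path)
    loci2, matrix2 = read_loci(path)
    assert [l.locus_id for l in loci2] == [l.locus_id for l in loci]
    assert matrix2.experiments == matrix.experiments
    assert matrix2.factors == matrix.factors
    np.testing.assert_array_equal(matrix2.entries, matrix.entries)


def test_write_loci_count_mismatch(tmp_path):
    loci, matrix = _toy_matrix()
    with pytest.raises(ConsistencyError):
        write_loci(loci[:1], matrix, tmp_path / "x.csv")


def test_write_loci_zero_loci_header_only(tmp_path):
    matrix = BindingMatrix([], ["expA", "expB"], ["FA", "FB"], np.zeros((0, 2), dtype=bool))
    path = tmp_path / "empty.csv"
    write_loci([], matrix, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 2  # factor comment + header
    assert lines[1] == "chrom,start,end,expA,expB"


def test_tss_strand_aware(tmp_path):
    p = tmp_path / "tss.bed"
    p.write_text("chr1\t100\t200\tgeneA\t0\t+\nchr1\t300\t400\tgeneB\t0\t-\n")
    genes = read_tss(p)
    lookup = dict(zip(genes.df["gene_id"], genes.df["tss"]))
    assert lookup == {"geneA": 100, "geneB": 399}


def test_expression_roundtrip_and_group_check(tmp_path):
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["a1", "a2", "b1", "b2"],
    )
    from combind.core import ExpressionTable

    table = ExpressionTable(values, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    write_expression(table, tmp_path / "e.tsv", tmp_path / "g.tsv")
    again = read_expression(tmp_path / "e.tsv", tmp_path / "g.tsv")
    pd.testing.assert_frame_equal(again.values, values)
    with pytest.raises(ConsistencyError, match=">= 2 samples"):
        ExpressionTable(values[["a1", "a2", "b1"]], {"a1": "A", "a2": "A", "b1": "B"})
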