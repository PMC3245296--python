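"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED6 and 10-column narrowPeak for peaks, bedGraph for signal,
BED-like TSS annotation, a TSV expression table with a sidecar group file,
and the loci CSV (chrom, start, end, one 0/1 column per experiment).

Every reader rejects malformed input with the offending line number; no
silent repair. Coordinates pass through unchanged (0-based half-open).
"""
from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    BindingMatrix,
    ExpressionTable,
    GeneAnnotation,
    Locus,
    PeakSet,
    SignalTrack,
    _empty_peak_frame,
)
from .errors import ConsistencyError, FormatError


def _lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append((lineno, line.split("\t") if "\t" in line else line.split()))
    return out


def read_peaks(
    path,
    experiment_id: str,
    factor: str,
    chrom_sizes: Mapping[str, int],
    genome_id: str = "genome",
    scores_are_pvalues: bool = False,
) -> PeakSet:
    """Read a BED3+/narrowPeak peak list into a sorted :class:`PeakSet`.

    narrowPeak column 8 (-log10 p) becomes the score; a 4-6 column BED falls
    back to column 5 / 1000 if present, else 0. With ``scores_are_pvalues``
    the score column carries raw p-values and is converted to -log10.
    """
    chroms, starts, ends, scores, summits = [], [], [], [], []
    for lineno, cols in _lines(path):
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
        chrom = cols[0]
        if chrom not in chrom_sizes:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not (0 <= start < end):
            raise FormatError(f"{path}:{lineno}: need 0 <= start < end, got {start}, {end}")
        if end > chrom_sizes[chrom]:
            raise FormatError(
                f"{path}:{lineno}: end {end} beyond {chrom} length {chrom_sizes[chrom]}"
            )
        score, summit = 0.0, None
        if len(cols) >= 10:  # narrowPeak dialect
            score = float(cols[7])
            s = int(cols[9])
            summit = s if s >= 0 else None
        elif len(cols) >= 5:
            score = float(cols[4]) / 1000.0
        if scores_are_pvalues:
            score = -math.log10(score) if score > 0 else 320.0
        if score < 0:
            raise FormatError(f"{path}:{lineno}: negative score {score}")
        if summit is not None and not (0 <= summit < end - start):
            raise FormatError(f"{path}:{lineno}: summit offset {summit} outside peak")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        scores.append(score)
        summits.append(summit)
    if not chroms:
        df = _empty_peak_frame()
    else:
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.array(starts, dtype=np.int64),
                "end": np.array(ends, dtype=np.int64),
                "score": np.array(scores, dtype=float),
                "summit": summits,
            }
        )
    return PeakSet(df, experiment_id, factor, genome_id, chrom_sizes)


def write_peaks(peak_set: PeakSet, path) -> None:
    """Write as BED5 (score column carries -log10 p, not capped at 1000)."""
    with open(path, "w") as fh:
        for row in peak_set.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.score:g}\n")


def read_signal(path, genome_id: str = "genome") -> SignalTrack:
    """Read a bedGraph; overlapping spans are a format error."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, cols in _lines(path):
        if len(cols) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad bedGraph fields") from exc
        if not (0 <= start < end):
            raise FormatError(f"{path}:{lineno}: need 0 <= start < end")
        per_chrom.setdefault(cols[0], []).append((start, end, value))
    runs = {}
    for chrom, rows in per_chrom.items():
        s = np.array([r[0] for r in rows], dtype=np.int64)
        e = np.array([r[1] for r in rows], dtype=np.int64)
        v = np.array([r[2] for r in rows], dtype=float)
        runs[chrom] = (s, e, v)
    return SignalTrack(genome_id, runs)  # SignalTrack enforces disjointness


def write_signal(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            s, e, v = track.runs[chrom]
            for i in range(s.size):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")


def read_tss(path) -> GeneAnnotation:
    """BED-like TSS file: chrom, start, end, gene_id[, score, strand].

    The TSS position is the start for + / unstranded records and end-1 for -.
    """
    recs = []
    for lineno, cols in _lines(path):
        if len(cols) < 4:
            raise FormatError(f"{path}:{lineno}: TSS bed needs >= 4 columns")
        strand = cols[5] if len(cols) >= 6 else "+"
        start, end = int(cols[1]), int(cols[2])
        tss = start if strand != "-" else end - 1
        recs.append((cols[3], cols[0], tss, strand))
    return GeneAnnotation(pd.DataFrame(recs, columns=["gene_id", "chrom", "tss", "strand"]))


def read_regions(path) -> pd.DataFrame:
    """Plain BED3+ region set as a sorted frame (chrom, start, end)."""
    recs = []
    for lineno, cols in _lines(path):
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        start, end = int(cols[1]), int(cols[2])
        if not (0 <= start < end):
            raise FormatError(f"{path}:{lineno}: need 0 <= start < end")
        recs.append((cols[0], start, end))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_regions(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_loci(loci, matrix: BindingMatrix, path) -> None:
    """Loci CSV: chrom,start,end plus one 0/1 column per experiment.

    A ``#factors:`` comment line preserves experiment -> factor labels so the
    file round-trips through :func:`read_loci` without loss.
    """
    loci = list(loci)
    if len(loci) != matrix.n_loci:
        raise ConsistencyError(f"{len(loci)} loci vs {matrix.n_loci} matrix rows")
    with open(path, "w") as fh:
        fh.write("#factors:" + ",".join(f"{e}={f}" for e, f in zip(matrix.experiments, matrix.factors)) + "\n")
        fh.write(",".join(["chrom", "start", "end"] + list(matrix.experiments)) + "\n")
        for i, locus in enumerate(loci):
            flags = ",".join(str(int(x)) for x in matrix.entries[i])
            iv = locus.interval
            fh.write(f"{iv.chrom},{iv.start},{iv.end}" + ("," + flags if flags else "") + "\n")


def read_loci(path) -> tuple[list[Locus], BindingMatrix]:
    factors_map: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#factors:"):
            for pair in first[len("#factors:"):].split(","):
                if pair:
                    e, f = pair.split("=", 1)
                    factors_map[e] = f
            header = fh.readline().rstrip("\n")
        else:
            header = first
        cols = header.split(",")
        if cols[:3] != ["chrom", "start", "end"]:
            raise FormatError(f"{path}: bad loci header {cols[:3]}")
        experiments = cols[3:]
        loci: list[Locus] = []
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3 + len(experiments):
                raise FormatError(f"{path}:{lineno}: expected {3 + len(experiments)} fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            loci.append(Locus.from_span(chrom, start, end))
            rows.append([int(x) for x in parts[3:]])
    entries = np.array(rows, dtype=bool).reshape(len(loci), len(experiments))
    factors = [factors_map.get(e, e) for e in experiments]
    matrix = BindingMatrix(loci, experiments, factors, entries)
    return loci, matrix


def read_expression(expr_path, groups_path) -> ExpressionTable:
    """TSV with gene_id + one column per sample; sidecar maps sample -> group.

    Sidecar lines: ``sample_id<TAB>A`` or ``sample_id<TAB>B``.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups: dict[str, str] = {}
    for lineno, cols in _lines(groups_path):
        if len(cols) != 2 or cols[1] not in ("A", "B"):
            raise FormatError(f"{groups_path}:{lineno}: expected 'sample<TAB>A|B'")
        groups[cols[0]] = cols[1]
    return ExpressionTable(values, groups)


def write_expression(table: ExpressionTable, expr_path, groups_path) -> None:
    table.values.to_csv(expr_path, sep="\t")
    with open(groups_path, "w") as fh:
        for sample in table.values.columns:
            fh.write(f"{sample}\t{table.groups[sample]}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    for lineno, cols in _lines(path):
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: chrom sizes needs 2 columns")
        sizes[cols[0]] = int(cols[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
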