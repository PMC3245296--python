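"""Iterative integration of peaks into regulatory loci and the binding matrix.

A locus is a connected component of the >=1-bp overlap graph over all peaks
of all experiments; its interval spans min(start)..max(end) of the component,
so chained peaks extend a locus beyond any single peak ("iterative"
integration is order-independent by construction).
"""
from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

from .core import BindingMatrix, Locus, PeakSet
from .errors import ConsistencyError
from .intervals import merge, overlap_ranges


def _check_same_genome(peak_sets: Sequence[PeakSet]) -> None:
    genomes = {ps.genome_id for ps in peak_sets}
    if len(genomes) > 1:
        raise ConsistencyError(f"peak sets span multiple genomes: {sorted(genomes)}")


def integrate_loci(peak_sets: Sequence[PeakSet]) -> list[Locus]:
    """Merge all peaks from all experiments into disjoint, sorted loci."""
    _check_same_genome(peak_sets)
    per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for ps in peak_sets:
        for chrom, starts, ends in ps.by_chrom():
            per_chrom.setdefault(chrom, []).append((starts, ends))
    loci: list[Locus] = []
    for chrom in sorted(per_chrom):
        starts = np.concatenate([s for s, _ in per_chrom[chrom]])
        ends = np.concatenate([e for _, e in per_chrom[chrom]])
        ms, me, comp = merge(starts, ends)
        counts = np.bincount(comp, minlength=ms.size)
        for i in range(ms.size):
            loci.append(Locus.from_span(chrom, int(ms[i]), int(me[i]), int(counts[i])))
    return loci


def build_matrix(loci: Sequence[Locus], peak_sets: Sequence[PeakSet]) -> BindingMatrix:
    """Binary loci x experiments occupancy under the >=1-shared-base rule.

    Column order follows the input experiment order. A peak overlapping no
    locus is a consistency error (cannot happen when the loci were integrated
    from a superset of these peak sets).
    """
    _check_same_genome(peak_sets)
    loci = list(loci)
    # per-chromosome sorted locus arrays with global row indices
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chrom_rows: dict[str, list[int]] = {}
    for i, locus in enumerate(loci):
        chrom_rows.setdefault(locus.interval.chrom, []).append(i)
    for chrom, rows in chrom_rows.items():
        rows_arr = np.array(rows, dtype=np.int64)
        s = np.array([loci[i].interval.start for i in rows], dtype=np.int64)
        e = np.array([loci[i].interval.end for i in rows], dtype=np.int64)
        order = np.argsort(s, kind="mergesort")
        by_chrom[chrom] = (s[order], e[order], rows_arr[order])
    entries = np.zeros((len(loci), len(peak_sets)), dtype=bool)
    for j, ps in enumerate(peak_sets):
        for chrom, p_starts, p_ends in ps.by_chrom():
            if chrom not in by_chrom:
                raise ConsistencyError(
                    f"peak on {chrom} overlaps no locus (chromosome absent from loci)"
                )
            ls, le, rows = by_chrom[chrom]
            lo, hi = overlap_ranges(p_starts, p_ends, ls, le)
            if (hi <= lo).any():
                raise ConsistencyError(f"a peak of {ps.experiment_id} overlaps no locus")
            for a, b in zip(lo, hi):
                entries[rows[a:b], j] = True
    experiments = [ps.experiment_id for ps in peak_sets]
    factors = [ps.factor for ps in peak_sets]
    return BindingMatrix(loci, experiments, factors, entries)


def count_multiplicity(matrix: BindingMatrix) -> dict[int, int]:
    """Histogram of (number of experiments bound at a locus) -> locus count."""
    return dict(sorted(Counter(int(x) for x in matrix.row_sums()).items()))
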