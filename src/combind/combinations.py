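"""Combination queries over the binding matrix and conditional co-localization.

A query selects loci by occupancy pattern: all ``required`` labels bound
(AND), no ``forbidden`` label bound (NOT), and at least one ``any_of`` label
bound (OR). Labels are experiment ids or factor names; a factor name pools
all experiments of that factor (OR by default, AND with
``intersect_replicates``).

The headline statistic is the fraction of selected loci also bound by a
target factor, with a z-score against a null in which the target's peaks are
position-randomized while the conditioning loci stay fixed. Depletion shows
up as negative z.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .colocalization_stats import UniverseModel, randomize_positions
from .core import BindingMatrix, PeakSet
from .errors import ConfigError, QueryError
from .intervals import merge, overlaps_any


@dataclass(frozen=True)
class CombinationQuery:
    required: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()
    any_of: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        object.__setattr__(self, "any_of", frozenset(self.any_of))
        overlap = (self.required & self.forbidden) | (self.required & self.any_of) | (
            self.forbidden & self.any_of
        )
        if overlap:
            raise QueryError(f"labels in multiple roles: {sorted(overlap)}")

    @property
    def labels(self) -> frozenset[str]:
        return self.required | self.forbidden | self.any_of

    def describe(self) -> str:
        parts = []
        if self.required:
            parts.append("+".join(sorted(self.required)))
        if self.any_of:
            parts.append("v(" + "|".join(sorted(self.any_of)) + ")")
        if self.forbidden:
            parts.append("-" + "-".join(sorted(self.forbidden)))
        return " ".join(parts) if parts else "all"


def label_column(
    matrix: BindingMatrix, label: str, intersect_replicates: bool = False
) -> np.ndarray:
    """Occupancy vector for an experiment id or a pooled factor label."""
    idx = matrix.columns_for(label)
    if not idx:
        raise QueryError(f"unknown experiment or factor label {label!r}")
    cols = matrix.entries[:, idx]
    return cols.all(axis=1) if intersect_replicates else cols.any(axis=1)


def select_loci(
    matrix: BindingMatrix, query: CombinationQuery, intersect_replicates: bool = False
) -> np.ndarray:
    """Boolean mask over loci satisfying the query."""
    mask = np.ones(matrix.n_loci, dtype=bool)
    for label in query.required:
        mask &= label_column(matrix, label, intersect_replicates)
    for label in query.forbidden:
        mask &= ~label_column(matrix, label, intersect_replicates)
    if query.any_of:
        any_mask = np.zeros(matrix.n_loci, dtype=bool)
        for label in query.any_of:
            any_mask |= label_column(matrix, label, intersect_replicates)
        mask &= any_mask
    return mask


@dataclass(frozen=True)
class CombinationResult:
    query: CombinationQuery
    target: str
    n_selected: int
    n_cooccupied: int
    fraction: float  # NaN when n_selected == 0 (flagged empty)
    z: float | None = None  # Monte-Carlo z; None if no null was run or degenerate
    p: float | None = None  # two-sided empirical p
    analytic_z: float | None = None  # hypergeometric z conditioning on n_selected
    empty: bool = False


class _LociIndex:
    """Per-chromosome sorted locus arrays for fast column recomputation."""

    def __init__(self, matrix: BindingMatrix):
        rows: dict[str, list[int]] = {}
        for i, locus in enumerate(matrix.loci):
            rows.setdefault(locus.interval.chrom, []).append(i)
        self.by_chrom = {}
        for chrom, idx in rows.items():
            idx = np.array(idx, dtype=np.int64)
            s = np.array([matrix.loci[i].interval.start for i in idx], dtype=np.int64)
            e = np.array([matrix.loci[i].interval.end for i in idx], dtype=np.int64)
            order = np.argsort(s, kind="mergesort")
            self.by_chrom[chrom] = (s[order], e[order], idx[order])
        self.n_loci = matrix.n_loci

    def occupancy(self, peak_sets: Sequence[PeakSet]) -> np.ndarray:
        col = np.zeros(self.n_loci, dtype=bool)
        for ps in peak_sets:
            for chrom, p_s, p_e in ps.by_chrom():
                if chrom not in self.by_chrom:
                    continue
                l_s, l_e, idx = self.by_chrom[chrom]
                ms, me, _ = merge(p_s, p_e)
                hit = overlaps_any(l_s, l_e, ms, me)
                col[idx[hit]] = True
        return col


def target_null_columns(
    matrix: BindingMatrix,
    target_peak_sets: Sequence[PeakSet],
    n_iter: int = 500,
    effective_genome: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """n_iter position-randomized occupancy columns for a target's peaks.

    Shareable across queries: the null randomizes the target only, so the
    same draws serve every conditioning set.
    """
    rng = np.random.default_rng(seed)
    index = _LociIndex(matrix)
    genome = target_peak_sets[0].genome_size
    eff = effective_genome if effective_genome is not None else genome // 4
    cols = np.empty((n_iter, matrix.n_loci), dtype=bool)
    for i in range(n_iter):
        rand_sets = [randomize_positions(ps, eff, rng) for ps in target_peak_sets]
        cols[i] = index.occupancy(rand_sets)
    return cols


def combination_fraction(
    matrix: BindingMatrix,
    query: CombinationQuery,
    target: str,
    target_peak_sets: Sequence[PeakSet] | None = None,
    n_iter: int = 500,
    effective_genome: int | None = None,
    seed: int = 0,
    universe: UniverseModel | None = None,
    intersect_replicates: bool = False,
    null_columns: np.ndarray | None = None,
) -> CombinationResult:
    """Fraction of query-selected loci also bound by ``target``, with nulls.

    The Monte-Carlo null position-randomizes the target's peaks (keeping the
    selection fixed) and recomputes the co-occupied count per draw. The
    analytic z treats the n_selected loci as draws from the slot universe.
    """
    if target in query.labels:
        raise QueryError(f"target {target!r} is part of the query")
    selected = select_loci(matrix, query, intersect_replicates)
    n_selected = int(selected.sum())
    target_col = label_column(matrix, target, intersect_replicates)
    if n_selected == 0:
        return CombinationResult(query, target, 0, 0, float("nan"), empty=True)
    n_cooccupied = int((selected & target_col).sum())
    fraction = n_cooccupied / n_selected
    analytic_z = None
    if universe is not None:
        N = universe.n_slots
        n_t = int(target_col.sum())
        expected = n_selected * n_t / N
        var = expected * (N - n_selected) / N * (N - n_t) / (N - 1) if N > 1 else 0.0
        analytic_z = None if var <= 0 else float((n_cooccupied - expected) / np.sqrt(var))
    z = p = None
    if null_columns is None and target_peak_sets:
        null_columns = target_null_columns(
            matrix, target_peak_sets, n_iter, effective_genome, seed
        )
    if null_columns is not None:
        null = (null_columns & selected).sum(axis=1).astype(float)
        n_iter = null.size
        sd = null.std(ddof=1)
        if sd > 0:
            z = float((n_cooccupied - null.mean()) / sd)
        p_up = (1 + (null >= n_cooccupied).sum()) / (n_iter + 1)
        p_lo = (1 + (null <= n_cooccupied).sum()) / (n_iter + 1)
        p = float(min(1.0, 2 * min(p_up, p_lo)))
    return CombinationResult(
        query, target, n_selected, n_cooccupied, fraction, z, p, analytic_z
    )


def standard_query_family(factors: Sequence[str]) -> list[CombinationQuery]:
    """The standard bar-chart family over a factor triple.

    Single factors in two variants (others unconstrained, others forbidden),
    all pairs (AND, third unconstrained), the triple AND, the exclusive
    combinations with forbidden complements, and the any-of ("OR") query.
    """
    f = list(factors)
    if len(f) != 3:
        raise ConfigError(f"standard family needs exactly 3 factors, got {len(f)}")
    queries = []
    for x in f:
        queries.append(CombinationQuery(required={x}))
        queries.append(CombinationQuery(required={x}, forbidden=set(f) - {x}))
    for i in range(3):
        for j in range(i + 1, 3):
            queries.append(CombinationQuery(required={f[i], f[j]}))
            queries.append(
                CombinationQuery(required={f[i], f[j]}, forbidden=set(f) - {f[i], f[j]})
            )
    queries.append(CombinationQuery(required=set(f)))
    queries.append(CombinationQuery(any_of=set(f)))
    return queries


def exclusive_combinations(factors: Sequence[str]) -> list[CombinationQuery]:
    """The 8 mutually exclusive AND/NOT combinations over a factor triple."""
    f = list(factors)
    out = []
    for bits in range(8):
        req = {f[i] for i in range(3) if bits >> i & 1}
        out.append(CombinationQuery(required=req, forbidden=set(f) - req))
    return out


def combination_profile_table(
    matrix: BindingMatrix,
    factors: Sequence[str],
    targets: Sequence[str],
    target_peak_sets: dict[str, Sequence[PeakSet]] | None = None,
    n_iter: int = 500,
    effective_genome: int | None = None,
    seed: int = 0,
    universe: UniverseModel | None = None,
) -> pd.DataFrame:
    """One row per (query, target): the combination-conditional fractions."""
    nulls: dict[str, np.ndarray] = {}
    for t_i, target in enumerate(targets):
        peaks = (target_peak_sets or {}).get(target)
        if peaks:
            nulls[target] = target_null_columns(
                matrix, peaks, n_iter, effective_genome, seed + t_i
            )
    rows = []
    for query in standard_query_family(factors):
        for target in targets:
            res = combination_fraction(
                matrix, query, target, None, n_iter, effective_genome, seed,
                universe, null_columns=nulls.get(target),
            )
            rows.append(
                {
                    "query": query.describe(),
                    "target": target,
                    "n_selected": res.n_selected,
                    "n_cooccupied": res.n_cooccupied,
                    "fraction": res.fraction,
                    "z": res.z,
                    "p": res.p,
                    "analytic_z": res.analytic_z,
                }
            )
    return pd.DataFrame(rows)
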