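"""Cross-species binding conservation through an orthology block map.

The block map plays the role of a UCSC chain file + LiftOver: ordered,
equal-length interval pairs translating source-genome coordinates to a
target genome. A locus maps when enough of it (``minmatch``, default 0.1)
is covered by blocks and its image is unique — one target chromosome, with
same-chromosome image segments no farther apart than a gap tolerance.

A binding event is *conserved* when a source locus bound by a factor maps
to an interval sharing >=1 base with a target-genome locus bound by the
same factor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .combinations import (
    CombinationQuery,
    label_column,
    select_loci,
    standard_query_family,
    exclusive_combinations,
)
from .core import BindingMatrix, GenomicInterval, Locus
from .errors import ConfigError, FormatError
from .intervals import merge, overlaps_any


class OrthologyMap:
    """Equal-length interval blocks from a source to a target genome.

    Source blocks may not overlap within a chromosome; target strand '-'
    maps coordinates by reflection.
    """

    def __init__(self, blocks: pd.DataFrame):
        required = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end", "strand"]
        if list(blocks.columns) != required:
            raise FormatError(f"orthology map needs columns {required}")
        blocks = blocks.sort_values(["src_chrom", "src_start"], kind="mergesort").reset_index(drop=True)
        if len(blocks):
            src_len = blocks["src_end"] - blocks["src_start"]
            tgt_len = blocks["tgt_end"] - blocks["tgt_start"]
            if (src_len != tgt_len).any():
                raise FormatError("block source and target lengths differ")
            if (src_len < 1).any():
                raise FormatError("empty block")
            if (~blocks["strand"].isin(["+", "-"])).any():
                raise FormatError("block strand must be + or -")
            for chrom, sub in blocks.groupby("src_chrom", sort=False):
                if (sub["src_start"].to_numpy()[1:] < sub["src_end"].to_numpy()[:-1]).any():
                    raise FormatError(f"overlapping source blocks on {chrom}")
        self.blocks = blocks
        self._by_chrom = {
            chrom: (
                sub["src_start"].to_numpy(dtype=np.int64),
                sub["src_end"].to_numpy(dtype=np.int64),
                sub.index.to_numpy(),
            )
            for chrom, sub in blocks.groupby("src_chrom", sort=False)
        }

    @classmethod
    def identity(cls, chrom_sizes: Mapping[str, int]) -> "OrthologyMap":
        rows = [
            (chrom, 0, size, chrom, 0, size, "+") for chrom, size in chrom_sizes.items()
        ]
        return cls(pd.DataFrame(rows, columns=[
            "src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end", "strand"
        ]))

    def overlapping_blocks(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        if chrom not in self._by_chrom:
            return self.blocks.iloc[0:0]
        s, e, idx = self._by_chrom[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        return self.blocks.loc[idx[lo:hi]]


def read_map(path) -> OrthologyMap:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end", "strand"],
    )
    return OrthologyMap(df)


def write_map(omap: OrthologyMap, path) -> None:
    omap.blocks.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class MappedLocus:
    source: Locus
    target: GenomicInterval | None
    status: str  # mapped | unmapped | ambiguous | below_minmatch

    def __post_init__(self) -> None:
        if (self.target is not None) != (self.status == "mapped"):
            raise ConfigError("target present iff status == mapped")


def map_locus(
    locus: Locus,
    omap: OrthologyMap,
    minmatch: float = 0.1,
    gap_tolerance: int | None = None,
) -> MappedLocus:
    """Translate a locus through the block map.

    unmapped: no block overlap; below_minmatch: covered fraction < minmatch;
    ambiguous: image on >1 target chromosome, or same-chromosome segments
    separated by more than gap_tolerance (default 10x the locus length).
    Otherwise the target is the forward-strand span of the mapped bases.
    """
    if not (0 < minmatch <= 1):
        raise ConfigError(f"minmatch must be in (0, 1], got {minmatch}")
    iv = locus.interval
    if gap_tolerance is None:
        gap_tolerance = 10 * iv.length
    blocks = omap.overlapping_blocks(iv.chrom, iv.start, iv.end)
    if blocks.empty:
        return MappedLocus(locus, None, "unmapped")
    covered = 0
    segments: list[tuple[str, int, int]] = []
    for row in blocks.itertuples(index=False):
        ov_s = max(iv.start, row.src_start)
        ov_e = min(iv.end, row.src_end)
        covered += ov_e - ov_s
        if row.strand == "+":
            t_s = row.tgt_start + (ov_s - row.src_start)
            t_e = t_s + (ov_e - ov_s)
        else:  # reflection: source base p -> tgt_end - 1 - (p - src_start)
            t_e = row.tgt_end - (ov_s - row.src_start)
            t_s = t_e - (ov_e - ov_s)
        segments.append((row.tgt_chrom, t_s, t_e))
    if covered / iv.length < minmatch:
        return MappedLocus(locus, None, "below_minmatch")
    chroms = {c for c, _, _ in segments}
    if len(chroms) > 1:
        return MappedLocus(locus, None, "ambiguous")
    segments.sort(key=lambda t: t[1])
    for (_, _, prev_end), (_, next_start, _) in zip(segments, segments[1:]):
        if next_start - prev_end > gap_tolerance:
            return MappedLocus(locus, None, "ambiguous")
    tgt_chrom = segments[0][0]
    span = GenomicInterval(tgt_chrom, min(s for _, s, _ in segments), max(e for _, _, e in segments))
    return MappedLocus(locus, span, "mapped")


def map_loci(
    loci: Sequence[Locus], omap: OrthologyMap, minmatch: float = 0.1
) -> list[MappedLocus]:
    return [map_locus(l, omap, minmatch) for l in loci]


class _TargetIndex:
    """Sorted target-genome loci with per-factor occupancy for overlap tests."""

    def __init__(self, matrix_tgt: BindingMatrix):
        self.matrix = matrix_tgt
        rows: dict[str, list[int]] = {}
        for i, locus in enumerate(matrix_tgt.loci):
            rows.setdefault(locus.interval.chrom, []).append(i)
        self.by_chrom = {}
        for chrom, idx in rows.items():
            idx = np.array(idx, dtype=np.int64)
            s = np.array([matrix_tgt.loci[i].interval.start for i in idx], dtype=np.int64)
            e = np.array([matrix_tgt.loci[i].interval.end for i in idx], dtype=np.int64)
            order = np.argsort(s, kind="mergesort")
            self.by_chrom[chrom] = (s[order], e[order], idx[order])

    def bound_overlap(self, target: GenomicInterval, col: np.ndarray) -> bool:
        if target.chrom not in self.by_chrom:
            return False
        s, e, idx = self.by_chrom[target.chrom]
        lo = np.searchsorted(e, target.start, side="right")
        hi = np.searchsorted(s, target.end, side="left")
        return bool(col[idx[lo:hi]].any())

    def bound_factors(self, target: GenomicInterval, cols: dict[str, np.ndarray]) -> set[str]:
        if target.chrom not in self.by_chrom:
            return set()
        s, e, idx = self.by_chrom[target.chrom]
        lo = np.searchsorted(e, target.start, side="right")
        hi = np.searchsorted(s, target.end, side="left")
        hit = idx[lo:hi]
        return {f for f, col in cols.items() if col[hit].any()}


def call_conserved(
    matrix_src: BindingMatrix,
    matrix_tgt: BindingMatrix,
    omap: OrthologyMap,
    factor: str,
    minmatch: float = 0.1,
) -> pd.DataFrame:
    """Per-locus conservation flags for every source locus bound by ``factor``.

    Returns a frame with locus_id, status, conserved; unmapped / ambiguous /
    below_minmatch loci are never conserved but stay in the tally.
    """
    src_col = label_column(matrix_src, factor)
    tgt_col = label_column(matrix_tgt, factor)
    index = _TargetIndex(matrix_tgt)
    rows = []
    for i in np.flatnonzero(src_col):
        locus = matrix_src.loci[i]
        mapped = map_locus(locus, omap, minmatch)
        conserved = mapped.status == "mapped" and index.bound_overlap(mapped.target, tgt_col)
        rows.append((locus.locus_id, mapped.status, conserved))
    return pd.DataFrame(rows, columns=["locus_id", "status", "conserved"])


@dataclass(frozen=True)
class ConservationResult:
    query: CombinationQuery
    factor: str
    n_query_loci: int
    n_mappable: int
    n_conserved: int
    fraction_conserved: float  # over mappable loci; NaN when none map
    z: float | None = None


def _conserved_count(
    loci: Sequence[Locus],
    omap: OrthologyMap,
    index: _TargetIndex,
    tgt_col: np.ndarray,
    minmatch: float,
) -> tuple[int, int]:
    n_mappable = n_conserved = 0
    for locus in loci:
        mapped = map_locus(locus, omap, minmatch)
        if mapped.status == "mapped":
            n_mappable += 1
            if index.bound_overlap(mapped.target, tgt_col):
                n_conserved += 1
    return n_mappable, n_conserved


def _randomize_loci(
    loci: Sequence[Locus], chrom_sizes: Mapping[str, int], rng: np.random.Generator
) -> list[Locus]:
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    probs = sizes / sizes.sum()
    out = []
    for locus in loci:
        w = locus.interval.length
        for _ in range(1000):
            c = int(rng.choice(len(chroms), p=probs))
            if sizes[c] >= w:
                break
        start = int(rng.integers(0, sizes[c] - w + 1))
        out.append(Locus.from_span(chroms[c], start, start + w))
    return out


def conservation_by_combination(
    matrix_src: BindingMatrix,
    matrix_tgt: BindingMatrix,
    omap: OrthologyMap,
    factors: Sequence[str],
    minmatch: float = 0.1,
    extra_condition: pd.DataFrame | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
    n_iter: int = 0,
    seed: int = 0,
    queries: Sequence[CombinationQuery] | None = None,
) -> pd.DataFrame:
    """Conserved fractions per (combination query, factor).

    ``extra_condition`` (a BED-like frame) restricts each query to loci
    overlapping the region set — the developmental-enhancer stratification.
    With ``n_iter`` > 0 and ``chrom_sizes`` given, a randomized-locus null
    (uniform re-placement of the selected loci, remap, recount) yields z.
    """
    index = _TargetIndex(matrix_tgt)
    region_mask = None
    if extra_condition is not None:
        region_mask = _region_overlap_mask(matrix_src.loci, extra_condition)
    rows = []
    rng = np.random.default_rng(seed)
    for query in (queries if queries is not None else standard_query_family(factors)):
        sel = select_loci(matrix_src, query)
        if region_mask is not None:
            sel = sel & region_mask
        for factor in factors:
            fac_col = label_column(matrix_src, factor)
            take = np.flatnonzero(sel & fac_col)
            loci = [matrix_src.loci[i] for i in take]
            tgt_col = label_column(matrix_tgt, factor)
            n_mappable, n_conserved = _conserved_count(loci, omap, index, tgt_col, minmatch)
            frac = n_conserved / n_mappable if n_mappable else float("nan")
            z = None
            if n_iter > 0 and chrom_sizes is not None and loci:
                null = np.empty(n_iter)
                for it in range(n_iter):
                    rand = _randomize_loci(loci, chrom_sizes, rng)
                    _, null[it] = _conserved_count(rand, omap, index, tgt_col, minmatch)
                sd = null.std(ddof=1)
                z = float((n_conserved - null.mean()) / sd) if sd > 0 else None
            rows.append(
                {
                    "query": query.describe(),
                    "factor": factor,
                    "n_query_loci": len(loci),
                    "n_mappable": n_mappable,
                    "n_conserved": n_conserved,
                    "fraction_conserved": frac,
                    "z": z,
                }
            )
    return pd.DataFrame(rows)


def _region_overlap_mask(loci: Sequence[Locus], regions: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(loci), dtype=bool)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        ms, me, _ = merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        by_chrom[chrom] = (ms, me)
    for i, locus in enumerate(loci):
        iv = locus.interval
        if iv.chrom in by_chrom:
            ms, me = by_chrom[iv.chrom]
            mask[i] = bool(
                overlaps_any(np.array([iv.start]), np.array([iv.end]), ms, me)[0]
            )
    return mask


def conserved_combination_matrix(
    matrix_src: BindingMatrix,
    matrix_tgt: BindingMatrix,
    omap: OrthologyMap,
    factors: Sequence[str],
    minmatch: float = 0.1,
) -> pd.DataFrame:
    """Distribution of target-genome combination classes per source combination.

    Rows: the 8 exclusive source combinations of the factor triple; columns:
    number of the three factors bound at the orthologous position (0..3, with
    3 = the full triple). Row fractions are over mapped loci and sum to 1.
    """
    tgt_cols = {f: label_column(matrix_tgt, f) for f in factors}
    index = _TargetIndex(matrix_tgt)
    rows = []
    for query in exclusive_combinations(factors):
        sel = np.flatnonzero(select_loci(matrix_src, query))
        counts = np.zeros(len(factors) + 1, dtype=np.int64)
        n_mapped = 0
        for i in sel:
            mapped = map_locus(matrix_src.loci[i], omap, minmatch)
            if mapped.status != "mapped":
                continue
            n_mapped += 1
            bound = index.bound_factors(mapped.target, tgt_cols)
            counts[len(bound)] += 1
        row = {"source_combination": query.describe(), "n_mapped": n_mapped}
        for j in range(len(factors) + 1):
            row[f"target_{j}_factors"] = counts[j] / n_mapped if n_mapped else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
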