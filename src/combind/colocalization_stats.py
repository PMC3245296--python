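"""Pairwise co-localization significance and the co-binding network.

Two complementary nulls quantify how surprising a shared-binding count is:

* a hypergeometric "slot" model — the effective genome (by default one
  quarter of the genome, a deliberately conservative choice) is divided into
  N slots of one typical locus width; the loci bound by experiment A and by
  experiment B are draws from those slots, and the number bound by both
  follows Hypergeom(N, n_a, n_b);
* a Monte-Carlo position-randomization null — one peak set keeps its peak
  lengths but receives uniformly random positions within the effective
  genome, and the loci-level overlap count is recomputed per draw.

The z-scores from the hypergeometric test feed the experiment similarity
matrix, average-linkage clustering, and the thresholded co-binding network.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .core import BindingMatrix, Locus, PeakSet
from .errors import ConfigError
from .intervals import merge


@dataclass(frozen=True)
class UniverseModel:
    """Discrete universe for the hypergeometric overlap test.

    n_slots = floor(effective_genome / slot_width); the effective genome
    defaults to genome_size / 4 and the slot width to the median locus
    length of the integrated set.
    """

    n_slots: int

    def __post_init__(self) -> None:
        if self.n_slots < 1:
            raise ConfigError(f"universe needs >= 1 slot, got {self.n_slots}")

    @classmethod
    def from_loci(
        cls,
        loci: Sequence[Locus],
        genome_size: int,
        effective_genome_fraction: float = 0.25,
        slot_width: int | None = None,
    ) -> "UniverseModel":
        if slot_width is None:
            widths = [l.interval.length for l in loci]
            if not widths:
                raise ConfigError("cannot derive slot width from zero loci")
            slot_width = int(np.median(widths))
        if slot_width < 1:
            raise ConfigError(f"slot width must be >= 1, got {slot_width}")
        return cls(int(genome_size * effective_genome_fraction) // slot_width)


@dataclass(frozen=True)
class OverlapStats:
    n_universe: int
    n_a: int
    n_b: int
    k_observed: int
    expected: float
    variance: float
    z: float
    p_upper: float
    degenerate: bool = False
    mc_z: float | None = None
    mc_p: float | None = None


def hypergeom_overlap(
    matrix: BindingMatrix, exp_a: str, exp_b: str, universe: UniverseModel
) -> OverlapStats:
    """Exact hypergeometric moments and upper tail for a pair of experiments.

    z = (k - E[k]) / sd[k]; reported as 0 with the degenerate flag when the
    variance vanishes (empty column or saturated universe).
    """
    col_a = matrix.column(exp_a)
    col_b = matrix.column(exp_b)
    n_a, n_b = int(col_a.sum()), int(col_b.sum())
    k = int((col_a & col_b).sum())
    N = universe.n_slots
    if N < n_a or N < n_b:
        raise ConfigError(
            f"universe of {N} slots smaller than marginals ({n_a}, {n_b}); "
            "widen the effective genome or the slot width"
        )
    expected = n_a * n_b / N
    variance = expected * (N - n_a) / N * (N - n_b) / (N - 1) if N > 1 else 0.0
    degenerate = variance <= 0.0
    z = 0.0 if degenerate else (k - expected) / np.sqrt(variance)
    p_upper = float(hypergeom.sf(k - 1, N, n_a, n_b))
    return OverlapStats(N, n_a, n_b, k, expected, variance, z, p_upper, degenerate)


def _effective_lengths(chrom_sizes: dict[str, int], effective_genome: int) -> tuple[list[str], np.ndarray]:
    genome_size = sum(chrom_sizes.values())
    chroms = sorted(chrom_sizes)
    lengths = np.array(
        [max(1, int(chrom_sizes[c] * effective_genome / genome_size)) for c in chroms],
        dtype=np.int64,
    )
    return chroms, lengths


def randomize_positions(
    peak_set: PeakSet,
    effective_genome: int | None = None,
    seed: int | np.random.Generator = 0,
) -> PeakSet:
    """Place each peak, length preserved, uniformly within the effective genome.

    The effective genome (default genome_size / 4) is apportioned to the
    chromosomes proportionally to their true share; a chromosome is drawn
    with probability equal to that share and the start uniformly within it.
    Randomized peaks may overlap each other. Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if effective_genome is None:
        effective_genome = peak_set.genome_size // 4
    widths = peak_set.widths()
    if widths.size and int(widths.max()) > effective_genome:
        raise ConfigError(
            f"peak of {int(widths.max())} bp exceeds effective genome {effective_genome}"
        )
    chroms, lengths = _effective_lengths(peak_set.chrom_sizes, effective_genome)
    probs = lengths / lengths.sum()
    n = widths.size
    chrom_idx = rng.choice(lengths.size, size=n, p=probs)
    # redraw chromosomes too short for the peak until every placement fits
    for _ in range(10_000):
        bad = lengths[chrom_idx] < widths
        if not bad.any():
            break
        chrom_idx[bad] = rng.choice(lengths.size, size=int(bad.sum()), p=probs)
    else:
        raise ConfigError("could not place all peaks within the effective genome")
    room = lengths[chrom_idx] - widths + 1
    starts = (rng.random(n) * room).astype(np.int64)
    df = peak_set.df.copy()
    df["chrom"] = [chroms[i] for i in chrom_idx]
    df["start"] = starts
    df["end"] = starts + widths
    df["summit"] = None
    return peak_set.replace(df)


def _cobound_loci_count(set_a: PeakSet, set_b: PeakSet) -> int:
    """Number of integrated loci of a ∪ b covered by peaks of both sets."""
    total = 0
    a_chrom = {c: (s, e) for c, s, e in set_a.by_chrom()}
    b_chrom = {c: (s, e) for c, s, e in set_b.by_chrom()}
    for chrom in set(a_chrom) | set(b_chrom):
        sa, ea = a_chrom.get(chrom, (np.zeros(0, np.int64),) * 2)
        sb, eb = b_chrom.get(chrom, (np.zeros(0, np.int64),) * 2)
        if not sa.size or not sb.size:
            continue
        _, _, comp = merge(np.concatenate([sa, sb]), np.concatenate([ea, eb]))
        n_comp = int(comp.max()) + 1 if comp.size else 0
        in_a = np.zeros(n_comp, dtype=bool)
        in_b = np.zeros(n_comp, dtype=bool)
        in_a[comp[: sa.size]] = True
        in_b[comp[sa.size :]] = True
        total += int((in_a & in_b).sum())
    return total


@dataclass(frozen=True)
class MCNull:
    observed: int
    null_mean: float
    null_sd: float
    mc_p: float
    mc_z: float | None  # None when the null is degenerate (sd == 0)
    n_iter: int

    @property
    def degenerate(self) -> bool:
        return self.mc_z is None


def mc_overlap_null(
    set_a: PeakSet,
    set_b: PeakSet,
    n_iter: int = 1000,
    effective_genome: int | None = None,
    seed: int = 0,
    randomize_both: bool = False,
) -> MCNull:
    """Monte-Carlo null for the loci-level overlap of two peak sets.

    Randomizes set_b's positions (optionally both sets) ``n_iter`` times and
    recounts co-bound loci. mc_p uses the add-one empirical estimator, so it
    is never exactly zero.
    """
    if n_iter < 100:
        raise ConfigError(f"n_iter must be >= 100, got {n_iter}")
    rng = np.random.default_rng(seed)
    observed = _cobound_loci_count(set_a, set_b)
    null = np.empty(n_iter)
    for i in range(n_iter):
        rb = randomize_positions(set_b, effective_genome, rng)
        ra = randomize_positions(set_a, effective_genome, rng) if randomize_both else set_a
        null[i] = _cobound_loci_count(ra, rb)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    mc_p = float((1 + (null >= observed).sum()) / (n_iter + 1))
    mc_z = None if null_sd == 0 else (observed - null_mean) / null_sd
    return MCNull(observed, null_mean, null_sd, mc_p, mc_z, n_iter)


@dataclass
class SimilarityMatrix:
    experiments: list[str]
    z_values: np.ndarray  # symmetric, diagonal NaN

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.shape != (len(self.experiments),) * 2:
            raise ConfigError("similarity matrix shape mismatch")
        self.z_values = z

    def z(self, a: str, b: str) -> float:
        return float(self.z_values[self.experiments.index(a), self.experiments.index(b)])


def similarity_matrix(matrix: BindingMatrix, universe: UniverseModel) -> SimilarityMatrix:
    """Pairwise hypergeometric z for every experiment pair."""
    n = len(matrix.experiments)
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            stats = hypergeom_overlap(matrix, matrix.experiments[i], matrix.experiments[j], universe)
            z[i, j] = z[j, i] = stats.z
    return SimilarityMatrix(list(matrix.experiments), z)


def cluster_experiments(sim: SimilarityMatrix, n_clusters: int) -> dict[str, int]:
    """Average-linkage agglomerative clustering on distance = max(z) - z."""
    n = len(sim.experiments)
    if not (1 <= n_clusters <= n):
        raise ConfigError(f"n_clusters must be in [1, {n}]")
    z = sim.z_values.copy()
    off = ~np.eye(n, dtype=bool)
    zmax = np.nanmax(z[off]) if n > 1 else 0.0
    dist = zmax - z
    np.fill_diagonal(dist, 0.0)
    dist[np.isnan(dist)] = zmax
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=n_clusters, criterion="maxclust")
    return {exp: int(lbl) for exp, lbl in zip(sim.experiments, labels)}


@dataclass
class CobindingNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (a, b, z) with z >= threshold
    threshold: float


def threshold_network(sim: SimilarityMatrix, z_threshold: float) -> CobindingNetwork:
    """Edges are experiment pairs whose similarity z meets the threshold."""
    edges = []
    n = len(sim.experiments)
    for i in range(n):
        for j in range(i + 1, n):
            zij = sim.z_values[i, j]
            if np.isfinite(zij) and zij >= z_threshold:
                edges.append((sim.experiments[i], sim.experiments[j], float(zij)))
    return CobindingNetwork(list(sim.experiments), edges, z_threshold)


def universe_for(
    matrix: BindingMatrix,
    genome_size: int,
    effective_genome_fraction: float = 0.25,
    slot_width: int | None = None,
) -> UniverseModel:
    return UniverseModel.from_loci(matrix.loci, genome_size, effective_genome_fraction, slot_width)
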