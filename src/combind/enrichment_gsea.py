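"""Gene-set enrichment: signal-to-noise ranking and the weighted-KS walk.

Genes are ranked by the two-group signal-to-noise ratio
s_g = (mean_A - mean_B) / (sd_A + sd_B), with each group's sd floored at
max(0.2 * |group mean|, 0.2) — the convention of the original GSEA
implementation. The enrichment score is the signed extremum of a running
sum that climbs |s_g|^p-weighted at genes in the set and falls 1/(N - N_h)
at genes outside it; with p = 0 this reduces to the classical
Kolmogorov-Smirnov statistic on hit positions. Significance comes from
sample-label permutation (re-ranking each time).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import ExpressionTable
from .errors import CombindError, ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    genes: list[str]  # ordered by stat, descending
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != self.stats.size:
            raise ConfigError("genes and stats must be parallel")
        if np.any(np.diff(self.stats) > 0):
            raise ConfigError("stats must be non-increasing")


def _snr(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, floor_min: float) -> np.ndarray:
    def moments(mask):
        sub = values[:, mask]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        return mean, np.maximum(sd, np.maximum(0.2 * np.abs(mean), floor_min))

    mean_a, sd_a = moments(mask_a)
    mean_b, sd_b = moments(mask_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def signal_to_noise(expr: ExpressionTable, floor_min: float = 0.2) -> RankedList:
    """Rank genes by (mean_A - mean_B)/(sd_A + sd_B), descending.

    Ties are broken by gene_id so the ranking is deterministic.
    """
    samples = list(expr.values.columns)
    mask_a = np.array([expr.groups[s] == "A" for s in samples])
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ConfigError("each group needs >= 2 samples")
    stats = _snr(expr.values.to_numpy(dtype=float), mask_a, mask_b, floor_min)
    genes = np.asarray(expr.values.index, dtype=object)
    order = np.lexsort((genes, -stats))
    return RankedList([str(g) for g in genes[order]], stats[order])


def _walk(stats: np.ndarray, hits: np.ndarray, weight_p: float) -> np.ndarray:
    """Running sum of the weighted-KS walk over a descending ranking."""
    n = stats.size
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise CombindError("gene set must hit some but not all ranked genes")
    steps = np.empty(n)
    weights = np.abs(stats[hits]) ** weight_p
    total = weights.sum()
    if total == 0:  # all hit stats exactly zero: fall back to equal weights
        steps[hits] = 1.0 / n_hits
    else:
        steps[hits] = weights / total
    steps[~hits] = -1.0 / (n - n_hits)
    return np.cumsum(steps)


def _extremum(running: np.ndarray) -> float:
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and the full running sum for one gene set."""
    gene_set = set(gene_set)
    hits = np.array([g in gene_set for g in ranked.genes])
    running = _walk(ranked.stats, hits, weight_p)
    return _extremum(running), running


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    es: float
    p_value: float  # add-one corrected, never exactly 0
    n_hits: int
    leading_edge: list[str]
    mode: str = "sample_label"


def _leading_edge(ranked: RankedList, hits: np.ndarray, running: np.ndarray) -> list[str]:
    i = int(np.argmax(np.abs(running)))
    if running[i] >= 0:
        take = hits & (np.arange(hits.size) <= i)
    else:
        take = hits & (np.arange(hits.size) > i)
    return [g for g, t in zip(ranked.genes, take) if t]


def permutation_p(
    expr: ExpressionTable,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "sample_label",
    weight_p: float = 1.0,
    gene_set_id: str = "set",
    floor_min: float = 0.2,
) -> EnrichmentResult:
    """Permutation p-value for a gene set's enrichment score.

    ``sample_label`` mode permutes group labels and re-ranks per draw; when
    the design is too small for label permutation (< 6 samples) it falls
    back to gene-set permutation with a logged warning.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    gene_set = set(gene_set)
    ranked = signal_to_noise(expr, floor_min)
    hits = np.array([g in gene_set for g in ranked.genes])
    running = _walk(ranked.stats, hits, weight_p)
    es_obs = _extremum(running)
    samples = list(expr.values.columns)
    values = expr.values.to_numpy(dtype=float)
    mask_a = np.array([expr.groups[s] == "A" for s in samples])
    genes = np.asarray(expr.values.index, dtype=object)
    in_set = np.array([str(g) in gene_set for g in genes])
    if mode == "sample_label" and len(samples) < 6:
        logger.warning("only %d samples: falling back to gene-set permutation", len(samples))
        mode = "gene_set"
    null = np.empty(n_perm)
    if mode == "sample_label":
        n_a = int(mask_a.sum())
        for i in range(n_perm):
            perm = rng.permutation(len(samples))
            pm_a = np.zeros(len(samples), dtype=bool)
            pm_a[perm[:n_a]] = True
            stats = _snr(values, pm_a, ~pm_a, floor_min)
            order = np.lexsort((genes, -stats))
            null[i] = _extremum(_walk(stats[order], in_set[order], weight_p))
    elif mode == "gene_set":
        n_hits = int(hits.sum())
        for i in range(n_perm):
            fake = np.zeros(hits.size, dtype=bool)
            fake[rng.choice(hits.size, size=n_hits, replace=False)] = True
            null[i] = _extremum(_walk(ranked.stats, fake, weight_p))
    else:
        raise ConfigError(f"unknown permutation mode {mode!r}")
    p = float((1 + (np.abs(null) >= abs(es_obs)).sum()) / (n_perm + 1))
    return EnrichmentResult(
        gene_set_id, es_obs, p, int(hits.sum()), _leading_edge(ranked, hits, running), mode
    )


def read_gene_sets(path) -> dict[str, set[str]]:
    """GMT-style lines: set_id <TAB> description <TAB> gene ids..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            sets[cols[0]] = set(cols[2:])
    return sets
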