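"""Locus annotation: promoter proximity, region-set enrichment, metaprofiles.

Proximity is measured from the locus midpoint to the nearest TSS; loci more
than the cutoff (default 1000 bp) away are "distal". Signal metaprofiles
average a bedGraph track in fixed-width bins around the locus midpoint —
the H3K27ac-around-bound-loci picture.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colocalization_stats import randomize_positions
from .core import GeneAnnotation, Locus, PeakSet, SignalTrack, _empty_peak_frame
from .errors import CombindError, ConfigError
from .intervals import merge, overlaps_any


def classify_proximity(
    loci: Sequence[Locus], genes: GeneAnnotation, cutoff: int = 1000
) -> pd.DataFrame:
    """Nearest TSS per locus and the proximal/distal split.

    distance is signed (TSS minus locus midpoint); proximal iff
    |distance| <= cutoff, so "more than cutoff away" is distal. Ties on
    |distance| go to the lower-coordinate TSS. Loci on chromosomes without
    any annotated gene get distance +inf, class distal, and flagged=True.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.df.groupby("chrom", sort=False):
        by_chrom[chrom] = (sub["tss"].to_numpy(dtype=np.int64), sub["gene_id"].to_numpy())
    rows = []
    for locus in loci:
        mid = locus.interval.midpoint
        chrom = locus.interval.chrom
        if chrom not in by_chrom:
            rows.append((locus.locus_id, None, float("inf"), "distal", True))
            continue
        tss, ids = by_chrom[chrom]
        j = int(np.searchsorted(tss, mid))
        # candidates straddling the midpoint; lower coordinate wins ties
        best_i, best_d = None, None
        for i in (j - 1, j):
            if 0 <= i < tss.size:
                d = abs(int(tss[i]) - mid)
                if best_d is None or d < best_d:
                    best_i, best_d = i, d
        dist = int(tss[best_i]) - mid
        klass = "proximal" if abs(dist) <= cutoff else "distal"
        rows.append((locus.locus_id, str(ids[best_i]), dist, klass, False))
    return pd.DataFrame(
        rows, columns=["locus_id", "nearest_gene", "distance", "klass", "flagged"]
    )


def region_overlap_enrichment(
    loci: Sequence[Locus],
    regions: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    n_iter: int = 500,
    effective_genome: int | None = None,
    seed: int = 0,
) -> tuple[float, float | None, float]:
    """Fraction of loci overlapping a region set, with a randomization z.

    The null re-places the loci (lengths preserved) uniformly within the
    effective genome and recounts overlaps. Returns (fraction, z, p); z is
    None when the null count never varies.
    """
    if regions.empty:
        raise ConfigError("region set is empty")
    if not loci:
        raise ConfigError("no loci given")
    merged = {
        chrom: merge(sub["start"].to_numpy(), sub["end"].to_numpy())[:2]
        for chrom, sub in regions.groupby("chrom", sort=False)
    }

    def count(ps: PeakSet) -> int:
        total = 0
        for chrom, s, e in ps.by_chrom():
            if chrom in merged:
                ms, me = merged[chrom]
                total += int(overlaps_any(s, e, ms, me).sum())
        return total

    ps = _loci_as_peakset(loci, chrom_sizes)
    observed = count(ps)
    fraction = observed / len(loci)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = count(randomize_positions(ps, effective_genome, rng))
    sd = null.std(ddof=1)
    z = float((observed - null.mean()) / sd) if sd > 0 else None
    p_up = (1 + (null >= observed).sum()) / (n_iter + 1)
    p_lo = (1 + (null <= observed).sum()) / (n_iter + 1)
    return fraction, z, float(min(1.0, 2 * min(p_up, p_lo)))


def _loci_as_peakset(loci: Sequence[Locus], chrom_sizes: Mapping[str, int]) -> PeakSet:
    df = _empty_peak_frame()
    if loci:
        df = pd.DataFrame(
            {
                "chrom": [l.interval.chrom for l in loci],
                "start": np.array([l.interval.start for l in loci], dtype=np.int64),
                "end": np.array([l.interval.end for l in loci], dtype=np.int64),
                "score": 0.0,
                "summit": None,
            }
        )
    return PeakSet(df, "loci", "loci", "genome", chrom_sizes)


@dataclass(frozen=True)
class Profile:
    window: int  # half-width W in bases
    n_bins: int
    values: np.ndarray  # per-bin mean signal over loci
    n_loci: int


def signal_profile(
    loci: Sequence[Locus],
    track: SignalTrack,
    window: int = 3000,
    n_bins: int = 60,
    anchor: str = "midpoint",
    chrom_sizes: Mapping[str, int] | None = None,
) -> Profile:
    """Average signal in ``n_bins`` bins across [anchor-W, anchor+W) per locus.

    Each locus contributes its per-bin mean track value; the profile is the
    mean over loci. Windows running off a chromosome end are clipped and the
    affected bins' denominators adjusted (a bin with no covered bases for a
    locus simply drops that locus).
    """
    if not loci:
        raise CombindError("signal_profile needs at least one locus")
    if (2 * window) % n_bins != 0:
        raise ConfigError(f"n_bins={n_bins} must divide 2*window={2 * window} evenly")
    bin_width = 2 * window // n_bins
    if anchor not in ("midpoint", "start"):
        raise ConfigError(f"unknown anchor {anchor!r}")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for locus in loci:
        iv = locus.interval
        a = iv.midpoint if anchor == "midpoint" else iv.start
        chrom_end = None if chrom_sizes is None else chrom_sizes.get(iv.chrom)
        for b in range(n_bins):
            b_start = a - window + b * bin_width
            b_end = b_start + bin_width
            c_start = max(b_start, 0)
            c_end = b_end if chrom_end is None else min(b_end, chrom_end)
            if c_end <= c_start:
                continue
            sums[b] += track.segment_sum(iv.chrom, c_start, c_end) / (c_end - c_start)
            counts[b] += 1
    values = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return Profile(window, n_bins, values, len(loci))
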