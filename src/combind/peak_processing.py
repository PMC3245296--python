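"""Peak-list filters: significance cutoff, control cleaning, stringent subset.

The cleaning step removes every treatment peak that shares at least one base
with a control (treatment-unspecific) peak — whole peaks are discarded, never
trimmed. The stringent subset keeps the top fraction of peaks ranked by
significance, the specificity control for the p-value cutoff.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PeakSet
from .errors import ConfigError, ConsistencyError
from .intervals import merge, overlaps_any


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_removed_pvalue: int = 0
    n_removed_control: int = 0

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_pvalue - self.n_removed_control


def filter_by_significance(peaks: PeakSet, max_p: float) -> tuple[PeakSet, FilterReport]:
    """Keep peaks with p <= max_p, i.e. score >= -log10(max_p) (inclusive)."""
    if not (0 < max_p <= 1):
        raise ConfigError(f"max_p must be in (0, 1], got {max_p}")
    threshold = -math.log10(max_p)
    keep = peaks.df["score"].to_numpy() >= threshold
    out = peaks.replace(peaks.df[keep])
    return out, FilterReport(len(peaks), n_removed_pvalue=int((~keep).sum()))


def clean_against_control(
    peaks: PeakSet, control_peaks: PeakSet
) -> tuple[PeakSet, FilterReport]:
    """Discard every treatment peak sharing >=1 base with any control peak."""
    if peaks.genome_id != control_peaks.genome_id:
        raise ConsistencyError(
            f"genome mismatch: {peaks.genome_id!r} vs {control_peaks.genome_id!r}"
        )
    keep = np.ones(len(peaks), dtype=bool)
    control_by_chrom = {c: (s, e) for c, s, e in control_peaks.by_chrom()}
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        if chrom not in control_by_chrom:
            continue
        cs, ce = control_by_chrom[chrom]
        ms, me, _ = merge(cs, ce)  # control peaks may overlap each other
        hit = overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), ms, me)
        keep[sub.index.to_numpy()] = ~hit
    out = peaks.replace(peaks.df[keep])
    return out, FilterReport(len(peaks), n_removed_control=int((~keep).sum()))


def stringent_subset(peaks: PeakSet, fraction: float) -> PeakSet:
    """The ceil(fraction * n) highest-scoring peaks, re-sorted genomically.

    Ties at the score boundary go to the earlier (chrom, start) peak, so the
    result is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    n = len(peaks)
    if n == 0:
        return peaks.replace(peaks.df)
    m = math.ceil(fraction * n)
    # df is genomically sorted; stable sort on -score keeps genomic order for ties
    order = np.argsort(-peaks.df["score"].to_numpy(), kind="mergesort")[:m]
    return peaks.replace(peaks.df.iloc[np.sort(order)])
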