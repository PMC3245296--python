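"""Domain types: genomic intervals, peaks, loci, the binding matrix, tracks.

Coordinate convention is 0-based half-open (BED) throughout; 1-based inputs
must be converted explicitly at the reader (no auto-detection). Peak scores
are -log10 of the peak-caller p-value, so "sorted by p-value" ascending is
descending score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise FormatError(f"invalid chromosome name {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end; empty intervals are rejected)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base; book-ended intervals do not overlap."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    experiment_id: str
    factor: str
    score: float = 0.0  # -log10(p)
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise FormatError(f"peak score must be >= 0, got {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise FormatError(
                f"summit offset {self.summit_offset} outside [0, {self.interval.length})"
            )


class PeakSet:
    """All peaks of one ChIP-seq experiment, sorted by (chrom, start).

    Backed by a DataFrame with columns chrom/start/end/score/summit for
    vectorised interval work; `peaks` iterates typed :class:`Peak` records.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        experiment_id: str,
        factor: str,
        genome_id: str,
        chrom_sizes: Mapping[str, int],
    ) -> None:
        required = {"chrom", "start", "end", "score", "summit"}
        if not required.issubset(df.columns):
            raise ConsistencyError(f"PeakSet frame missing columns {required - set(df.columns)}")
        df = df.reset_index(drop=True)
        if len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(f"peak {i}: need 0 <= start < end")
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in chrom_sizes:
                    raise FormatError(f"unknown chromosome {chrom!r}")
                if (sub["end"] > chrom_sizes[chrom]).any():
                    raise FormatError(f"peak beyond end of {chrom} ({chrom_sizes[chrom]} bp)")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.experiment_id = experiment_id
        self.factor = factor
        self.genome_id = genome_id
        self.chrom_sizes = dict(chrom_sizes)

    @classmethod
    def from_peaks(
        cls,
        peaks: Sequence[Peak],
        genome_id: str,
        chrom_sizes: Mapping[str, int],
        experiment_id: str | None = None,
        factor: str | None = None,
    ) -> "PeakSet":
        if peaks:
            experiment_id = experiment_id or peaks[0].experiment_id
            factor = factor or peaks[0].factor
        df = pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in peaks],
                "start": np.array([p.interval.start for p in peaks], dtype=np.int64),
                "end": np.array([p.interval.end for p in peaks], dtype=np.int64),
                "score": np.array([p.score for p in peaks], dtype=float),
                "summit": [p.summit_offset for p in peaks],
            }
        )
        if not peaks:
            df = _empty_peak_frame()
        return cls(df, experiment_id or "", factor or "", genome_id, chrom_sizes)

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def peaks(self) -> Iterator[Peak]:
        for row in self.df.itertuples(index=False):
            yield Peak(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                self.experiment_id,
                self.factor,
                float(row.score),
                None if row.summit is None or (isinstance(row.summit, float) and np.isnan(row.summit)) else int(row.summit),
            )

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def replace(self, df: pd.DataFrame) -> "PeakSet":
        return PeakSet(df, self.experiment_id, self.factor, self.genome_id, self.chrom_sizes)

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub["start"].to_numpy(), sub["end"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


def _empty_peak_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "score": pd.Series(dtype=float),
            "summit": pd.Series(dtype=object),
        }
    )


@dataclass(frozen=True)
class Locus:
    """A merged regulatory site spanning all transitively overlapping peaks."""

    interval: GenomicInterval
    locus_id: str
    source_peak_count: int = 1

    @classmethod
    def from_span(cls, chrom: str, start: int, end: int, n_peaks: int = 1) -> "Locus":
        return cls(GenomicInterval(chrom, start, end), f"{chrom}:{start}-{end}", n_peaks)


class BindingMatrix:
    """Loci x experiments binary occupancy table — the central object.

    entry(l, e) = 1 iff locus l shares >=1 base with >=1 peak of experiment e;
    every locus carries at least one 1 when built from its own peak sets.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        experiments: Sequence[str],
        factors: Sequence[str],
        entries: np.ndarray,
    ) -> None:
        entries = np.asarray(entries, dtype=bool)
        if entries.shape != (len(loci), len(experiments)):
            raise ConsistencyError(
                f"entries shape {entries.shape} != ({len(loci)}, {len(experiments)})"
            )
        if len(experiments) != len(factors):
            raise ConsistencyError("experiments and factors must be parallel")
        if len(set(experiments)) != len(experiments):
            raise ConsistencyError("duplicate experiment ids")
        self.loci = list(loci)
        self.experiments = list(experiments)
        self.factors = list(factors)
        self.entries = entries

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def column(self, experiment_id: str) -> np.ndarray:
        return self.entries[:, self.experiments.index(experiment_id)]

    def columns_for(self, label: str) -> list[int]:
        """Indices for an experiment id, else all experiments of a factor."""
        if label in self.experiments:
            return [self.experiments.index(label)]
        idx = [i for i, f in enumerate(self.factors) if f == label]
        return idx

    def row_sums(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [l.interval.chrom for l in self.loci],
                "start": np.array([l.interval.start for l in self.loci], dtype=np.int64),
                "end": np.array([l.interval.end for l in self.loci], dtype=np.int64),
            }
        )
        for j, exp in enumerate(self.experiments):
            df[exp] = self.entries[:, j].astype(np.int8)
        return df


class SignalTrack:
    """Sparse step function per chromosome: disjoint sorted (start, end, value)
    runs, zero elsewhere (bedGraph semantics)."""

    def __init__(self, genome_id: str, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.genome_id = genome_id
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="mergesort")
            s, e, v = s[order], e[order], v[order]
            if s.size and (s[1:] < e[:-1]).any():
                raise FormatError(f"overlapping signal spans on {chrom}")
            if s.size and (s >= e).any():
                raise FormatError(f"empty signal span on {chrom}")
            self.runs[chrom] = (s, e, v)

    def segment_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of the track over [start, end) (value x covered bases)."""
        if chrom not in self.runs or end <= start:
            return 0.0
        s, e, v = self.runs[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float((ov * v[lo:hi]).sum())

    def mean_value(self, chrom: str, start: int, end: int) -> float:
        """Mean value over [start, end), counting uncovered bases as 0."""
        if end <= start:
            return 0.0
        return self.segment_sum(chrom, start, end) / (end - start)


@dataclass
class GeneAnnotation:
    """TSS positions: one record per gene, ids unique."""

    df: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        if self.df["gene_id"].duplicated().any():
            raise FormatError("duplicate gene_id in annotation")
        self.df = self.df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ExpressionTable:
    """Genes x samples non-negative expression with a two-group design."""

    values: pd.DataFrame  # index gene_id, columns sample_id
    groups: dict[str, str] = field(default_factory=dict)  # sample_id -> "A" | "B"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ConsistencyError(f"samples without group assignment: {sorted(missing)}")
        for g in ("A", "B"):
            if sum(1 for s in self.values.columns if self.groups[s] == g) < 2:
                raise ConsistencyError(f"group {g} needs >= 2 samples for signal-to-noise")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]
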