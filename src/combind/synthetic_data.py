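"""Synthetic multi-factor ChIP-seq data with planted, recoverable structure.

The generator emulates the statistical skeleton of a two-species
combinatorial-binding study: "hotspot" regulatory loci receive a factor
subset drawn from a joint occupancy model; target factors (Mediator-like
co-activators and a CTCF-like control) bind conditionally on the
combination class; each hotspot conserves to a simulated orthologous genome
with a combination-dependent probability (boosted at developmental-enhancer
hotspots); decoy peaks, signal bumps, a TSS annotation straddling the
proximal/distal cutoff, and a two-group expression table with planted
shifts complete the bundle. Everything is deterministic given the seed and
every emitted record traces to a hotspot or a noise draw.
"""
from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import OrthologyMap, map_locus, write_map
from .core import (
    ExpressionTable,
    GeneAnnotation,
    Locus,
    PeakSet,
    SignalTrack,
    _empty_peak_frame,
)
from .errors import ConfigError
from .genomic_io import (
    write_chrom_sizes,
    write_expression,
    write_peaks,
    write_regions,
    write_signal,
)

CLASS_NAMES = ("none", "single", "pair", "triple")


def _default_joint_model() -> dict[tuple[str, ...], float]:
    f = ("OCT4", "SOX2", "NANOG")
    model: dict[tuple[str, ...], float] = {(): 0.18}
    for x in f:
        model[(x,)] = 0.12
    for i in range(3):
        for j in range(i + 1, 3):
            model[tuple(sorted((f[i], f[j])))] = 0.07
    model[f] = 0.25
    return model


def _default_cooccupancy() -> dict[str, dict[str, float]]:
    return {
        # Mediator-like: strongly combination-dependent
        "MED1": {"none": 0.02, "single": 0.12, "pair": 0.25, "triple": 0.45},
        "MED12": {"none": 0.02, "single": 0.15, "pair": 0.30, "triple": 0.60},
        # insulator-like control: mildly depleted at combinatorial loci
        "CTCF": {"none": 0.10, "single": 0.08, "pair": 0.05, "triple": 0.03},
    }


def _default_conservation() -> dict[str, float]:
    return {
        "none": 0.02,
        "single": 0.05,
        "pair": 0.10,
        "triple": 0.15,
        "triple_enhancer": 0.55,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_size: int = 10_000_000
    n_chroms: int = 4
    n_hotspots: int = 500
    hotspot_width_mean: float = 400.0
    hotspot_width_sd: float = 80.0
    factors: tuple[str, ...] = ("OCT4", "SOX2", "NANOG")
    joint_model: dict[tuple[str, ...], float] = field(default_factory=_default_joint_model)
    n_noise_peaks: int = 40
    # per-experiment decoy overrides: the insulator analog binds abundantly
    # genome-wide at its own sites, which is what makes its depletion at
    # combinatorially bound loci detectable
    target_noise_peaks: dict[str, int] = field(default_factory=lambda: {"CTCF": 1200})
    n_control_peaks: int = 25
    target_cooccupancy: dict[str, dict[str, float]] = field(default_factory=_default_cooccupancy)
    conservation_rates: dict[str, float] = field(default_factory=_default_conservation)
    enhancer_fraction: float = 0.10
    unmappable_fraction: float = 0.10
    tss_fraction: float = 0.5
    n_genes: int = 400
    n_samples_per_group: int = 4
    expression_effect: float = 2.0
    signal_amplitude: float = 5.0
    min_hotspot_gap: int = 2000

    def validate(self) -> None:
        total = sum(self.joint_model.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"joint_model probabilities sum to {total}, not 1")
        for probs in ([self.enhancer_fraction, self.unmappable_fraction, self.tss_fraction]
                      + list(self.conservation_rates.values())):
            if not (0 <= probs <= 1):
                raise ConfigError(f"probability {probs} outside [0, 1]")
        for target, by_class in self.target_cooccupancy.items():
            for klass, p in by_class.items():
                if not (0 <= p <= 1):
                    raise ConfigError(f"{target}/{klass} probability {p} outside [0, 1]")
        footprint = self.n_hotspots * (self.hotspot_width_mean + self.min_hotspot_gap)
        if footprint > 0.8 * self.genome_size:
            raise ConfigError(
                f"infeasible config: {self.n_hotspots} hotspots x "
                f"~{self.hotspot_width_mean + self.min_hotspot_gap:.0f} bp exceed the genome"
            )


@dataclass
class GroundTruth:
    """Per-hotspot planted state plus the block map used."""

    hotspots: pd.DataFrame  # chrom/start/end/subset/klass/enhancer/mappable/conserved/<targets>/gene columns
    omap: OrthologyMap
    chrom_sizes_src: dict[str, int]
    chrom_sizes_tgt: dict[str, int]

    def realized_rate(self, mask: pd.Series, flag: str) -> float:
        sub = self.hotspots[mask]
        return float(sub[flag].mean()) if len(sub) else float("nan")


@dataclass
class SimBundle:
    config: SimulationConfig
    truth: GroundTruth
    source_peaks: dict[str, PeakSet]  # factor + target experiments, source genome
    target_peaks: dict[str, PeakSet]  # factor experiments, target genome
    control_peaks: PeakSet  # treatment-unspecific peaks for the cleaning step
    signal: SignalTrack
    tss: GeneAnnotation
    enhancers: pd.DataFrame
    expression: ExpressionTable
    active_gene_set: set[str]  # genes near Mediator-bound triple hotspots
    poised_gene_set: set[str]  # genes near triple hotspots without Mediator

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.truth.chrom_sizes_src, out / "source.chrom.sizes")
        write_chrom_sizes(self.truth.chrom_sizes_tgt, out / "target.chrom.sizes")
        for name, ps in self.source_peaks.items():
            write_peaks(ps, out / f"source_{name}.bed")
        for name, ps in self.target_peaks.items():
            write_peaks(ps, out / f"target_{name}.bed")
        write_peaks(self.control_peaks, out / "source_control.bed")
        write_signal(self.signal, out / "h3k27ac.bedgraph")
        with open(out / "tss.bed", "w") as fh:
            for row in self.tss.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.tss}\t{row.tss + 1}\t{row.gene_id}\t0\t{row.strand}\n")
        write_regions(self.enhancers, out / "enhancers.bed")
        write_expression(self.expression, out / "expression.tsv", out / "groups.tsv")
        write_map(self.truth.omap, out / "orthology_map.tsv")
        truth = self.truth.hotspots.copy()
        truth["subset"] = truth["subset"].map(lambda t: "+".join(t))
        payload = {
            "hotspots": truth.to_dict(orient="records"),
            "active_gene_set": sorted(self.active_gene_set),
            "poised_gene_set": sorted(self.poised_gene_set),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)


def planted_value(bundle: SimBundle, key: str) -> float:
    """Realized planted value for a recovery key.

    Keys: ``cooccupancy/<TARGET>/<class>`` (P(target | combination class)),
    ``conservation/<class>`` (conserved fraction among mappable hotspots of
    the class; class may be ``triple_enhancer``), ``proximal_fraction``
    (share of planted genes within 1000 bp), ``es_sign/active`` and
    ``es_sign/poised`` (expected enrichment-score sign).
    """
    hs = bundle.truth.hotspots
    parts = key.split("/")
    if parts[0] == "cooccupancy":
        target, klass = parts[1], parts[2]
        sub = hs[hs["klass"] == klass]
        return float(sub[target].mean()) if len(sub) else float("nan")
    if parts[0] == "conservation":
        klass = parts[1]
        if klass == "triple_enhancer":
            mask = (hs["klass"] == "triple") & hs["enhancer"]
        elif klass == "triple_not_enhancer":
            mask = (hs["klass"] == "triple") & ~hs["enhancer"]
        else:
            mask = hs["klass"] == klass
        sub = hs[mask & hs["mappable"]]
        return float(sub["conserved"].mean()) if len(sub) else float("nan")
    if key == "es_sign/active":
        return 1.0
    if key == "es_sign/poised":
        return -1.0
    raise ConfigError(f"unknown recovery key {key!r}")


def truth_report(bundle: SimBundle, estimates: Mapping[str, tuple[float, int]]) -> pd.DataFrame:
    """Compare pipeline estimates against the planted (realized) values.

    ``estimates`` maps recovery keys (see :func:`planted_value`) to
    (estimate, n) pairs; the tolerance is 3 binomial standard errors at the
    planted rate, or a plain sign match for ``es_sign`` keys.
    """
    rows = []
    for key, (est, n_obs) in estimates.items():
        planted = planted_value(bundle, key)
        if key.startswith("es_sign"):
            ok = bool(np.sign(est) == np.sign(planted))
            rows.append((key, planted, est, abs(est - planted), float("nan"), ok))
            continue
        se = float(np.sqrt(max(planted * (1 - planted), 1e-12) / max(n_obs, 1)))
        err = abs(est - planted)
        rows.append((key, planted, est, err, 3 * se, bool(err <= 3 * se)))
    return pd.DataFrame(
        rows, columns=["key", "planted", "estimate", "abs_error", "tolerance", "pass"]
    )


def _place_hotspots(cfg: SimulationConfig, rng: np.random.Generator,
                    chroms: list[str], chrom_size: int) -> pd.DataFrame:
    """Uniform non-overlapping placement with a minimum gap (rejection sampled)."""
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    margin = 4000  # keep profile windows and planted TSSs inside the chromosome
    while len(rows) < cfg.n_hotspots:
        attempts += 1
        if attempts > 10_000 + 100 * cfg.n_hotspots:
            raise ConfigError("hotspot placement failed: genome too crowded")
        w = max(100, int(rng.normal(cfg.hotspot_width_mean, cfg.hotspot_width_sd)))
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(margin, chrom_size - margin - w))
        lo, hi = start - cfg.min_hotspot_gap, start + w + cfg.min_hotspot_gap
        spans = placed[chrom]
        i = bisect.bisect_left(spans, (lo, lo))
        ok = True
        for j in (i - 1, i):
            if 0 <= j < len(spans) and spans[j][0] < hi and lo < spans[j][1]:
                ok = False
        if not ok:
            continue
        spans.insert(i, (start, start + w))
        rows.append((chrom, start, start + w))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _jittered_peak(rng: np.random.Generator, start: int, end: int, chrom_size: int) -> tuple[int, int]:
    """Shift/resize a hotspot peak while keeping >= 50% overlap with it."""
    w = end - start
    max_shift = max(1, w // 2 - 1)
    shift = int(np.clip(rng.normal(0, w / 10), -max_shift, max_shift))
    w2 = max(100, int(w + rng.normal(0, w / 10)))
    s = max(0, min(start + shift, chrom_size - w2))
    return s, s + w2


def _peakset(rows: list, name: str, factor: str, genome_id: str,
             chrom_sizes: Mapping[str, int]) -> PeakSet:
    if not rows:
        return PeakSet(_empty_peak_frame(), name, factor, genome_id, chrom_sizes)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    df["summit"] = None
    return PeakSet(df, name, factor, genome_id, chrom_sizes)


def simulate(config: SimulationConfig | None = None) -> SimBundle:
    """Draw one full synthetic study bundle; deterministic given config.seed."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_size = cfg.genome_size // cfg.n_chroms
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: chrom_size for c in chroms}

    hotspots = _place_hotspots(cfg, rng, chroms, chrom_size)
    n = len(hotspots)

    # factor subset per hotspot from the joint model
    subsets = list(cfg.joint_model)
    probs = np.array([cfg.joint_model[s] for s in subsets])
    drawn = rng.choice(len(subsets), size=n, p=probs)
    hotspots["subset"] = [tuple(sorted(subsets[i])) for i in drawn]
    hotspots["klass"] = [CLASS_NAMES[len(s)] for s in hotspots["subset"]]
    hotspots["enhancer"] = rng.random(n) < cfg.enhancer_fraction

    # target occupancy conditional on the combination class
    for target, by_class in cfg.target_cooccupancy.items():
        p = hotspots["klass"].map(by_class).to_numpy(dtype=float)
        hotspots[target] = rng.random(n) < p

    # orthology map: delete a window around unmappable hotspots
    hotspots["mappable"] = ~(rng.random(n) < cfg.unmappable_fraction)
    omap, chrom_sizes_tgt = _build_map(hotspots, chroms, chrom_sizes)

    # conservation conditional on class (enhancer boosts the triple class)
    rate = hotspots["klass"].map(cfg.conservation_rates).to_numpy(dtype=float)
    boost = (hotspots["klass"] == "triple") & hotspots["enhancer"]
    rate[boost.to_numpy()] = cfg.conservation_rates["triple_enhancer"]
    hotspots["conserved"] = (rng.random(n) < rate) & hotspots["mappable"]

    # source-genome peaks: hotspot peaks + uniform decoys per experiment
    source_peaks: dict[str, PeakSet] = {}
    all_names = list(cfg.factors) + list(cfg.target_cooccupancy)
    for name in all_names:
        rows = []
        for h in hotspots.itertuples(index=False):
            bound = name in h.subset if name in cfg.factors else getattr(h, name)
            if bound:
                s, e = _jittered_peak(rng, h.start, h.end, chrom_size)
                rows.append((h.chrom, s, e, float(rng.uniform(5, 50))))
        n_decoys = cfg.target_noise_peaks.get(name, cfg.n_noise_peaks)
        rows += _noise_peaks(cfg, rng, hotspots, chroms, chrom_size, n_decoys)
        source_peaks[name] = _peakset(rows, name, name, "source", chrom_sizes)

    # target-genome peaks at conserved hotspots (same factor subset, remapped)
    target_rows: dict[str, list] = {name: [] for name in cfg.factors}
    for h in hotspots.itertuples(index=False):
        if not h.conserved:
            continue
        mapped = map_locus(Locus.from_span(h.chrom, h.start, h.end), omap, minmatch=0.1)
        if mapped.status != "mapped":
            continue
        for name in h.subset:
            s, e = _jittered_peak(
                rng, mapped.target.start, mapped.target.end, chrom_sizes_tgt[mapped.target.chrom]
            )
            target_rows[name].append((mapped.target.chrom, s, e, float(rng.uniform(5, 50))))
    target_peaks = {
        name: _peakset(rows, name, name, "target", chrom_sizes_tgt)
        for name, rows in target_rows.items()
    }

    # treatment-unspecific control peaks, kept clear of hotspots so cleaning
    # removes only decoys
    control_peaks = _peakset(
        _noise_peaks(cfg, rng, hotspots, chroms, chrom_size, cfg.n_control_peaks),
        "control", "control", "source", chrom_sizes,
    )

    signal = _signal_track(cfg, hotspots)
    tss, expression, active_set, poised_set = _genes_and_expression(cfg, rng, hotspots, chrom_size)
    enh = hotspots[hotspots["enhancer"]]
    enhancers = pd.DataFrame(
        {"chrom": enh["chrom"], "start": enh["start"] - 200, "end": enh["end"] + 200}
    ).reset_index(drop=True)

    truth = GroundTruth(hotspots, omap, dict(chrom_sizes), dict(chrom_sizes_tgt))
    return SimBundle(
        cfg, truth, source_peaks, target_peaks, control_peaks, signal, tss,
        enhancers, expression, active_set, poised_set,
    )


def _noise_peaks(cfg, rng, hotspots, chroms, chrom_size, count: int | None = None) -> list:
    """Uniform decoy peaks kept clear of every hotspot."""
    spans = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
             for c, sub in hotspots.groupby("chrom", sort=False)}
    rows = []
    for _ in range(cfg.n_noise_peaks if count is None else count):
        for _attempt in range(1000):
            w = max(100, int(rng.normal(cfg.hotspot_width_mean, cfg.hotspot_width_sd)))
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_size - w))
            s_arr, e_arr = spans.get(chrom, (np.zeros(0), np.zeros(0)))
            if not ((s_arr < start + w) & (start < e_arr)).any():
                rows.append((chrom, start, start + w, float(rng.uniform(5, 20))))
                break
    return rows


def _build_map(hotspots, chroms, chrom_sizes) -> tuple[OrthologyMap, dict[str, int]]:
    """Deletion-only block map: unmappable hotspots sit in alignment gaps."""
    rows = []
    chrom_sizes_tgt = {}
    gaps_by_chrom = {
        c: sorted(
            (max(0, h.start - 500), min(chrom_sizes[c], h.end + 500))
            for h in hotspots[(hotspots["chrom"] == c) & ~hotspots["mappable"]].itertuples()
        )
        for c in chroms
    }
    for chrom in chroms:
        size = chrom_sizes[chrom]
        pos, offset = 0, 0
        for g_start, g_end in gaps_by_chrom[chrom]:
            if g_start > pos:
                rows.append((chrom, pos, g_start, chrom, pos - offset, g_start - offset, "+"))
            offset += g_end - max(pos, g_start)
            pos = max(pos, g_end)
        if pos < size:
            rows.append((chrom, pos, size, chrom, pos - offset, size - offset, "+"))
        chrom_sizes_tgt[chrom] = size - offset
    omap = OrthologyMap(pd.DataFrame(rows, columns=[
        "src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end", "strand"
    ]))
    return omap, chrom_sizes_tgt


def _signal_track(cfg, hotspots) -> SignalTrack:
    """Gaussian signal bumps (50-bp steps) at Mediator-bound hotspots."""
    targets = [t for t in cfg.target_cooccupancy if t.startswith("MED")]
    step = 50
    bins: dict[str, dict[int, float]] = {}
    for h in hotspots.itertuples(index=False):
        if not any(getattr(h, t) for t in targets):
            continue
        center = (h.start + h.end) // 2
        sigma = max(200.0, (h.end - h.start) / 2)
        half = int(3 * sigma)
        chrom_bins = bins.setdefault(h.chrom, {})
        for b in range((center - half) // step, (center + half) // step + 1):
            if b < 0:
                continue
            x = b * step + step / 2 - center
            chrom_bins[b] = chrom_bins.get(b, 0.0) + cfg.signal_amplitude * float(
                np.exp(-x * x / (2 * sigma * sigma))
            )
    runs = {}
    for chrom, chrom_bins in bins.items():
        keys = sorted(chrom_bins)
        s = np.array([k * step for k in keys], dtype=np.int64)
        runs[chrom] = (s, s + step, np.array([chrom_bins[k] for k in keys]))
    return SignalTrack("source", runs)


def _genes_and_expression(cfg, rng, hotspots, chrom_size):
    """Planted TSSs straddling the proximal cutoff + a two-group expression table.

    Genes near Mediator-bound triple hotspots are shifted up in group A
    (stem-like); genes near triple hotspots without Mediator are shifted up
    in group B (differentiated-like) — the active/poised contrast.
    """
    med_targets = [t for t in cfg.target_cooccupancy if t.startswith("MED")]
    gene_rows, planted = [], {}
    g = 0
    for i, h in enumerate(hotspots.itertuples(index=False)):
        if rng.random() >= cfg.tss_fraction:
            continue
        proximal = rng.random() < 0.5
        dist = int(rng.integers(100, 901)) if proximal else int(rng.integers(2000, 20001))
        sign = 1 if rng.random() < 0.5 else -1
        tss = int(np.clip((h.start + h.end) // 2 + sign * dist, 0, chrom_size - 1))
        gene_id = f"g{g:04d}"
        g += 1
        gene_rows.append((gene_id, h.chrom, tss, "+"))
        planted[i] = gene_id
    while g < cfg.n_genes:
        gene_id = f"b{g:04d}"
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        gene_rows.append((gene_id, chrom, int(rng.integers(0, chrom_size)), "+"))
        g += 1
    tss = GeneAnnotation(pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"]))

    active_set, poised_set = set(), set()
    for i, gene_id in planted.items():
        h = hotspots.iloc[i]
        if h["klass"] != "triple":
            continue
        if any(h[t] for t in med_targets):
            active_set.add(gene_id)
        else:
            poised_set.add(gene_id)

    n_per = cfg.n_samples_per_group
    samples = [f"ES_{i}" for i in range(n_per)] + [f"diff_{i}" for i in range(n_per)]
    groups = {s: ("A" if s.startswith("ES") else "B") for s in samples}
    gene_ids = [r[0] for r in gene_rows]
    base = rng.normal(8.0, 1.0, size=(len(gene_ids), 2 * n_per))
    for gi, gene_id in enumerate(gene_ids):
        if gene_id in active_set:
            base[gi, :n_per] += cfg.expression_effect
        elif gene_id in poised_set:
            base[gi, n_per:] += cfg.expression_effect
    values = pd.DataFrame(np.clip(base, 0, None), index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    return tss, ExpressionTable(values, groups), active_set, poised_set
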