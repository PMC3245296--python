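"""End-to-end orchestration: simulate → clean → integrate → coloc → combos →
conserve → annotate → gsea.

One global seed fans out to per-stage seeds through a fixed stage-name hash,
so each stage is reproducible on its own. Each stage records SHA-256
checksums of its outputs in the run manifest and verifies the checksums of
the inputs it consumes; a failing stage renames its outputs to ``.partial``
and aborts the run with the stage named.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, colocalization_stats as coloc, enrichment_gsea as gsea
from .combinations import CombinationQuery, combination_profile_table, select_loci
from .conservation import conservation_by_combination, conserved_combination_matrix
from .core import BindingMatrix
from .errors import CombindError, ConfigError
from .genomic_io import write_loci
from .locus_integration import build_matrix, integrate_loci
from .peak_processing import clean_against_control, filter_by_significance
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "integrate", "coloc", "combos", "conserve", "annotate", "gsea")

_DEFAULTS: dict[str, object] = {
    "out_dir": "combind_run",
    "seed": 0,
    "effective_genome_fraction": 0.25,
    "mc_iters": 200,
    "minmatch": 0.1,
    "proximal_cutoff": 1000,
    "stringent_fraction": 0.1,
    "max_p": 1e-5,
    "z_threshold": 5.0,
    "n_perm": 200,
    "n_hotspots": 500,
    "genome_size": 10_000_000,
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    out_dir: str = "combind_run"
    seed: int = 0
    effective_genome_fraction: float = 0.25
    mc_iters: int = 200
    minmatch: float = 0.1
    proximal_cutoff: int = 1000
    stringent_fraction: float = 0.1
    max_p: float = 1e-5
    z_threshold: float = 5.0
    n_perm: int = 200
    n_hotspots: int = 500
    genome_size: int = 10_000_000
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` text config; unknown keys are errors."""
        values = dict(_DEFAULTS)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in values:
                    raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
                default = _DEFAULTS[key]
                if isinstance(default, bool):
                    values[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(value)
                elif isinstance(default, float):
                    values[key] = float(value)
                else:
                    values[key] = value
        return cls(**values)  # type: ignore[arg-type]


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed fan-out: independent of stage execution order, < 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(CombindError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": config.__dict__.copy(), "stages": []}
        self.checksums: dict[str, str] = {}
        self.state: dict = {}

    def record(self, stage: str, seed: int, t0: float, outputs: list[Path]) -> None:
        sums = {str(p.relative_to(self.out)): _sha256(p) for p in outputs}
        self.checksums.update({str(p): _sha256(p) for p in outputs})
        self.manifest["stages"].append(
            {
                "name": stage,
                "seed": seed,
                "wall_time_s": round(time.time() - t0, 3),
                "outputs": sums,
            }
        )

    def verify_input(self, stage: str, path: Path) -> None:
        key = str(path)
        if key in self.checksums and _sha256(path) != self.checksums[key]:
            raise PipelineError(stage, ConfigError(f"checksum mismatch for input {path}"))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        stream=None,
    )
    run = _Run(config)
    for stage in STAGES:
        seed = stage_seed(config.seed, stage)
        t0 = time.time()
        fn = globals()[f"_stage_{stage}"]
        planned: list[Path] = []
        try:
            outputs = fn(run, seed, planned)
        except PipelineError:
            _mark_partial(planned)
            raise
        except Exception as exc:
            _mark_partial(planned)
            raise PipelineError(stage, exc) from exc
        run.record(stage, seed, t0, outputs)
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)
    manifest_path = run.out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(run.manifest, fh, indent=1)
    return run.manifest


def _mark_partial(planned: list[Path]) -> None:
    for p in planned:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".partial"))


def _stage_simulate(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    cfg = SimulationConfig(
        seed=seed, n_hotspots=run.config.n_hotspots, genome_size=run.config.genome_size
    )
    bundle = simulate(cfg)
    sim_dir = run.out / "sim"
    bundle.write(sim_dir)
    run.state["bundle"] = bundle
    return sorted(sim_dir.iterdir())


def _stage_clean(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    bundle = run.state["bundle"]
    run.verify_input("clean", run.out / "sim" / "source_control.bed")
    cleaned, reports = {}, {}
    for name, ps in bundle.source_peaks.items():
        ps1, rep1 = filter_by_significance(ps, run.config.max_p)
        ps2, rep2 = clean_against_control(ps1, bundle.control_peaks)
        cleaned[name] = ps2
        reports[name] = {
            "n_input": rep1.n_input,
            "n_removed_pvalue": rep1.n_removed_pvalue,
            "n_removed_control": rep2.n_removed_control,
            "n_output": rep2.n_output,
        }
    run.state["cleaned"] = cleaned
    path = run.out / "clean_report.json"
    planned.append(path)
    with open(path, "w") as fh:
        json.dump(reports, fh, indent=1)
    return [path]


def _stage_integrate(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    cleaned = run.state["cleaned"]
    sets = list(cleaned.values())
    loci = integrate_loci(sets)
    matrix = build_matrix(loci, sets)
    run.state["matrix"] = matrix
    path = run.out / "loci.csv"
    planned.append(path)
    write_loci(loci, matrix, path)
    return [path]


def _stage_coloc(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    run.verify_input("coloc", run.out / "loci.csv")
    matrix: BindingMatrix = run.state["matrix"]
    bundle = run.state["bundle"]
    universe = coloc.universe_for(
        matrix, bundle.config.genome_size, run.config.effective_genome_fraction
    )
    sim = coloc.similarity_matrix(matrix, universe)
    run.state["universe"] = universe
    sim_path = run.out / "similarity_z.tsv"
    pd.DataFrame(sim.z_values, index=sim.experiments, columns=sim.experiments).to_csv(
        sim_path, sep="\t"
    )
    clusters = coloc.cluster_experiments(sim, n_clusters=min(3, len(sim.experiments)))
    net = coloc.threshold_network(sim, run.config.z_threshold)
    net_path = run.out / "network_edges.tsv"
    with open(net_path, "w") as fh:
        fh.write("node_a\tnode_b\tz\n")
        for a, b, z in net.edges:
            fh.write(f"{a}\t{b}\t{z:.6g}\n")
    cl_path = run.out / "clusters.json"
    planned.extend([sim_path, net_path, cl_path])
    with open(cl_path, "w") as fh:
        json.dump(clusters, fh, indent=1)
    return [sim_path, net_path, cl_path]


def _stage_combos(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    matrix: BindingMatrix = run.state["matrix"]
    bundle = run.state["bundle"]
    factors = list(bundle.config.factors)
    targets = list(bundle.config.target_cooccupancy)
    table = combination_profile_table(
        matrix,
        factors,
        targets,
        target_peak_sets={t: [bundle.source_peaks[t]] for t in targets},
        n_iter=run.config.mc_iters,
        # conditional null: the target is re-placed over the FULL genome so the
        # fixed conditioning loci keep their real coordinate support
        effective_genome=bundle.config.genome_size,
        seed=seed,
        universe=run.state["universe"],
    )
    path = run.out / "combination_fractions.tsv"
    planned.append(path)
    table.to_csv(path, sep="\t", index=False)
    run.state["combos"] = table
    return [path]


def _stage_conserve(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    bundle = run.state["bundle"]
    factors = list(bundle.config.factors)
    src_sets = [run.state["cleaned"][f] for f in factors]
    src_loci = integrate_loci(src_sets)
    matrix_src = build_matrix(src_loci, src_sets)
    tgt_sets = [bundle.target_peaks[f] for f in factors]
    tgt_loci = integrate_loci(tgt_sets)
    matrix_tgt = build_matrix(tgt_loci, tgt_sets)
    run.state["matrix_src"] = matrix_src
    run.state["matrix_tgt"] = matrix_tgt
    queries = [CombinationQuery(required={f}, forbidden=set(factors) - {f}) for f in factors]
    queries.append(CombinationQuery(required=set(factors)))
    table = conservation_by_combination(
        matrix_src, matrix_tgt, bundle.truth.omap, factors,
        minmatch=run.config.minmatch, queries=queries,
    )
    strat = conservation_by_combination(
        matrix_src, matrix_tgt, bundle.truth.omap, factors,
        minmatch=run.config.minmatch,
        extra_condition=bundle.enhancers,
        queries=[CombinationQuery(required=set(factors))],
    )
    strat["query"] = strat["query"] + " & enhancer"
    table = pd.concat([table, strat], ignore_index=True)
    combo_mat = conserved_combination_matrix(
        matrix_src, matrix_tgt, bundle.truth.omap, factors, run.config.minmatch
    )
    p1 = run.out / "conservation.tsv"
    p2 = run.out / "conserved_combinations.tsv"
    planned.extend([p1, p2])
    table.to_csv(p1, sep="\t", index=False)
    combo_mat.to_csv(p2, sep="\t", index=False)
    run.state["conservation"] = table
    return [p1, p2]


def _stage_annotate(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    bundle = run.state["bundle"]
    matrix: BindingMatrix = run.state["matrix"]
    factors = list(bundle.config.factors)
    prox = annotation.classify_proximity(matrix.loci, bundle.tss, run.config.proximal_cutoff)
    triple = select_loci(matrix, CombinationQuery(required=set(factors)))
    triple_loci = [matrix.loci[i] for i in np.flatnonzero(triple)]
    frac, z, p = annotation.region_overlap_enrichment(
        triple_loci,
        bundle.enhancers,
        bundle.truth.chrom_sizes_src,
        n_iter=run.config.mc_iters,
        effective_genome=bundle.config.genome_size,
        seed=seed,
    )
    profile = annotation.signal_profile(
        triple_loci, bundle.signal, chrom_sizes=bundle.truth.chrom_sizes_src
    )
    p1 = run.out / "proximity.tsv"
    p2 = run.out / "enhancer_enrichment.json"
    p3 = run.out / "signal_profile.tsv"
    planned.extend([p1, p2, p3])
    prox.to_csv(p1, sep="\t", index=False)
    with open(p2, "w") as fh:
        json.dump({"fraction": frac, "z": z, "p": p, "n_loci": len(triple_loci)}, fh, indent=1)
    bin_width = 2 * profile.window // profile.n_bins
    pd.DataFrame(
        {
            "bin_start_offset": np.arange(profile.n_bins) * bin_width - profile.window,
            "mean_signal": profile.values,
        }
    ).to_csv(p3, sep="\t", index=False)
    run.state["enhancer_enrichment"] = (frac, z, p, len(triple_loci))
    return [p1, p2, p3]


def _stage_gsea(run: _Run, seed: int, planned: list[Path]) -> list[Path]:
    bundle = run.state["bundle"]
    results = {}
    for set_id, genes in (
        ("active", bundle.active_gene_set),
        ("poised", bundle.poised_gene_set),
    ):
        if not genes:
            continue
        res = gsea.permutation_p(
            bundle.expression, genes, n_perm=run.config.n_perm, seed=seed, gene_set_id=set_id
        )
        results[set_id] = {
            "es": res.es,
            "p_value": res.p_value,
            "n_hits": res.n_hits,
            "mode": res.mode,
        }
    path = run.out / "gsea.json"
    planned.append(path)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1)
    run.state["gsea"] = results
    return [path]
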