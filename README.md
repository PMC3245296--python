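# combind

Combinatorial transcription-factor binding analysis for multi-factor
ChIP-seq experiments.

In embryonic stem cells the pluripotency factors OCT4, SOX2 and NANOG often
occupy the same regulatory loci simultaneously. Whether a locus is bound by
one of them or by all three turns out to predict very different biology:
co-localization of the Mediator co-activator, active-enhancer chromatin,
expression of nearby genes, and — most strikingly — whether the binding
event is conserved between species. `combind` provides the full analysis
machinery to ask these questions of any collection of peak sets:

* **Locus integration** — peaks from all experiments are merged into
  regulatory loci (connected components of the ≥1-bp overlap graph), giving
  a binary loci × experiments **binding matrix**.
* **Co-localization statistics** — for experiments A and B with `n_A`, `n_B`
  bound loci and `k` shared, significance comes from a hypergeometric slot
  model, `k ~ Hypergeom(N, n_A, n_B)` with `N = effective_genome /
  slot_width` (effective genome = ¼ of the genome, a conservative choice),
  plus a Monte-Carlo null that re-places peaks uniformly with lengths
  preserved. z-scores feed average-linkage clustering of experiments and a
  thresholded co-binding network.
* **Combination queries** — AND / OR / NOT selections over the matrix
  ("loci bound by all three factors but not CTCF"), with the fraction of
  selected loci co-occupied by a target factor and a randomization z
  (negative z = depletion).
* **Conservation** — loci are mapped between genomes through an orthology
  block map (LiftOver-equivalent semantics: `minmatch` coverage, unique
  image required); a binding event is conserved when the same factor is
  bound at the orthologous locus. Conserved fractions are stratified by
  combination class and by overlap with annotated region sets.
* **Annotation** — nearest-TSS proximal/distal classification (1 kb
  cutoff), region-set overlap enrichment, and binned signal metaprofiles
  around loci.
* **Gene-set enrichment** — genes ranked by the two-group signal-to-noise
  ratio `s_g = (μ_A − μ_B)/(σ_A + σ_B)`; the enrichment score is the signed
  extremum of the weighted Kolmogorov–Smirnov running sum, with a
  sample-label permutation p-value.
* **Synthetic data** — a generator that plants all of the above structure
  (joint occupancy, combination-dependent target co-occupancy and
  conservation, enhancer flags, expression shifts) with recoverable ground
  truth, so every statistic can be validated end to end.

## Worked example

```bash
combind run --out-dir demo --seed 7
```

runs the whole pipeline on a fresh synthetic bundle (10 Mb genome, 500
regulatory hotspots, factors OCT4/SOX2/NANOG, targets MED1/MED12/CTCF) and
writes per-stage tables plus a manifest. The same analysis from Python:

```python
from combind.synthetic_data import SimulationConfig, simulate
from combind.locus_integration import integrate_loci, build_matrix
from combind.combinations import CombinationQuery, combination_fraction

bundle = simulate(SimulationConfig(seed=1))
sets = list(bundle.source_peaks.values())
matrix = build_matrix(integrate_loci(sets), sets)
triple = CombinationQuery(required={"OCT4", "SOX2", "NANOG"})
res = combination_fraction(matrix, triple, "MED1",
                           [bundle.source_peaks["MED1"]],
                           effective_genome=bundle.config.genome_size,
                           n_iter=300, seed=7)
print(f"{res.n_selected} combinatorially bound loci; "
      f"MED1 at {100 * res.fraction:.1f}% (z = {res.z:.1f})")
```

prints

```
113 combinatorially bound loci; MED1 at 43.4% (z = 40.8)
```

i.e. of the 113 loci bound by all three factors, 43.4 % also carry the
Mediator subunit — about forty standard deviations above what uniformly
re-placed MED1 peaks would produce. The same bundle yields the conservation
contrast (a few % for singly bound loci, ~14 % for combinatorially bound
ones, >50 % at developmental-enhancer loci) and a positive/negative
enrichment-score pair for genes near Mediator-bound vs Mediator-free
combinatorial loci.

## Layout

```
src/combind/
  core.py                 domain types (intervals, peaks, loci, matrix, tracks)
  genomic_io.py           BED / narrowPeak / bedGraph / TSV / loci-CSV I/O
  intervals.py            vectorized merge & overlap primitives
  peak_processing.py      p-value filter, control cleaning, stringent subset
  locus_integration.py    locus merging and the binding matrix
  colocalization_stats.py hypergeometric + Monte-Carlo nulls, clustering, network
  combinations.py         AND/OR/NOT queries and conditional co-localization
  conservation.py         orthology block map, remapping, conserved fractions
  annotation.py           TSS proximity, region enrichment, signal profiles
  enrichment_gsea.py      signal-to-noise ranking and weighted-KS scores
  synthetic_data.py       ground-truth generator
  pipeline.py, cli.py     orchestration and the `combind` command line
```

See `docs/methods.md` for the statistical models, parameter defaults and
known limitations.
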