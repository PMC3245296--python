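# Methods

## Coordinates and overlap

All coordinates are 0-based half-open (BED convention), everywhere,
internally and on disk; 1-based inputs must be converted explicitly at the
reader — nothing is auto-detected, because silent convention guessing is the
main corruption vector in interval pipelines. "Overlap" means at least one
shared base throughout: `[a,b)` and `[c,d)` overlap iff `a < d` and `c < b`,
so book-ended intervals do not overlap, and a single shared base is enough
to merge peaks, discard a control-hit peak, or set a binding-matrix entry.
Peak scores are `-log10(p)` of the peak caller's p-value; ranking "by
p-value" is therefore descending score, with ties broken by genomic
position so every subset operation is deterministic.

## Locus integration

Regulatory loci are the connected components of the ≥1-bp overlap graph
over the union of all experiments' peaks; each locus spans
`min(start)..max(end)` of its component, so chains of pairwise-overlapping
peaks extend transitively into one locus that can exceed any single peak's
span. The operation is idempotent, order-independent, and conserves base
coverage exactly (tested against a brute-force union-find oracle). Locus
ids are `{chrom}:{start}-{end}` for stable joins across stages.

## Co-localization nulls

Two nulls quantify shared binding between experiments A and B:

**Hypergeometric slot model.** The effective genome — by default one
quarter of the genome size, a deliberately conservative reduction of the
accessible space — is divided into `N = effective_genome / slot_width`
slots, with `slot_width` defaulting to the median integrated-locus length.
With `n_A`, `n_B` loci bound and `k` shared,
`k ~ Hypergeom(N, n_A, n_B)`; we report the exact mean `n_A n_B / N`,
variance, upper-tail probability, and `z = (k − E k)/sd`. Zero-variance
cases (empty column, saturated universe) are flagged degenerate with
`z = 0`, never ±∞. The slot discretization is one defensible reading of a
continuous problem; the Monte-Carlo null below is the authoritative
cross-check, and the test suite verifies that under both-set randomization
the empirical null moments match the hypergeometric closed form when the
slot width equals the collision width `2w − 1` of width-`w` peaks.

**Position randomization.** Peaks keep their lengths and receive uniform
positions; the effective genome is apportioned to chromosomes by their
share and a chromosome is drawn with that probability. Randomized peaks may
overlap each other (no rejection), keeping the estimator unbiased. For
*pairwise* overlap statistics both sets live in the same reduced quarter
space (the conservative convention). For *conditional* statistics — the
combination-fraction z, region-set enrichment, the conservation null —
the conditioning loci keep their real coordinates, so the randomized
set is re-placed over the **full** genome; re-placing it into the quarter
prefix while the fixed loci span the whole genome would bias the null
downward. Empirical p-values use the add-one estimator
`(1 + #{null ≥ obs})/(n_iter + 1)` and are never exactly zero.

Experiment similarity is the matrix of pairwise hypergeometric z-scores;
experiments are clustered by average-linkage agglomeration on
`distance = max(z) − z` (linkage chosen for robustness to the heavy-tailed
z distribution; the clustering is deterministic given the matrix), and the
co-binding network keeps edges with `z ≥ threshold` — the threshold is a
required analysis parameter with no universal default.

## Combination queries

A query has `required` (AND), `forbidden` (NOT) and `any_of` (OR) label
sets over experiments or factors; a factor label pools its experiments by
OR (an `intersect_replicates` switch gives AND pooling). The 8 exclusive
AND/NOT combinations of a factor triple partition the loci selected by the
OR query — asserted on every profile-table run. The combination-conditional
co-localization fraction conditions on the selected loci and randomizes
only the target factor's peaks, recomputing the target column per draw;
this preserves the conditioning set exactly and makes depletion visible as
negative z. An analytic hypergeometric z (treating the selected loci as
draws against the target's genome-wide locus occupancy) is reported
alongside as a cross-check. Because the caption convention for
single-factor bars is ambiguous, the standard query family emits both
variants: the factor alone with the others unconstrained, and with the
others forbidden.

## Conservation

The orthology map is a chain-style TSV of equal-length blocks
`(src_chrom, src_start, src_end, tgt_chrom, tgt_start, tgt_end, strand)`;
source blocks may not overlap, and negative-strand blocks map by
reflection (images reported in forward coordinates). A locus maps when (i)
at least `minmatch` (default 0.1) of its bases are covered by blocks, and
(ii) its image is unique: one target chromosome, with same-chromosome
image segments separated by at most `gap_tolerance` (default 10× the locus
length — an explicit stand-in for LiftOver's span-based rejection, which
the original tool does not document at this granularity). Uniqueness is
enforced per merged locus, not per constituent peak. Raising `minmatch`
never increases the mapped count, and an identity map is the identity on
every locus (both property-tested).

A source locus bound by a factor is *conserved* when its mapped interval
shares ≥1 base with a target-genome locus whose same-factor column is 1.
Unmapped / ambiguous / below-minmatch loci are tallied separately and never
count as conserved; conserved fractions are reported over mappable loci.
The optional region-set stratification intersects each query with loci
overlapping the set (the developmental-enhancer analysis); the optional z
re-places the selected source loci uniformly over the full source genome,
remaps and recounts.

## Annotation

TSS distance is signed, measured from the locus midpoint (merged loci have
no single summit; midpoint matches the profile anchoring and is
scale-stable for wide loci — an edge-distance switch exists). A locus is
proximal iff `|distance| ≤ 1000` bp, so "more than 1 kb away" is distal;
ties go to the lower-coordinate TSS. Signal metaprofiles average the track
in `n_bins` equal bins across `[midpoint − W, midpoint + W)` with
`W = 3000` and 60 bins by default; each locus contributes its per-bin mean
value, windows are clipped at chromosome ends with per-bin denominators
adjusted, and the profile is linear in the track (tested against a
per-base accumulation oracle).

## Gene-set enrichment

Genes are ranked by the signal-to-noise ratio
`s_g = (μ_A − μ_B)/(σ_A + σ_B)` with each group's sd floored at
`max(0.2·|μ|, 0.2)` — the convention of the original GSEA implementation,
which the upstream analysis used as external software. The enrichment
score walks the descending ranking, rising `|s_g|^p / Σ_hits |s|^p` at set
members and falling `1/(N − N_hits)` otherwise; the score is the signed
extremum of the running sum, which ends at 0 by construction. `p = 1` is
the default; `p = 0` reduces to the classical two-sample KS statistic on
hit vs miss positions, which the tests exploit as a closed-form check.
Significance permutes sample labels and re-ranks per draw; designs with
fewer than 6 samples fall back to gene-set permutation with a logged
warning (label permutation is too granular there). The reported p uses the
add-one correction and is never exactly 0.

## Synthetic data

The generator emulates the statistical skeleton of a two-species
multi-factor binding study, not its sequence-level detail. Defaults: a
10 Mb genome on 4 chromosomes with 500 non-overlapping hotspot loci
(width ≈ N(400, 80) bp, ≥2 kb apart so ground truth maps 1:1 to integrated
loci); a joint occupancy model over factor subsets (triple 0.25, each pair
0.07, each single 0.12, none 0.18); Mediator-analog targets bound
conditionally on the combination class (MED1 0.02/0.12/0.25/0.45 and MED12
0.02/0.15/0.30/0.60 for none/single/pair/triple — the monotone effect the
co-localization analysis should recover) and an insulator-analog control
with mildly *decreasing* rates (0.10/0.08/0.05/0.03) plus 1200 background
sites of its own, matching the real situation in which insulator binding
is genome-wide abundant (its site count is a few-fold the number of
combinatorial loci) yet depleted at enhancers; 40 uniform decoy peaks per
experiment and 25 treatment-unspecific control peaks, both kept clear of
hotspots. Peak positions jitter by N(0, w/10) truncated to retain ≥50%
hotspot overlap, exercising merging without breaking locus identity.

Conservation is planted per class — none 0.02, single 0.05, pair 0.10,
triple 0.15, rising to 0.55 for triple hotspots flagged as developmental
enhancers (10% of hotspots) — mirroring the qualitative <5% / ~15% /
>50% contrast the conservation analysis is built to detect. The orthologous
genome is produced by a deletion-only block map whose gaps swallow a
configurable 10% of hotspots; conserved hotspots re-emit their factor
subset at the mapped coordinates. Gaussian signal bumps (amplitude 5,
50-bp steps) mark Mediator-bound hotspots; planted TSSs straddle the 1-kb
proximal cutoff; the expression table (400 genes, 4 + 4 samples,
N(8, 1) baseline clipped at 0) shifts genes near Mediator-bound triple
hotspots up by 2 units in the stem-like group and genes near
Mediator-free triple hotspots up in the differentiated-like group — the
active/poised contrast. The bundle is byte-deterministic given the seed,
and `truth_report` compares any pipeline estimate against the *realized*
planted rate (what the random draws actually produced) at a 3-binomial-SE
tolerance.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: mappability and GC structure, correlated
backgrounds between experiments, quantitative occupancy, peak-caller
artefacts, rearrangements beyond deletions in the orthology map, and
realistic expression covariance. Recovery results validate the statistical
machinery, not robustness to those confounders.

## Problem sizes and numerical choices

Default analysis scale (500 hotspots, ~1200 loci with the insulator
background, 200–500 null iterations, 500 permutations) runs the full
pipeline in seconds; validation experiments in the test suite use
50-seed calibration batches and 20–40-seed recovery batches at the same or
slightly reduced scale. The conservation-recovery experiment switches
decoys off so the planted per-class rates are identifiable (decoy loci are
planted non-conserved singles and would otherwise dilute the single-class
estimate by a known factor). The GSEA power experiment uses 5 + 5 samples:
with 4 + 4, label permutation has only 70 distinct splits and the
achievable p-value floor sits too close to 0.05 for a stable power
statement. Ties, degenerate variances and empty selections are always
flagged rather than coerced; all randomness flows from explicit seeds
through `numpy.random.default_rng`, and the pipeline derives per-stage
seeds from the global seed by a fixed stage-name hash so stages are
reproducible independently of execution order.

## Known limitations

The hypergeometric universe is a modelling choice with no unique answer;
conclusions should lean on the Monte-Carlo z when the two disagree. The
randomization nulls are unstratified (no GC, mappability or chromatin-state
matching). The orthology remapper handles deletion/offset/inversion maps
but not duplications (a source interval maps to at most one image by
construction). Conservation is called at locus resolution — a conserved
event does not imply base-level sequence conservation.
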