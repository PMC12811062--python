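# Methods

## The fitness model

tnfit scores each disrupted gene in a pooled transposon library by
competitive fitness over a fixed growth interval. Writing
*n*<sub>t1</sub>, *n*<sub>t2</sub> for the gene's read proportions at
inoculation and harvest and *d* for the population expansion factor
(harvest OD600 over inoculation OD600),

W = ln(n_t2 · d / n_t1) / ln((1 − n_t2) · d / (1 − n_t1)).

The numerator is the natural-log fold-expansion of the mutant lineage
(n_t2·d/n_t1 is how many times the lineage itself multiplied); the
denominator is the same quantity for everything else in the flask. W = 1
means the mutant grew exactly as fast as the rest of the population,
W = 0 that it did not grow at all, W > 1 that the disruption helped.

Assumptions worth stating:

- *d* is measured per flask (per replicate) and each replicate's W uses
  its own *d*; replicate W values are combined by arithmetic mean, and
  the replicate distance is the maximum pairwise absolute difference
  (for duplicates, simply |w1 − w2|).
- Proportions are computed against the total of the count table. If the
  table contains every mapped read this equals reads-in-library; when a
  caller aggregates only genic reads the denominator shrinks accordingly
  (both n_t1 and n_t2 shift together, which largely cancels in W).
- Natural logarithms throughout.

### What "fitness" means in a mixed population

W is defined *relative to the rest of the population*, and this matters
whenever a non-trivial fraction of the library is non-neutral. If a
fraction *q* of t1 abundance carries strongly deleterious insertions, the
"rest of the population" expands by roughly (1 − q)·E rather than the
neutral lineage's E, so every neutral gene's competitive fitness is
ln E / ln((1 − q)E) ≈ 1 − ln(1 − q)/ln d above one — about +0.02 for
q = 10%, d ≈ 120. This is not estimator error: it is what the statistic
measures. Consequently the simulator's generative parameter W_true (the
exponent in the lineage's E^W expansion) coincides with estimated W
exactly only when at most one gene is non-neutral; recovery tests
therefore separate (a) exact inversion on single-perturbation libraries,
(b) sampling error against the exact finite-population estimand (the
noise-free rerun of the same flasks), and (c) a coarser ±0.05 agreement
with W_true across the library, which absorbs the definitional offset.

## Exclusion rules

- **Zero counts.** A gene with zero reads in any relevant sample is
  flagged and its affected replicate W is absent — never a substituted
  number. A zero only says the lineage disappeared at some unknown point
  within the ~7 generations; treating it as a very small number would
  fabricate a rate.
- **Low t1 representation.** Genes averaging ≤ 50 t1 reads (strictly
  more than 50 survives) are flagged: their inoculation proportion is too
  noisy to anchor the ratio. In the carbon-shift design these are also
  the candidate essential genes of the isolation medium, since their
  mutants never accumulated in the library.

## The selection cascade

Order of operations, with every stage's survivor count recorded:

1. **Completeness** — genes free of both flags in every condition.
2. **Baseline neutrality** — baseline mean W inside the closed band
   [0.9, 1.1]: the gene's loss "does not affect" baseline growth.
   Closed because the band's wording is inclusive ("between").
3. **Replicate concordance** — replicate distance strictly below 0.2 in
   every challenge condition. Strict because the wording is "less than".
   Stages 2 and 3 are computed in parallel on the completeness survivors
   and reported separately (`parallel_counts`); their intersection is
   carried forward.
4. **Differential / specific calls** — at each threshold θ ∈
   {0.2, 0.3, 0.4} (strict >), a gene is differential on substrate *s*
   when |mean W(s) − mean W(baseline)| > θ, and specific to *s* when
   differential on *s* alone.

The published screen's counts (3,705 zero-free genes; 2,825 in the
sucrose neutral band; 2,807 replicate-concordant; 424 / 85 differential
at 0.2 / 0.4; 55 acetate-specific at 0.4) can be recomputed by running
`run_cascade` with the default `FilterConfig` on the study's deposited
per-gene fitness table. That table is not redistributed here; to run the
reproduction, save it as `data/file_s1_fitness.tsv` with columns
`gene_id`, `condition`, `w_rep1`, `w_rep2` (or `mean_w` plus
`replicate_distance`), one row per gene × condition, conditions named
`sucrose` (baseline), `acetate`, `succinate`, `glycerol`. The paragraph
in the source describing the ordering is ambiguous about whether the
424/85/55 differential counts were taken after the neutral-band filter,
the concordance filter, or both; the default here is the intersection
(both), and the other two variants are reachable by passing a config with
the corresponding filter disabled (band (−∞, ∞) or distance cap ∞).

## The simulator

`make_library` draws a library of N genes in which a fraction (default
10%) is deleterious with fitness uniform on [0, 0.6] and the rest exactly
neutral; t1 abundances are log-normal. `simulate_experiment` expands each
lineage by E^W (E jittered ±5% per flask, emulating flask-to-flask
variation in the harvest OD; the flask's realized abundance-weighted
expansion is recorded as its OD ratio, which is exactly the *d* the
estimator should consume) and sequences by multinomial draw at the
requested depth. Depth 0 switches to noise-free mode: expected
proportions scaled to a nominal 15M reads, as real-valued "counts",
intended only for tests; the random stream is consumed identically in
both modes, so a depth-0 rerun at the same seed reproduces the same
flasks and serves as the exact estimand of a sampled run.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| background expansion E | 121.1 | mid-range of the published per-flask expansion factors (99–155, ~7 generations) |
| replicates | 2 | duplicate flasks, as in the screen |
| depth | 15,000,000 | the screen's per-sample mapped-read scale |
| abundance dispersion σ | 1.4 | puts ~1–2% of a 5,000-gene library under 50 t1 reads at 15M depth, exercising the low-count exclusion |
| frac. deleterious | 0.1 | a mostly-neutral library with a minority of deleterious genes, matching the screen's observed composition |
| deleterious fitness range | [0, 0.6] | spans dead to mildly impaired lineages |
| replicate jitter | ±5% | per-flask variation of the same order as the published duplicate expansion factors |
| inoculation OD | 0.05 | implied by harvest ODs of ~5–8 at expansion ~100–155; the OD pair is free, only the ratio matters |

What the simulator does **not** emulate: insertion-site positions within
genes (sites exist only for the aggregation step's own tests), PCR and
mapping bias, between-gene count correlation beyond the multinomial
constraint, bottlenecks during inoculation, and genes whose
representation drifts during library isolation. Passing recovery tests
therefore demonstrates correctness of the estimator and cascade given
multinomially sampled counts, not robustness to library-prep artifacts.

## Numerical choices

- W is computed exactly as the log-ratio; no clamping, no
  pseudo-counts. Zero harvest proportions raise a typed signal
  (`UndefinedFitnessError`) that the table layer converts into a flag
  plus an absent value.
- A denominator log of zero (the rest of the population did not expand)
  raises `DegenerateSampleError`; it cannot occur in realistic runs
  (d ≫ 1) but is checked rather than returned as ±inf.
- Mean mapped reads are rounded half away from zero to the nearest
  integer; all W comparisons run on full precision, and TSVs print W with
  six decimals.
- Gene trimming for site aggregation removes `edge_trim`·length from each
  gene end, rounding toward the interior (ceil), so a trimmed interval
  never overlaps the removed fraction; coordinates are 1-based inclusive
  end-to-end, and boundary insertions at a gene's first or last base
  count as inside.
- Overlapping genes both receive a shared site's reads by default
  (a disruption disrupts both); a "first gene" mode exists for callers
  that need disjoint totals.

## Test problem sizes

The recovery suite runs 20 seeded screens of 5,000 genes × 2 flasks at
15M reads (plus matched noise-free reruns), the cascade oracle check runs
1,000 random ≤50-gene tables against an independent brute-force re-scan,
and the planted-signal check uses a 1,000-gene noise-free screen with 100
planted effects. These sizes keep the whole suite in the tens of seconds
on one CPU while matching the screen's per-sample depth exactly.

## Known limitations

- With duplicate flasks there is no variance model and no hypothesis
  test on W; the cascade is a deterministic threshold classifier, which
  is faithful to the screen's design but provides no error rates.
- The low-count and zero-count exclusions interact with depth: at much
  lower sequencing depth more genes are flagged and the cascade's input
  shrinks; thresholds are counts, not proportions, by design.
- The t1 library is a single pooled sample; its sampling noise is shared
  across all conditions and replicates and does not average out.
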