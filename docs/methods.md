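# Methods

This note documents the statistical models, parameter defaults, and design
choices behind `twostep-rnaseq`, and what the simulation-based tests do and
do not establish about real data.

## The two-step design and the re-pooling formula

A two-step screen sequences many barcoded libraries shallowly in one pooled
run, ranks conditions (here: by DE-gene count at 10% BH-FDR), and re-pools a
selection of the *same physical libraries* for deep sequencing. Because step
one is itself a sequencing experiment, it measures each library's **digital
concentration** `R_i` — raw reads obtained per µL of library pooled — which
folds in cluster-formation efficiency and any other library-specific yield
factor. With a cumulative per-sample target `T` and reads already collected
`D_i`, the re-pool volume is

```
V_i = max(0, T − D_i) / R_i
```

with pool proportions `V_i / ΣV_j`. Under exact delivery of
`run_output = Σ_j (T − D_j)+` assignable reads, predicted reads are
`run_output · (T − D_i)+ / Σ(T − D_j)+`, so every deficient library ends
exactly at `T`; under multinomial allocation noise the cumulative depth
distribution still tightens sharply (the acceptance suite requires a CV
reduction in ≥95 of 100 simulated 96-plex experiments; in practice it is
100/100). Choices the formula's text leaves open:

- **Over-sequenced libraries** (`D_i ≥ T`) get volume 0 (deficit clamped at
  zero) rather than a negative dose.
- Both volumes and normalized proportions are reported, since either may be
  the quantity pipetted.
- In iterative plans, `R_i` is re-estimated from the most recent run by
  default (`r_update="latest"`); `"pooled"` volume-weights all runs. A
  library with zero reads in the new run keeps its previous `R_i` (no
  information).
- Undetermined (unassigned-barcode) reads never enter `R_i`; the expected
  yield of a planned run refers to assignable reads (an
  `assignable_fraction` knob, default 1.0, scales it).
- Volumes are reported at 0.01 µL resolution; full precision is kept
  internally.

## Count model and the synthetic-data generator

Counts follow a hierarchical Gamma–Poisson: per library (sample) `s` and
gene `g`, a latent relative rate

```
q_gs ~ Gamma(shape = 1/α_g, mean = r_gs)
```

is drawn once per library, and sequencing at depth `d` yields
`K ~ Poisson(d · q_gs)`. Marginally `K ~ NB(µ = d·r_gs, α_g)` with variance
`µ + α µ²` (the standard parameterization). Two matrices generated at
different depths from the *same* latent rates emulate re-sequencing the same
libraries — which is what step two physically does. This coupling matters:
with only three replicates per group and a dispersion floor of 0.05, fold
changes estimated from *independent* biological experiments at 5 M and 75 M
reads/sample can rank-correlate at best ρ ≈ 0.5–0.6 regardless of depth,
while re-sequenced libraries share their biological noise and reach
ρ ≈ 0.9 — the regime a two-step design operates in.

Expected rates fold together a log-normal baseline abundance, the treatment
effect `2^lfc` for treated samples, and a covariate bias
`exp(gc_beta·GC + len_beta·log10(len) + gclen_beta·GC·log10(len))`, then
renormalize per sample so that depth is the only column-total driver
(sequencing is compositional).

Generator defaults (the simulated study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10,000 | transcripts (one per gene) |
| `groups` | control 3 + treatment 3 | replicates per condition |
| `frac_de` | 0.10 | fraction of genes with true effects per treatment |
| `effect_sd` | 1.0 | sd of true log2 fold changes |
| `baseline_log_mean/sd` | 3.0 / 2.0 | natural-log abundance scale/spread (~4 orders of magnitude dynamic range) |
| `disp_a0`, `disp_a1` | 0.05, 2.0 | dispersion trend α(µ) = a0 + a1/µ |
| `eff_log_sd` | 0.5 | log-sd of per-library cluster efficiencies (2–3× depth spread) |
| `gc_beta`, `len_beta`, `gclen_beta` | 1.0, 0.3, 0.0 | covariate bias coefficients |
| `ref_depth` | 5 × 10⁶ | depth anchoring the µ in the dispersion trend |

Per-gene true dispersions are placed exactly on the trend evaluated at the
gene's expected control count at `ref_depth` (no extra gene-level scatter);
cluster efficiencies are log-normal rescaled to mean 1 — a right-skewed
spread consistent with observed per-barcode depth distributions; transcript
lengths are log-uniform in [200, 20000] bp and GC is Beta-shaped in
[0.2, 0.8]. One global seed feeds fixed per-operation substreams
(annotation, baseline, effects, efficiencies, rates, counts), so stages
re-run independently yet reproducibly.

**What the generator does not emulate:** isoform structure (one transcript
per gene), read-level artifacts (no FASTQ, mapping or duplicate-removal
effects), batch or run effects beyond depth, correlated gene modules,
outlier samples, and gene-level dispersion scatter around the trend.
Passing tests therefore demonstrate the machinery's correctness and the
depth-vs-power trade-offs under a faithful NB world, not robustness to every
real-data pathology.

## Differential expression engine

Per contrast (a treatment and its matched vehicle control), each transcript
gets an NB GLM with log link, intercept + condition indicator, log size
factors as offsets, and a fixed (shrunken) dispersion; estimation is
vectorized Fisher scoring (max 100 iterations, relative log-likelihood
tolerance 1e-8, steps clipped to ±5, coefficients bounded at |β| ≤ 22 on
the natural-log scale). Non-converged fits are reported as missing with a
flag, never silently. The Wald statistic `log2FC / SE` uses the observed
Fisher information and a normal reference (no small-sample t correction).
Transcripts with total raw reads ≤ 20 over the contrast's samples (strict
`> 20` filter; scope configurable to global) are marked untested and carry
missing p/q. BH adjustment is step-up over the tested set. A gene is DE if
at least one of its transcripts passes the FDR threshold; direction is
reported both from any significant transcript (conflicts flagged and counted
in both directions) and from the most significant one.

**Size factors** are median-of-ratios over transcripts observed in every
sample, rescaled to geometric mean 1, with a positive-counts fallback when
no transcript is shared.

**Dispersion estimation** pools a method-of-moments estimate across
conditions with ≥2 replicates:

```
α̂_g = Σ_c (n_c − 1)(v_c − m_c ξ_c)  /  Σ_c (n_c − 1) m_c² ,
```

(`m_c`, `v_c`: mean/variance of normalized counts within condition `c`;
`ξ_c` the mean reciprocal size factor, i.e. the shot-noise expectation),
clipped below at 1e-8. The mean trend `α(µ) = a0 + a1/µ` is fitted by a
**gamma GLM with identity link** and an outlier-re-excluding iteration
(>10× off the fit): moment estimates at a handful of residual degrees of
freedom are strongly right-skewed, so a median-targeting robust fit would
underestimate the trend and inflate every downstream Wald statistic; the
gamma family targets the conditional mean. The final dispersion
interpolates raw and trend on the log scale. The default weight is chosen
**empirically** per dataset: with `s2_samp = trigamma(df/2)` the theoretical
sampling variance of a log moment estimate and `s2_gene` the excess MAD² of
`log(raw/trend)` measured on high-information genes (α·µ > 20, where shot
noise cannot inflate the spread), the trend weight is
`s2_samp / (s2_samp + s2_gene)`. When the scatter around the trend is fully
explained by estimation noise the engine shrinks essentially to the trend —
which is what keeps control-vs-control contrasts clean (median 0 false DE
genes across 50 simulated null runs, and uniform p-values by KS in the large
majority of runs) — while data with genuine gene-level dispersion signal
retain weight on the raw estimates. A fixed weight in [0, 1] can be forced
via `shrink_weight`.

This engine is deliberately simpler than full empirical-Bayes DE machinery:
no Cox–Reid adjustment, no outlier replacement, no independent filtering,
and no fold-change shrinkage; it makes no claim of numerical agreement with
any specific external tool.

## Normalization chain and clustering

The chain is staged and order-enforced (each DataFrame carries a stage tag):

1. `FPKM_gs = count · 10⁹ / (length_g · total_s)`;
2. per-sample OLS residuals of `log2(FPKM + 0.5)` on
   `[1, GC, log10 len, GC·log10 len]` (pseudocount configurable; length on
   log10 scale so kilobase-vs-megabase outliers don't dominate; collinear
   columns dropped with a warning);
3. classic across-sample quantile normalization (rank → mean order
   statistic; ties get the mean of the reference values they span), which
   exactly equalizes marginal distributions;
4. per-individual centering of each transcript by the 10% trimmed (Tukey's)
   mean across that individual's samples — `floor(trim·n)` values dropped
   from each tail, plain mean with a warning when an individual has fewer
   than 3 samples.

Clustering: Pearson correlation between sample columns, average-linkage
agglomeration on `1 − r` (both configurable), leaf order, flat cuts, and a
Newick serialization of the dendrogram. Zero-variance samples are excluded
with a warning.

## Downsampling evaluation

Thinning replaces each count by `Binomial(count, r)` — distributionally
identical to keeping each read with probability `r`, hence to sequencing the
same library at a fraction `r` of the depth; ratio 1 is the exact identity
(no RNG consumed). Default ratios 1, 1/2, 1/4, 1/6, 1/8, 1/10, 1/12
correspond to multiplexing 96·(1/r) samples on the same flow cell.
Concordance metrics: Spearman ρ of log2 fold changes over genes tested in
both results (all genes, not just significant ones; <10 shared genes is an
error), and the recovered fraction of a reference DE set. Per-treatment and
across-treatment means are both reported. The generic rank-correlation
helper returns an exact permutation p-value for n ≤ 10 (full n!
enumeration, so use deliberately) and a normal approximation
`z = ρ√(n−1)` above that.

## Simulated study sizes

The acceptance script and test suite run one treatment vs control with 3
replicates each at 10,000 genes (5 M vs 75 M reads/sample), 50 null runs at
5,000 genes, and 100 re-pooling simulations at 96 libraries; these sizes
give stable estimates of every reported quantity while completing in
seconds. Typical results: shallow/deep fold-change ρ ≈ 0.89, ρ ≈ 0.75 after
1/8 thinning, 65–80% DE-gene recovery at 1/2 thinning, 0 median null DE
genes, and 100/100 depth-CV reductions.

## Known limitations

- The Wald test with a normal reference is approximate at 3 replicates per
  group; calibration holds under the generator (where dispersions sit on
  the trend) and should be re-checked on data with heavy gene-level
  dispersion scatter.
- The trigamma-based sampling-variance approximation behind the automatic
  shrinkage weight ignores shot noise; it is measured on high-information
  genes to compensate, but extremely shallow data (most genes with α·µ < 20)
  fall back to a more conservative selection.
- `iterate_plan`'s pooled `R` update treats pre-plan volumes as unknown and
  only accumulates volumes it has seen.
- Gene-level inference assumes the annotation's transcript→gene map; with
  multi-transcript genes the "any transcript" rule is liberal by
  construction (conflicting directions are flagged, not resolved).
- FPKM totals are per-matrix column sums ("counted reads"), not mapped-read
  totals from an external log.
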