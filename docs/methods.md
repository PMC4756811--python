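# Methods

This document states the model and procedure each module implements, the
meaning and default of every parameter, the scope of the synthetic-data
generator, the numerical choices, and the limitations of the validation.

## 1. Interval algebra and region taxonomy (`intervals`)

All coordinates are **0-based, half-open** `[start, end)` (BED
convention). A `RegionSet` stores per-chromosome sorted, merged interval
arrays; merging joins overlapping *and abutting* intervals, so a
`RegionSet` is a canonical form and equality is well defined. Operations:

* `union`, `subtract`, `intersect` — sweep over merged endpoint arrays;
* `contains(chrom, positions)` — vectorized membership via binary search;
* `shore_of(cgi, genome, flank=2000)` — ±2 kb flanks of CGIs, minus CGI
  bases themselves, clipped to chromosome bounds;
* `promoter_of(gene, length=1500)` — strand-aware: 1 500 bp upstream of
  the TSS (`[start−1500, start)` on `+`, `[end, end+1500)` on `−`);
* `five_prime_body_of(gene, fraction=0.1)` — the first
  `max(1, floor(0.1·gene_length))` bases of the gene body from the TSS,
  strand-aware;
* `build_backbone(genome, functional_sets, repeats)` — the set
  difference of the whole genome against the union of CGIs, shores,
  promoters, 5′-bodies, exons, DNase sites, TF sites, enhancers and
  repeats. LADs are an *overlay* used for contrasts, never part of the
  removed union.

The backbone is validated against an independent per-base oracle: on
random toy genomes, boolean per-base coverage of the complement must
equal `build_backbone`'s interval output exactly.

## 2. Probe quality control (`probe_qc`)

Global (manifest-level) masks remove a probe entirely when any of:

| rule | parameter | default |
|---|---|---|
| SNP proximity | `snp_window` (bp, remove when `snp_dist ≤`) | 10 |
| repeat overlap | `repeat_within_15bp` flag set | 15 bp window |
| sex chromosome | `chrom ∈ {chrX, chrY, X, Y}` | — |

A per-cell mask marks individual (probe, sample) measurements whose
detection p-value is **strictly greater** than `detection_p_cut = 0.05`;
the rule is monotone in the cutoff. Retained probes are assigned to
region classes by position (`assign_regions`); a probe may belong to
several classes (e.g. a promoter CGI), and probes in none are reported
as `unannotated`.

## 3. Per-sample metrics and classification (`metrics`)

`avg_cgi` and `avg_backbone` are arithmetic means of unmasked beta
values over the probes of the class, **pairwise-complete** (masked cells
contribute nothing). Samples with fewer than `min_probes = 100` usable
probes get NaN and are left unclassified. Classification:

* CGI axis: `HC` if `avg_cgi > 0.24`, else `NC`;
* backbone axis: `LB` if `avg_backbone < 0.78`, else `NB`;
* the boundary values 0.24 / 0.78 belong to the normal classes
  (`NC`/`NB`), because the cutoffs are by construction the extremes of
  the observed normal ranges (0.18–0.24 and 0.78–0.82);
  `calibrate_thresholds` re-derives them as max/min over a normal cohort.

`concordance` reports Pearson correlations (pooled and per axis)
between array-derived and WGBS-derived per-sample averages over
complete pairs (≥ 3 required).

## 4. Differential calls and TF enrichment (`differential`)

Per-probe normal reference = mean beta over unmasked normal samples,
defined only where **≥ 2** normals are unmasked. A tumor probe is called
hypermethylated when `Δβ > 0.2` and hypomethylated when `Δβ < −0.2`
(strict inequalities; `dm_threshold = 0.2`). The call universe is the
set of probes with both a tumor value and a normal reference.

For a TF with binding-site probe set *S* inside the universe,

```
enrichment_rate = (dm_in / total_in) / (dm_out / total_out)
```

with `dm_in = |DM ∩ S|`, `total_in = |S|`, etc. The rate is `None`
(undefined) when there are no DM calls outside *S*, and 0 when there are
calls outside but none inside. TFs whose inside or outside universe is
empty are skipped.

## 5. Windows and LAD contrast (`windows`)

`sliding_window_means` averages a per-probe value (typically the cohort
mean Δβ vs normal) in windows of `bin = 2 Mb` advanced by
`step = 1 Mb`, anchored at position 0; the final partial window is kept,
and a probe at position *p* falls in windows
`max(0, ⌊(p−bin)/step⌋+1) … min(⌊p/step⌋, n_windows−1)` — two windows
for interior probes at the defaults. Windows without probes report NaN.
Output is bedGraph-compatible.

`lad_contrast` reports, per region class, the mean value inside vs
outside a LAD overlay and their difference; it raises if no probes fall
inside.

## 6. Association battery (`associations`)

* **Clinical variables** (stage, grade, MSI, smoking, …): ordinary least
  squares of the methylation average on the variable plus age and a sex
  dummy ("adjusted for age and sex wherever applicable" — the dummy is
  dropped in single-sex cohorts); the reported p is the coefficient's
  two-sided p. Text categories are first mapped through editable ordinal
  coding tables (`ORDINAL_CODES`). Degenerate designs (constant
  variable, collinearity, n < 4) return a missing result with a note.
* **Molecular variables**: Wilcoxon rank-sum (via the equivalent
  Mann–Whitney U) for binary, Kruskal–Wallis for categorical, Kendall
  tau-b for continuous. Fully tied categorical data yields
  (statistic 0, p 1) rather than NaN.
* **Multiplicity**: hand-rolled Benjamini–Hochberg step-up with an
  explicit family size `m` that may exceed the number of returned
  p-values (the "corrected by the number of comparisons" convention);
  NaN p-values propagate as NaN q-values. `scna_scan` corrects by the
  total number of genes attempted and sorts output positionally;
  `cross_tumor_percentiles` takes per-gene 10/20/30/40th percentiles of
  corrected p across tumor types (linear interpolation,
  `np.percentile(..., method="linear")`), dropping genes present in
  fewer than two types.

All four tests are calibrated end to end: under 1 000 null replicates
the rejection rate at α = 0.05 of each test lies in [0.03, 0.07].

## 7. Synthetic-cohort generator (`simulate`)

The generator's defaults **are** the study conditions; they were fixed
from the published normal ranges before any acceptance measurement and
are not tuned to test outcomes.

### Annotations

A toy genome (default `chr1` 12 Mb, `chr2` 8 Mb, `chrX` 2 Mb) receives
~250 genes with exons on the autosomes; CGIs at 60% of TSSs plus 50
intergenic; one polycomb-like TF (SUZ12) blanketing 40% of islands plus
three randomly placed TFs; DNase sites, enhancers, repeats; two LADs of
1–2 Mb per autosome; and the derived backbone (≈ 86% of this toy genome
— intentionally larger than the human fraction, since the toy genome
carries proportionally less annotation). The probe manifest samples
2 000 CGI, 2 000 backbone and 1 000 other-region positions uniformly
over the covered bases, plus 150 flagged probes split between SNP-near,
repeat-near and sex-chromosome, exercising every QC rule.

### Noise model

* Per-probe baseline mean: `Beta(μ·ν, (1−μ)·ν)` with ν = 60 and
  compartment centers μ = 0.21 (CGI), 0.80 (backbone), 0.50 (other) —
  the midpoints of the published normal ranges.
* Per-sample compartment effect: `N(0, 0.005)` added to all probes of a
  compartment, keeping normal cohorts inside the published windows.
* Per-cell value: `Beta(m·κ, (1−m)·κ)` with κ = 300 around the cell mean
  m — mean-exact and bounded in [0, 1]. Cell means are clipped to
  [0.001, 0.999] with a warning if planted shifts escape.
* Detection p: U(0, 0.04), with a 0.002 failure rate replaced by
  U(0.051, 0.5).

### Planted structure

Each `TumorBlock` plants: a CGI shift δC concentrated 2× at
polycomb-TF islands, and a backbone shift δB concentrated 1.5× inside
LADs. Both weightings are **normalized to be mean-preserving**, so the
probe-average shift equals the nominal δ exactly; this is what makes
δB = 0.10 recoverable as a cohort mean of 0.70 ± 0.01. An additive
`lad_extra_shift` (default 0) plants a pure inside-LAD contrast on top.
Clinical slopes (age on backbone, stage on CGI), mutation effects
(gene → axis, effect, prevalence) and SCNA couplings (gene → axis,
target Kendall τ, realized through a Gaussian copula with
ρ = sin(πτ/2)) enter through the per-sample compartment effects, in
tumor blocks only. WGBS-like paired averages are the true per-sample
compartment means plus `N(0, 0.01)`.

Default blocks: TTA (null), TTB (δC = 0.10, δB = 0.01 → HC-NB),
TTC (δC = 0.08, δB = 0.10, TP53 mutation effect −0.04 at prevalence
0.4, NSD1 SCNA coupling τ = 0.4 → HC-LB).

### Determinism

All randomness flows from `CohortSpec.seed` through
`np.random.default_rng([seed, k])` child streams (k = 101 annotations,
202 cohort); equal specs yield byte-identical exports.

## 8. Pipeline and CLI

`run_pipeline(RunConfig)` chains simulate → QC → summarize →
differential/TF enrichment → windows/LAD contrast → associations → SCNA
scan, writing TSV/bedGraph outputs plus `run_manifest.json` with a
SHA-256 config digest; identical configs reproduce identical outputs.
The `backbone` CLI exposes each stage and `run-all`.

## 9. Numerical choices

* Intervals as int64 numpy arrays; membership by `searchsorted`.
* scipy for the rank tests, statsmodels OLS for adjusted models
  (standard methods, not reimplemented); BH is hand-rolled (numpy
  step-up, `np.minimum.accumulate`) to support declared family sizes,
  cross-checked against `statsmodels.stats.multitest`.
* Percentiles use linear interpolation between closest ranks.
* Averages are pairwise-complete; thresholds use strict/non-strict
  comparisons exactly as stated above (boundaries to normal classes, DM
  strictly greater).

## 10. Scope and limitations

* All problem sizes (toy genome, probe counts, cohort sizes) are this
  package's own choices, sized for single-CPU desk-scale runs.
* Passing the synthetic validation shows the *pipeline arithmetic and
  statistics* are correct and calibrated — interval algebra against a
  per-base oracle, enrichment and window math against brute force,
  planted parameters recovered, tests calibrated under the null. It
  does **not** show that real tumor cohorts have these properties;
  headline results on real data depend on consortium data and
  annotation versions and are outside desk scale.
* The generator's probe-level noise is exchangeable within compartments
  (no spatial autocorrelation beyond LAD/polycomb structure, no probe
  type-I/II chemistry bias, no batch effects); the clinical covariates
  are independent of each other; copy-number couplings act on
  compartment averages, not locally in cis.
* The WGBS arm simulates per-sample averages only, not base-level
  coverage; concordance conclusions are at the per-sample-average
  level.
* Sex-chromosome probes are removed globally, so X-linked biology is
  out of scope.
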